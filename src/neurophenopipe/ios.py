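"""Intrinsic optical signal (IOS) evoked-response analysis.

Widefield IOS imaging records cortical reflectance under red light; a
visually evoked hemodynamic response appears as a small fractional
*decrease* in reflectance over the responsive cortex.  The analysis chain
implemented here is

1. per-pixel normalisation against the pre-stimulus baseline (ΔR/R),
2. averaging across repeated stimulus trials and over a post-onset
   response window, giving a single trial-averaged response map,
3. region-of-interest (ROI) selection by a range rule: the pixels whose
   ΔR/R lies in the lowest ``fraction`` (default 30 %) of the min–max
   range of the map,
4. the evoked amplitude, reported as the magnitude of the mean
   reflectance decrease inside the ROI.

Maps keep their sign (responses are negative); the scalar amplitude is
reported positive so that a larger response sorts intuitively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "IOSMovie",
    "TrialSet",
    "ResponseMap",
    "ROIMask",
    "IOSResult",
    "DegenerateBaselineError",
    "DegenerateMapError",
    "compute_drr",
    "average_trials",
    "select_roi",
    "evoked_amplitude",
    "analyze_trialset",
]

#: trial count below which a warning (not an error) is raised; evoked IOS
#: responses are small against shot noise and are conventionally averaged
#: over at least this many stimulus presentations.
RECOMMENDED_MIN_TRIALS = 80


class DegenerateBaselineError(ValueError):
    """Baseline contains non-positive pixels; ΔR/R is undefined there."""


class DegenerateMapError(ValueError):
    """Response map is constant; the range rule cannot select an ROI."""


@dataclass
class IOSMovie:
    """A single-trial reflectance movie.

    Parameters
    ----------
    frames
        ``(n_frames, height, width)`` stack of non-negative reflectance
        counts.
    fps
        Acquisition rate in frames per second (nominally 30).
    stim_onset_frame
        Index of the first frame at/after stimulus onset.
    baseline_window
        ``(start, stop)`` frame interval (half-open) used as the
        pre-stimulus baseline.  Defaults to all frames before onset.
    """

    frames: np.ndarray
    fps: float
    stim_onset_frame: int
    baseline_window: tuple[int, int] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, height, width) stack")
        if self.frames.shape[0] < 2:
            raise ValueError("movie needs at least two frames")
        if np.any(self.frames < 0):
            raise ValueError("reflectance counts must be non-negative")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not 0 < self.stim_onset_frame < self.frames.shape[0]:
            raise ValueError("stim_onset_frame must fall inside the stack "
                             "with at least one pre-onset frame")
        if self.baseline_window is None:
            self.baseline_window = (0, self.stim_onset_frame)
        lo, hi = self.baseline_window
        if not (0 <= lo < hi <= self.stim_onset_frame):
            raise ValueError("baseline_window must be non-empty and "
                             "strictly pre-onset")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class TrialSet:
    """Repeated stimulus trials with identical geometry and timing."""

    trials: list[IOSMovie]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.trials) < 1:
            raise ValueError("TrialSet needs at least one trial")
        ref = self.trials[0]
        for m in self.trials[1:]:
            if (m.frames.shape != ref.frames.shape
                    or m.stim_onset_frame != ref.stim_onset_frame
                    or m.baseline_window != ref.baseline_window
                    or m.fps != ref.fps):
                raise ValueError("all trials must share geometry and timing")
        if len(self.trials) < RECOMMENDED_MIN_TRIALS:
            warnings.warn(
                f"TrialSet has {len(self.trials)} trials; evoked IOS "
                f"responses are conventionally averaged over at least "
                f"{RECOMMENDED_MIN_TRIALS}", stacklevel=2)

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass
class ResponseMap:
    """Trial-averaged ΔR/R map over the response window (signed)."""

    drr: np.ndarray
    response_window: tuple[int, int]
    fps: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.drr = np.asarray(self.drr, dtype=float)
        if self.drr.ndim != 2:
            raise ValueError("response map must be 2-D")
        if not np.all(np.isfinite(self.drr)):
            raise ValueError("response map contains non-finite values")


@dataclass
class ROIMask:
    """Boolean ROI from the range rule, with the cutoff that produced it."""

    mask: np.ndarray
    fraction: float
    threshold_value: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class IOSResult:
    """Bundle returned by :func:`analyze_trialset`."""

    response_map: ResponseMap
    roi: ROIMask
    amplitude: float


def compute_drr(movie: IOSMovie) -> np.ndarray:
    """Per-pixel fractional reflectance change against the baseline mean.

    ``drr[t, p] = (frames[t, p] - B[p]) / B[p]`` with ``B`` the mean over
    the movie's baseline window.  Baseline frames therefore map to ≈ 0 and
    an evoked response appears as negative values.

    Raises
    ------
    DegenerateBaselineError
        If any pixel's baseline mean is zero or negative.
    """
    lo, hi = movie.baseline_window
    baseline = movie.frames[lo:hi].mean(axis=0)
    n_bad = int(np.count_nonzero(baseline <= 0))
    if n_bad:
        raise DegenerateBaselineError(
            f"{n_bad} pixel(s) have non-positive baseline mean; "
            "ΔR/R is undefined")
    return (movie.frames - baseline) / baseline


def _default_response_window(movie: IOSMovie,
                             response_s: float = 2.0) -> tuple[int, int]:
    start = movie.stim_onset_frame
    stop = min(movie.n_frames, start + int(round(response_s * movie.fps)))
    return start, stop


def average_trials(trials: TrialSet,
                   response_window: tuple[int, int] | None = None,
                   response_s: float = 2.0) -> ResponseMap:
    """Average ΔR/R over trials, then over the post-onset response window.

    The response window defaults to stimulus onset → onset + ``response_s``
    seconds (2 s: the stimulus plus the hemodynamic lag).  Averaging is
    linear, so trial and frame averaging commute.
    """
    ref = trials.trials[0]
    if response_window is None:
        response_window = _default_response_window(ref, response_s)
    lo, hi = response_window
    if not (0 <= lo < hi <= ref.n_frames):
        raise ValueError("response_window outside the frame stack")
    acc = np.zeros(ref.shape, dtype=float)
    for movie in trials.trials:
        acc += compute_drr(movie)[lo:hi].mean(axis=0)
    drr = acc / trials.n_trials
    return ResponseMap(drr=drr, response_window=(lo, hi), fps=ref.fps,
                       metadata={"n_trials": trials.n_trials})


def select_roi(response_map: ResponseMap,
               fraction: float = 0.30,
               smooth_sigma_px: float = 1.0,
               mode: str = "range") -> ROIMask:
    """Select the response ROI from a trial-averaged ΔR/R map.

    ``mode="range"`` (default) keeps pixels whose value lies in the lowest
    ``fraction`` of the min–max range of the map, i.e. values
    ``<= min + fraction * (max - min)``.  ``mode="percentile"`` instead
    keeps the lowest ``fraction`` quantile of pixels.

    Because the range rule depends on the two extreme pixels, it is
    sensitive to residual pixel noise; the map is lightly Gaussian-smoothed
    (``smooth_sigma_px``, default 1 px) *for thresholding and mask
    derivation only*.  Amplitude is always measured on the unsmoothed map.

    Raises
    ------
    DegenerateMapError
        If the (smoothed) map is constant, so the range is zero.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    work = response_map.drr
    if smooth_sigma_px and smooth_sigma_px > 0:
        work = ndimage.gaussian_filter(work, sigma=smooth_sigma_px)
    vmin = float(work.min())
    vmax = float(work.max())
    if vmax == vmin:
        raise DegenerateMapError("response map is constant; range is zero")
    if mode == "range":
        threshold = vmin + fraction * (vmax - vmin)
    elif mode == "percentile":
        threshold = float(np.percentile(work, 100.0 * fraction))
    else:
        raise ValueError(f"unknown ROI mode {mode!r}")
    mask = work <= threshold
    return ROIMask(mask=mask, fraction=fraction, threshold_value=threshold,
                   metadata={"mode": mode,
                             "smooth_sigma_px": smooth_sigma_px,
                             "map_min": vmin, "map_max": vmax})


def evoked_amplitude(response_map: ResponseMap, roi: ROIMask) -> float:
    """Magnitude of the mean reflectance decrease inside the ROI.

    Returns ``-mean(ΔR/R)`` over the masked pixels, so that a deeper
    reflectance dip gives a larger (positive) amplitude.
    """
    if roi.mask.shape != response_map.drr.shape:
        raise ValueError("ROI and response map have different geometry")
    if roi.n_pixels == 0:
        raise ValueError("ROI mask is empty")
    return float(-response_map.drr[roi.mask].mean())


def analyze_trialset(trials: TrialSet,
                     fraction: float = 0.30,
                     response_window: tuple[int, int] | None = None,
                     response_s: float = 2.0,
                     smooth_sigma_px: float = 1.0,
                     mode: str = "range") -> IOSResult:
    """End-to-end convenience: ΔR/R averaging, ROI selection, amplitude."""
    rmap = average_trials(trials, response_window=response_window,
                          response_s=response_s)
    roi = select_roi(rmap, fraction=fraction,
                     smooth_sigma_px=smooth_sigma_px, mode=mode)
    amp = evoked_amplitude(rmap, roi)
    return IOSResult(response_map=rmap, roi=roi, amplitude=amp)


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Jaccard overlap between two boolean masks (1.0 for identical)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
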