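"""Line-length seizure detection, event metrics, Racine severity mapping.

Ictal activity is detected with the classic line-length feature: over a
sliding window, the sum of absolute successive sample differences of the
band-passed trace.  A per-animal threshold is calibrated on a
seizure-free baseline period as ``mean + k × SD`` of the windowed line
length (k = 8 by default).  Candidate events must lie in the 2–10 Hz
band (a zero-phase 4th-order Butterworth band-pass applied before the
statistic) and last at least 10 s.

Coarse supra-threshold windows localise an event only to within the
window length, so event edges are refined on a finely stepped
line-length profile: as the window slides across an event edge the line
length ramps between its baseline and ictal levels over exactly one
window length, so the half-level crossing (shifted by half a window)
estimates the edge to a fraction of the window.  The minimum-duration
rule is applied to the refined span.

Behavioral severity uses the 6-stage Racine scale, collapsed to three
categories: stages 1–2 tonic, stage 3 clonic, stages 4–6 tonic-clonic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .eeg import EEGRecording

__all__ = [
    "DetectorConfig",
    "SeizureEvent",
    "CalibrationResult",
    "RACINE_CATEGORIES",
    "line_length",
    "sliding_line_length",
    "bandpass",
    "calibrate_threshold",
    "detect_seizures",
    "event_metrics",
    "classify_racine",
    "incidence_table",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Parameters of the line-length detector.

    band_lo/band_hi : Hz, pass band applied before the statistic.
    threshold_k     : SD multiplier of the baseline threshold rule.
    min_duration_s  : events shorter than this are discarded.
    window_s/step_s : sliding line-length windowing.
    merge_gap_s     : supra-threshold spans closer than this are merged.
    refine_edges    : refine event boundaries on a fine line-length grid.
    refine_step_s   : step of that fine grid.
    normalize       : report line length per sample instead of per window.
    """

    band_lo: float = 2.0
    band_hi: float = 10.0
    threshold_k: float = 8.0
    min_duration_s: float = 10.0
    window_s: float = 1.0
    step_s: float = 0.5
    merge_gap_s: float = 1.0
    refine_edges: bool = True
    refine_step_s: float = 0.05
    normalize: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.band_lo < self.band_hi:
            raise ValueError("need 0 < band_lo < band_hi")
        if self.threshold_k < 0:
            raise ValueError("threshold_k must be non-negative")
        if self.min_duration_s <= 0:
            raise ValueError("min_duration_s must be positive")
        if not 0 < self.step_s <= self.window_s:
            raise ValueError("need 0 < step_s <= window_s")


@dataclass
class SeizureEvent:
    """A detected ictal interval on the record time base (seconds)."""

    start_s: float
    end_s: float
    peak_line_length: float
    channel: str = "frontal"

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError("event must have start_s < end_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class CalibrationResult:
    """Baseline line-length statistics and the resulting cutoff."""

    mean: float
    sd: float
    k: float
    threshold: float
    n_windows: int
    sd_convention: str = "sample (ddof=1)"


RACINE_CATEGORIES = {1: "tonic", 2: "tonic",
                     3: "clonic",
                     4: "tonic-clonic", 5: "tonic-clonic",
                     6: "tonic-clonic"}


def line_length(window: np.ndarray) -> float:
    """Sum of absolute successive differences over one window (µV)."""
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("line length needs a 1-D window of >= 2 samples")
    return float(np.abs(np.diff(x)).sum())


def bandpass(x: np.ndarray, fs: float, lo: float, hi: float,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    if hi >= fs / 2.0:
        raise ValueError(f"band edge {hi} Hz at/above Nyquist {fs / 2} Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def sliding_line_length(x: np.ndarray, fs: float,
                        window_s: float = 1.0, step_s: float = 0.5,
                        normalize: bool = False
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Line length over sliding windows.

    Returns ``(start_times_s, ll)`` where window *i* covers
    ``[start[i], start[i] + window_s)``.  With ``normalize`` the value is
    divided by the number of samples in the window.
    """
    x = np.asarray(x, dtype=float)
    win = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if win < 2 or len(x) < win:
        raise ValueError("record shorter than one line-length window")
    absdiff = np.abs(np.diff(x))
    csum = np.concatenate(([0.0], np.cumsum(absdiff)))
    starts = np.arange(0, len(x) - win + 1, step)
    # window of `win` samples spans `win - 1` successive differences
    ll = csum[starts + win - 1] - csum[starts]
    if normalize:
        ll = ll / win
    return starts / fs, ll


def calibrate_threshold(baseline: EEGRecording | np.ndarray,
                        cfg: DetectorConfig = DetectorConfig(),
                        fs: float | None = None,
                        channel: int | str = 0) -> CalibrationResult:
    """Threshold = baseline mean line length + k × SD (sample SD, n−1).

    ``baseline`` is a user-designated seizure-free interval.  The trace is
    band-passed to the detector band before the statistic, matching
    detection.
    """
    if isinstance(baseline, EEGRecording):
        x = baseline.channel(channel)
        fs = baseline.fs
    else:
        x = np.asarray(baseline, dtype=float)
        if fs is None:
            raise ValueError("fs required when baseline is a bare array")
    xf = bandpass(x, fs, cfg.band_lo, cfg.band_hi)
    _, ll = sliding_line_length(xf, fs, cfg.window_s, cfg.step_s,
                                cfg.normalize)
    if len(ll) < 2:
        raise ValueError("baseline must span at least two line-length "
                         "windows")
    mean = float(ll.mean())
    sd = float(ll.std(ddof=1))
    return CalibrationResult(mean=mean, sd=sd, k=cfg.threshold_k,
                             threshold=mean + cfg.threshold_k * sd,
                             n_windows=len(ll))


def _merge_spans(spans: list[tuple[float, float]],
                 gap_s: float) -> list[tuple[float, float]]:
    merged: list[tuple[float, float]] = []
    for start, end in spans:
        if merged and start - merged[-1][1] < gap_s:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _supra_runs(supra: np.ndarray, times: np.ndarray,
                gap_s: float) -> list[tuple[int, int]]:
    """Index runs of True entries, bridging gaps shorter than ``gap_s``."""
    idx = np.flatnonzero(supra)
    if len(idx) == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = idx[0]
    for i in idx[1:]:
        if times[i] - times[prev] >= gap_s:
            runs.append((start, prev))
            start = i
        prev = i
    runs.append((start, prev))
    return runs


def _refine_span(span: tuple[float, float], fine_t: np.ndarray,
                 fine_ll: np.ndarray, base_level: float,
                 cfg: DetectorConfig) -> tuple[float, float] | None:
    """Refine one coarse span on the finely stepped line-length profile.

    The ictal line-length level is the median fine value inside the
    coarse span; the refined event is the supra run (above the midpoint
    between baseline and ictal level, small gaps bridged) that overlaps
    the span, with both edges shifted by half a window — where the
    half-level crossing of the sliding statistic marks the true edge.
    """
    inside = (fine_t >= span[0]) & (fine_t + cfg.window_s <= span[1])
    if not inside.any():
        inside = (fine_t + cfg.window_s > span[0]) & (fine_t < span[1])
    if not inside.any():
        return None
    burst_level = float(np.median(fine_ll[inside]))
    level = 0.5 * (base_level + burst_level)
    supra = fine_ll > level
    half = cfg.window_s / 2.0
    best = None
    for i0, i1 in _supra_runs(supra, fine_t, cfg.merge_gap_s):
        t0 = fine_t[i0] + half
        t1 = fine_t[i1] + half
        overlap = min(t1, span[1]) - max(t0, span[0])
        if overlap > 0 and (best is None
                            or (t1 - t0) > (best[1] - best[0])):
            best = (float(t0), float(t1))
    return best


def detect_seizures(rec: EEGRecording,
                    threshold: float | CalibrationResult,
                    cfg: DetectorConfig = DetectorConfig(),
                    channel: int | str = 0) -> list[SeizureEvent]:
    """Detect ictal events against a calibrated line-length threshold.

    The trace is zero-phase band-passed to ``[band_lo, band_hi]``, the
    sliding line length computed, supra-threshold windows merged across
    gaps shorter than ``merge_gap_s``, edges refined (optional), and
    spans of at least ``min_duration_s`` returned sorted by start time.
    """
    if isinstance(threshold, CalibrationResult):
        threshold = threshold.threshold
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ch_name = (channel if isinstance(channel, str)
               else rec.channel_names[channel])
    x = rec.channel(channel)
    xf = bandpass(x, rec.fs, cfg.band_lo, cfg.band_hi)
    starts, ll = sliding_line_length(xf, rec.fs, cfg.window_s, cfg.step_s,
                                     cfg.normalize)
    supra = ll > threshold
    spans = [(float(t), float(t + cfg.window_s))
             for t in starts[supra]]
    merged = _merge_spans(spans, cfg.merge_gap_s)
    if cfg.refine_edges and merged:
        fine_t, fine_ll = sliding_line_length(
            xf, rec.fs, cfg.window_s, cfg.refine_step_s, cfg.normalize)
        base_level = float(np.median(fine_ll))
        refined_spans = []
        for span in merged:
            refined = _refine_span(span, fine_t, fine_ll, base_level, cfg)
            if refined is not None:
                refined_spans.append(refined)
        # fragments of one burst may refine to overlapping spans
        merged = _merge_spans(sorted(refined_spans), 0.0)
    events: list[SeizureEvent] = []
    for span in merged:
        if span[1] - span[0] < cfg.min_duration_s:
            continue
        in_span = (starts + cfg.window_s > span[0]) & (starts < span[1])
        peak = float(ll[in_span].max()) if in_span.any() else float("nan")
        events.append(SeizureEvent(
            start_s=rec.start_time_s + span[0],
            end_s=rec.start_time_s + span[1],
            peak_line_length=peak, channel=ch_name))
    events.sort(key=lambda ev: ev.start_s)
    return events


def event_metrics(events: Sequence[SeizureEvent],
                  record_start_s: float = 0.0,
                  record_duration_s: float | None = None) -> dict:
    """Latency to first event, event rate per hour, mean event duration.

    With no events, latency and mean duration are ``None`` and the rate
    is 0.  ``record_duration_s`` is required for the rate.
    """
    if record_duration_s is None or record_duration_s <= 0:
        raise ValueError("record_duration_s must be a positive duration")
    if not events:
        return {"latency_s": None, "frequency_per_h": 0.0,
                "mean_duration_s": None, "n_events": 0}
    ordered = sorted(events, key=lambda ev: ev.start_s)
    durations = [ev.duration_s for ev in ordered]
    return {
        "latency_s": ordered[0].start_s - record_start_s,
        "frequency_per_h": len(ordered) / (record_duration_s / 3600.0),
        "mean_duration_s": float(np.mean(durations)),
        "n_events": len(ordered),
    }


def classify_racine(stage: int) -> str:
    """Collapse a Racine stage (1–6) to tonic / clonic / tonic-clonic."""
    if not isinstance(stage, (int, np.integer)) or isinstance(stage, bool):
        raise ValueError("Racine stage must be an integer")
    if stage not in RACINE_CATEGORIES:
        raise ValueError(f"Racine stage {stage} outside 1..6")
    return RACINE_CATEGORIES[int(stage)]


def incidence_table(seized: pd.DataFrame | dict,
                    groups: Sequence[str] | None = None) -> pd.DataFrame:
    """Group × {seized, not_seized} contingency counts.

    ``seized`` is a DataFrame with ``group`` and boolean ``seized``
    columns (or a mapping group → iterable of booleans).  ``groups``
    optionally fixes the expected group set; unknown labels then raise
    and empty groups appear as (0, 0) rows.
    """
    if isinstance(seized, dict):
        rows = [(g, bool(v)) for g, vals in seized.items() for v in vals]
        seized = pd.DataFrame(rows, columns=["group", "seized"])
    if not {"group", "seized"} <= set(seized.columns):
        raise ValueError("need 'group' and 'seized' columns")
    if groups is not None:
        unknown = set(seized["group"]) - set(groups)
        if unknown:
            raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    table = pd.crosstab(seized["group"], seized["seized"].astype(bool))
    table = table.reindex(columns=[True, False], fill_value=0)
    table.columns = ["seized", "not_seized"]
    if groups is not None:
        table = table.reindex(groups, fill_value=0)
    table.index.name = "group"
    return table
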