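"""Scoring of the four behavioral assays from event-level inputs.

* Y-maze spontaneous alternation: a *triad* is three consecutive arm
  entries into three different arms; the alternation percentage is
  ``100 · n_triads / (n_entries − 2)`` (the maximum-possible-triads
  denominator).
* Morris water maze (MWM): swim-path distance and speed over the last
  training days, and probe-trial quadrant occupancy (target / right /
  opposite / left) in a 120-cm circular tank.
* Rotarod: mean fall latency over the trials of a session.
* Self-grooming: cumulative bout time inside the scoring window
  (by default minutes 10–20 of a 20-min session, after habituation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ArmEntrySequence",
    "SwimPath",
    "score_alternation",
    "path_length",
    "mwm_training_summary",
    "probe_quadrant_times",
    "grooming_time",
    "rotarod_latency",
]

QUADRANTS = ("T", "R", "O", "L")


@dataclass
class ArmEntrySequence:
    """Ordered arm entries in a three-arm (Y) maze.

    An entry is scored only when the animal fully enters a *different*
    arm, so consecutive duplicate labels are invalid.
    """

    entries: list[str]
    arms: tuple[str, ...] = ("A", "B", "C")
    session_duration_s: float = 480.0

    def __post_init__(self) -> None:
        self.entries = list(self.entries)
        bad = set(self.entries) - set(self.arms)
        if bad:
            raise ValueError(f"entries outside the arm set: {sorted(bad)}")
        for prev, cur in zip(self.entries, self.entries[1:]):
            if prev == cur:
                raise ValueError(
                    "consecutive duplicate arm entries are invalid: "
                    "re-entering the same arm is not a new entry")

    @property
    def n_entries(self) -> int:
        return len(self.entries)


def score_alternation(seq: ArmEntrySequence) -> dict:
    """Spontaneous alternation score of an arm-entry sequence.

    Counts consecutive entry triples visiting three distinct arms and
    reports ``alternation_pct = 100 · n_triads / (n_entries − 2)``.
    With fewer than three entries the percentage is undefined (``None``).
    """
    entries = seq.entries
    n = len(entries)
    n_triads = sum(
        len({entries[i], entries[i + 1], entries[i + 2]}) == 3
        for i in range(n - 2))
    pct = 100.0 * n_triads / (n - 2) if n >= 3 else None
    return {"n_entries": n, "n_triads": n_triads, "alternation_pct": pct}


@dataclass
class SwimPath:
    """Timestamped 2-D positions (cm) in a circular water tank.

    Coordinates are relative to the tank centre.  ``platform_center`` and
    ``platform_halfwidth`` describe the (possibly removed) escape
    platform; ``day`` and ``trial`` identify the training session.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    tank_diameter_cm: float = 120.0
    platform_center: tuple[float, float] | None = None
    platform_halfwidth_cm: float = 5.5
    day: int | None = None
    trial: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise ValueError("a swim path needs at least two samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        r = np.hypot(self.x, self.y)
        if np.any(r > self.tank_diameter_cm / 2.0 + 1e-9):
            raise ValueError("positions outside the tank")

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])


def path_length(path: SwimPath) -> float:
    """Total swim distance: sum of consecutive Euclidean steps (cm)."""
    return float(np.hypot(np.diff(path.x), np.diff(path.y)).sum())


def mwm_training_summary(paths: Sequence[SwimPath],
                         last_k_days: int = 3,
                         trials_per_day: int = 4) -> dict:
    """Mean distance and speed over the final training days.

    Averages over the ``last_k_days × trials_per_day`` trials of the
    final ``last_k_days`` training days; trials in which the platform was
    never reached contribute their full (time-limited) path.  Speed is
    each trial's distance over its duration, then averaged.
    """
    if any(p.day is None or p.trial is None for p in paths):
        raise ValueError("every path needs day and trial labels")
    days = sorted({p.day for p in paths})
    keep_days = set(days[-last_k_days:])
    selected = [p for p in paths if p.day in keep_days]
    if not selected:
        raise ValueError("no trials on the selected training days")
    distances = np.array([path_length(p) for p in selected])
    speeds = np.array([path_length(p) / p.duration_s for p in selected])
    return {
        "mean_distance_cm": float(distances.mean()),
        "mean_speed_cm_s": float(speeds.mean()),
        "n_trials": len(selected),
        "days_used": sorted(keep_days),
    }


def _quadrant_of(x: float, y: float, target_angle: float) -> str:
    """Quadrant label by angle, half-open 90° sectors centred on T.

    ``L`` is the counter-clockwise neighbour of the target quadrant and
    ``R`` the clockwise one; boundaries belong to the sector they open.
    """
    delta = math.atan2(y, x) - target_angle
    delta = (delta + math.pi) % (2.0 * math.pi) - math.pi  # wrap to (-pi, pi]
    quarter = math.pi / 4.0
    if -quarter <= delta < quarter:
        return "T"
    if quarter <= delta < 3 * quarter:
        return "L"
    if -3 * quarter <= delta < -quarter:
        return "R"
    return "O"


def probe_quadrant_times(path: SwimPath,
                         duration_s: float = 60.0) -> dict[str, float]:
    """Time spent per quadrant during the probe trial.

    The tank is divided into four 90° sectors centred on the target
    quadrant axis (the direction of the platform centre).  Each sample
    interval is assigned to the quadrant of its starting position, so the
    four times sum to the sampled duration to within one sample interval.
    """
    if path.platform_center is None:
        raise ValueError("probe analysis needs the platform centre to "
                         "orient the target quadrant")
    px, py = path.platform_center
    if px == 0 and py == 0:
        raise ValueError("platform centre cannot be the tank centre")
    target_angle = math.atan2(py, px)
    times = dict.fromkeys(QUADRANTS, 0.0)
    dt = np.diff(path.t)
    for i, step in enumerate(dt):
        q = _quadrant_of(path.x[i], path.y[i], target_angle)
        times[q] += float(step)
    # the final sample holds until the nominal end of the trial
    remaining = duration_s - (path.t[-1] - path.t[0])
    if remaining > 0:
        q = _quadrant_of(path.x[-1], path.y[-1], target_angle)
        times[q] += float(remaining)
    return times


def grooming_time(bouts: Sequence[tuple[float, float]],
                  scoring_window: tuple[float, float] = (600.0, 1200.0)
                  ) -> float:
    """Cumulative grooming time inside the scoring window (seconds).

    ``bouts`` are non-overlapping ``(start_s, end_s)`` intervals on the
    session time base; each contributes its intersection with the window
    (default: minutes 10–20, after a 10-min habituation).
    """
    w0, w1 = scoring_window
    if not w0 < w1:
        raise ValueError("scoring window must be a proper interval")
    ordered = sorted((float(a), float(b)) for a, b in bouts)
    for (a0, a1), (b0, b1) in zip(ordered, ordered[1:]):
        if b0 < a1:
            raise ValueError("grooming bouts overlap")
    total = 0.0
    for a, b in ordered:
        if b <= a:
            raise ValueError("bout end must follow bout start")
        total += max(0.0, min(b, w1) - max(a, w0))
    return total


def rotarod_latency(latencies: Sequence[float]) -> float:
    """Mean fall latency (s) over the consecutive trials of a session."""
    arr = np.asarray(list(latencies), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one trial latency required")
    if np.any(arr < 0):
        raise ValueError("latencies must be non-negative")
    return float(arr.mean())
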