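"""EEG epoching, FFT band power, and vigilance-stratified averaging.

Cortical EEG (nominally 400 Hz, frontal and occipital screw electrodes)
is segmented into fixed 30-s epochs and converted to power spectra by
FFT.  Power is integrated over the canonical rodent bands

====== ============
delta  0.5–4 Hz
theta  4–8 Hz
alpha  8–12 Hz
beta   12–30 Hz
gamma  30–45 Hz
====== ============

with half-open edges ``[lo, hi)`` so shared edges are never counted
twice, and the five band powers sum exactly to the total 0.5–45 Hz
power.  Epoch means are then stratified by vigilance state (active wake /
passive wake / sleep) and light cycle, requiring a minimum number of
epochs per stratum before a mean is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "CANONICAL_BANDS",
    "STATES",
    "CYCLES",
    "EEGRecording",
    "VigilanceLabels",
    "segment_epochs",
    "band_powers",
    "band_power_table",
    "average_band_powers",
    "exclude_epochs",
]

#: half-open [lo, hi) canonical band edges in Hz
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}

STATES = ("active-wake", "passive-wake", "sleep")
CYCLES = ("light", "dark")


@dataclass
class EEGRecording:
    """Sampled EEG trace in microvolts.

    ``data`` is ``(n_channels, n_samples)``; a 1-D array is promoted to a
    single channel.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = ("frontal",)
    start_time_s: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG samples must be finite")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("one channel name per data row required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, key: int | str = 0) -> np.ndarray:
        if isinstance(key, str):
            key = self.channel_names.index(key)
        return self.data[key]


@dataclass
class VigilanceLabels:
    """Per-epoch vigilance state and light-cycle annotations."""

    states: np.ndarray
    cycles: np.ndarray
    epoch_s: float = 30.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=object)
        self.cycles = np.asarray(self.cycles, dtype=object)
        if self.states.shape != self.cycles.shape or self.states.ndim != 1:
            raise ValueError("states and cycles must be equal-length 1-D")
        bad = set(self.states) - set(STATES)
        if bad:
            raise ValueError(f"unknown vigilance state(s): {sorted(bad)}")
        bad = set(self.cycles) - set(CYCLES)
        if bad:
            raise ValueError(f"unknown light-cycle label(s): {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return len(self.states)


def segment_epochs(rec: EEGRecording, epoch_s: float = 30.0) -> np.ndarray:
    """Split a recording into consecutive non-overlapping epochs.

    Returns ``(n_epochs, n_channels, samples_per_epoch)``; a trailing
    partial epoch is dropped.  Raises if the record is shorter than one
    epoch.
    """
    spe = int(round(epoch_s * rec.fs))
    n_epochs = rec.n_samples // spe
    if n_epochs < 1:
        raise ValueError(
            f"record of {rec.duration_s:.1f} s is shorter than one "
            f"{epoch_s:.0f}-s epoch")
    trimmed = rec.data[:, :n_epochs * spe]
    return trimmed.reshape(rec.n_channels, n_epochs, spe).swapaxes(0, 1)


def band_powers(epoch: np.ndarray, fs: float,
                bands: Mapping[str, tuple[float, float]] = CANONICAL_BANDS,
                window: str = "hann",
                welch_nperseg: int | None = None) -> dict[str, float]:
    """Band powers (µV²) of one epoch from a Hann-windowed periodogram.

    The epoch mean is removed before the FFT (DC lies outside every band).
    Band power is the integral of the one-sided spectral density over the
    half-open interval ``[lo, hi)``; ``total`` integrates over the full
    0.5–45 Hz analysis range.  With ``welch_nperseg`` set, Welch averaging
    of shorter segments replaces the single periodogram.
    """
    x = np.asarray(epoch, dtype=float)
    if x.ndim != 1:
        raise ValueError("epoch must be a 1-D sample array")
    hi_edge = max(hi for _, hi in bands.values())
    if fs / 2.0 < hi_edge:
        raise ValueError(
            f"fs={fs} Hz gives Nyquist {fs / 2:.1f} Hz < top band edge "
            f"{hi_edge:.1f} Hz")
    lo_edge = min(lo for lo, _ in bands.values())
    if len(x) < 2.0 * fs / lo_edge:
        raise ValueError("epoch too short to resolve the lowest band edge")
    if welch_nperseg:
        freqs, psd = sps.welch(x, fs=fs, window=window,
                               nperseg=welch_nperseg, detrend="constant")
    else:
        freqs, psd = sps.periodogram(x, fs=fs, window=window,
                                     detrend="constant")
    df = freqs[1] - freqs[0]
    out: dict[str, float] = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs < hi)
        out[name] = float(psd[sel].sum() * df)
    sel = (freqs >= lo_edge) & (freqs < hi_edge)
    out["total"] = float(psd[sel].sum() * df)
    return out


def band_power_table(rec: EEGRecording, epoch_s: float = 30.0,
                     channel: int | str = 0,
                     bands: Mapping[str, tuple[float, float]] = CANONICAL_BANDS,
                     **kwargs) -> pd.DataFrame:
    """Per-epoch band-power table for one channel.

    Returns a DataFrame indexed by epoch number with one column per band
    plus ``total``; fs and epoch length are kept in ``attrs``.
    """
    epochs = segment_epochs(rec, epoch_s=epoch_s)
    ch = (rec.channel_names.index(channel)
          if isinstance(channel, str) else channel)
    rows = [band_powers(ep[ch], rec.fs, bands=bands, **kwargs)
            for ep in epochs]
    table = pd.DataFrame(rows)
    table.index.name = "epoch"
    table.attrs["fs"] = rec.fs
    table.attrs["epoch_s"] = epoch_s
    table.attrs["channel"] = rec.channel_names[ch]
    return table


def average_band_powers(table: pd.DataFrame, labels: VigilanceLabels,
                        min_epochs: int = 12) -> pd.DataFrame:
    """Mean band powers per (state, cycle) stratum.

    A stratum mean is reported only when the stratum holds at least
    ``min_epochs`` epochs; under-populated strata keep their epoch count
    but carry NaN means.  ``labels`` must align one-to-one with the rows
    of ``table``.
    """
    idx = table.index.to_numpy().astype(int)
    if len(table) == 0:
        raise ValueError("empty band-power table")
    if idx.max() >= labels.n_epochs or labels.n_epochs < len(table):
        raise ValueError(
            f"{labels.n_epochs} labels cannot annotate epochs "
            f"{idx.min()}..{idx.max()}; annotations must align with the "
            "epoch table")
    value_cols = list(table.columns)
    work = table.copy()
    work["state"] = labels.states[idx]
    work["cycle"] = labels.cycles[idx]
    grouped = work.groupby(["state", "cycle"], sort=True)
    means = grouped[value_cols].mean()
    counts = grouped.size().rename("n_epochs")
    out = means.join(counts)
    under = out["n_epochs"] < min_epochs
    out.loc[under, value_cols] = np.nan
    out.attrs["min_epochs"] = min_epochs
    return out


def exclude_epochs(table: pd.DataFrame, events: Sequence,
                   epoch_s: float | None = None,
                   record_start_s: float = 0.0) -> pd.DataFrame:
    """Drop epochs that overlap any detected ictal event.

    ``events`` is a sequence of objects with ``start_s``/``end_s`` (or
    ``(start, end)`` tuples) on the record time base.  Used to keep
    baseline spectra uncontaminated by seizure activity.  Dropped epoch
    indices are recorded in ``result.attrs["excluded_epochs"]``.
    """
    if epoch_s is None:
        epoch_s = table.attrs.get("epoch_s", 30.0)
    drop: list[int] = []
    for idx in table.index:
        ep_start = record_start_s + idx * epoch_s
        ep_end = ep_start + epoch_s
        for ev in events:
            start = getattr(ev, "start_s", None)
            end = getattr(ev, "end_s", None)
            if start is None:
                start, end = ev
            if start < ep_end and end > ep_start:
                drop.append(idx)
                break
    out = table.drop(index=drop)
    out.attrs.update(table.attrs)
    out.attrs["excluded_epochs"] = drop
    return out
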