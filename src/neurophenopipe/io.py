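"""File I/O: multi-page TIFF stacks, EDF traces, schema-checked CSV.

TIFF stacks carry one frame per page with a JSON sidecar for timing
metadata (fps, stimulus onset).  EEG goes to EDF (16-bit, physical unit
µV); reading uses MNE's EDF reader, writing a minimal single-record-rate
EDF writer (no installed library writes EDF).  Tables are CSV with an
explicit column schema that fails loudly on unknown or missing columns.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .eeg import EEGRecording

__all__ = [
    "SchemaError",
    "write_tiff_stack",
    "read_tiff_stack",
    "write_edf",
    "read_edf",
    "write_table",
    "read_table",
]


class SchemaError(ValueError):
    """A table does not match its declared column schema."""


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def write_tiff_stack(path: str | Path, frames: np.ndarray,
                     metadata: dict | None = None) -> Path:
    """Write a (time, height, width) stack as a multi-page TIFF.

    Float stacks are stored as 32-bit float pages; integer stacks keep
    their dtype.  ``metadata`` goes to a ``<stem>.json`` sidecar.
    """
    path = Path(path)
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("expected a (time, height, width) stack")
    if np.issubdtype(frames.dtype, np.floating):
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames, photometric="minisblack")
    if metadata is not None:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(metadata, indent=2, sort_keys=True))
    return path


def read_tiff_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF stack and its JSON sidecar (if present)."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return frames, meta


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, rec: EEGRecording,
              patient: str = "X", recording: str = "X") -> Path:
    """Write an EEG recording to EDF (int16, physical dimension uV).

    One data record per second; a trailing partial second is zero-padded
    (the true sample count is recoverable from the recording duration).
    The physical range is chosen symmetric around zero from the data, so
    the quantisation step is ``max|x| / 32767``.
    """
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs))  # samples per 1-s record
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / spr))
    phys_max = float(np.max(np.abs(rec.data)))
    if phys_max == 0:
        phys_max = 1.0
    header = b"".join([
        _edf_field("0", 8),
        _edf_field(patient, 80),
        _edf_field(recording, 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(256 * (1 + n_ch)), 8),
        _edf_field("", 44),
        _edf_field(str(n_records), 8),
        _edf_field("1", 8),
        _edf_field(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(_edf_field(name, 16) for name in rec.channel_names),
        b"".join(_edf_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_field("uV", 8) for _ in range(n_ch)),
        b"".join(_edf_field(f"{-phys_max:.6g}"[:8], 8)
                 for _ in range(n_ch)),
        b"".join(_edf_field(f"{phys_max:.6g}"[:8], 8)
                 for _ in range(n_ch)),
        b"".join(_edf_field("-32768", 8) for _ in range(n_ch)),
        b"".join(_edf_field("32767", 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_field(str(spr), 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 32) for _ in range(n_ch)),
    ])
    # the header writes physical min/max truncated to 8 ascii chars;
    # quantise against the values actually written so the round trip
    # stays within one digital step
    written_max = float(f"{phys_max:.6g}"[:8])
    written_min = float(f"{-phys_max:.6g}"[:8])
    scale = (written_max - written_min) / (32767 - (-32768))
    offset = written_min - (-32768) * scale
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :rec.n_samples] = rec.data
    digital = np.clip(np.round((padded - offset) / scale),
                      -32768, 32767).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_records):
            for ch in range(n_ch):
                fh.write(digital[ch, r * spr:(r + 1) * spr].tobytes())
    return path


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (µV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data(units="uV")
    return EEGRecording(data=data, fs=float(raw.info["sfreq"]),
                        channel_names=tuple(raw.ch_names),
                        metadata={"source": str(path)})


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_table(path: str | Path, table: pd.DataFrame,
                index: bool = False) -> Path:
    path = Path(path)
    table.to_csv(path, index=index)
    return path


def read_table(path: str | Path,
               schema: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, optionally enforcing an exact column schema."""
    table = pd.read_csv(path)
    if schema is not None:
        expected = list(schema)
        got = list(table.columns)
        missing = [c for c in expected if c not in got]
        unknown = [c for c in got if c not in expected]
        if missing or unknown:
            raise SchemaError(
                f"{path}: schema mismatch (missing={missing}, "
                f"unknown={unknown})")
    return table
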