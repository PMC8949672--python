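"""ECG record loading and fixed-window beat segmentation.

Records are cut into consecutive non-overlapping one-second windows starting
at t=0; a trailing partial window is dropped.  No R-peak alignment or
filtering is performed — the constant timeframe is the whole contract.
Per-beat z-scoring is available (and on by default in the pipeline) to remove
the mV scale before the wavelet transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ECGRecord",
    "Beat",
    "FormatError",
    "CapabilityError",
    "segment_beats",
    "zscore",
    "load_csv",
    "load_wfdb",
]


class FormatError(ValueError):
    """Malformed input file."""


class CapabilityError(RuntimeError):
    """An optional capability (e.g. WFDB support) is not available."""


@dataclass
class ECGRecord:
    samples: np.ndarray
    fs: float
    record_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if self.samples.size == 0:
            raise ValueError("record has no samples")


@dataclass
class Beat:
    samples: np.ndarray
    source_record: str
    index: int
    label: str | None = None
    fs: float = 360.0


def segment_beats(record: ECGRecord, window: float = 1.0) -> list[Beat]:
    """Cut a record into consecutive windows of ``window`` seconds.

    Beat i covers samples [i*L, (i+1)*L) with L = round(fs*window); the
    trailing partial window is dropped.  Beats inherit the record label.
    """
    if window <= 0:
        raise ValueError(f"window must be > 0, got {window}")
    L = int(round(record.fs * window))
    n = len(record.samples)
    if n < L:
        raise ValueError(
            f"record '{record.record_id}' has {n} samples, shorter than one "
            f"{window} s window ({L} samples); no beats produced"
        )
    n_beats = n // L
    return [
        Beat(
            samples=record.samples[i * L : (i + 1) * L].copy(),
            source_record=record.record_id,
            index=i,
            label=record.label,
            fs=record.fs,
        )
        for i in range(n_beats)
    ]


def zscore(samples: np.ndarray) -> np.ndarray:
    """Per-beat standardisation; a constant beat maps to all zeros."""
    s = np.asarray(samples, dtype=float)
    sd = s.std()
    if sd == 0:
        return np.zeros_like(s)
    return (s - s.mean()) / sd


def load_csv(path) -> list[ECGRecord]:
    """Read records from the ``label,fs,s0,s1,...`` CSV dialect.

    One record per row.  A missing ``fs`` column or any non-finite sample is
    a FormatError naming the offending row (1-based, excluding the header).
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        logger.warning("CSV file %s is empty; returning no records", path)
        return []
    if df.empty:
        logger.warning("CSV file %s has no data rows; returning no records", path)
        return []
    cols = list(df.columns)
    if "fs" not in cols:
        raise FormatError(f"{path}: header must declare an 'fs' column, got {cols}")
    sample_cols = [c for c in cols if c not in ("label", "fs")]
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        vals = np.array([d[c] for c in sample_cols], dtype=float)
        if not np.all(np.isfinite(vals)):
            bad = sample_cols[int(np.flatnonzero(~np.isfinite(vals))[0])]
            raise FormatError(f"{path}: non-numeric sample in row {i} (column {bad})")
        fs = float(d["fs"])
        label = str(d["label"]) if "label" in d else None
        records.append(ECGRecord(vals, fs=fs, record_id=f"row{i}", label=label))
    return records


def load_wfdb(path) -> list[ECGRecord]:
    """Read a WFDB record (optional feature; requires the ``wfdb`` package).

    Only channel 0 is used; the sampling rate comes from the header.
    Annotations are not read — fragment labels come from a sidecar table.
    """
    try:
        import wfdb  # type: ignore
    except ImportError as exc:
        raise CapabilityError(
            "WFDB support requires the optional 'wfdb' package "
            "(pip install arrhythmianet[wfdb]); the core pipeline does not need it"
        ) from exc
    rec = wfdb.rdrecord(str(path))
    sig = np.asarray(rec.p_signal)
    if sig.ndim == 2 and sig.shape[1] > 1:
        logger.info("record %s has %d channels; using channel 0", path, sig.shape[1])
    samples = sig[:, 0] if sig.ndim == 2 else sig
    return [ECGRecord(samples, fs=float(rec.fs), record_id=str(rec.record_name))]
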