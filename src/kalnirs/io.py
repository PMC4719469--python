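"""Reading and writing the recording / event table formats.

A recording is a wide CSV: a ``time_s`` column (seconds from record
start, uniformly sampled) followed by one column per channel, named
``O{k}_HbO2`` and ``O{k}_HHb`` for optodes k = 1..16, holding
concentration changes relative to baseline.  Events are a
tab-separated table with ``onset``, ``duration`` (seconds) and
``condition`` columns (BIDS-events-like), plus an optional
``subject_id``.  Values round-trip bit-exactly (shortest-repr float
serialization).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
]

_TIME_JITTER = 1e-9  # max tolerated deviation from uniform sampling (s)


@dataclass
class Recording:
    """Multi-channel concentration time series at a fixed sample rate."""

    data: pd.DataFrame = field(repr=False)
    fs: float
    subject_id: str | None = None

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if "time_s" not in cols:
            raise ValueError("recording is missing the time_s column")
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise ValueError(f"duplicate channel names: {dupes}")
        t = self.data["time_s"].to_numpy(dtype=float)
        expected = np.arange(len(t)) / self.fs + t[0]
        bad = np.nonzero(np.abs(t - expected) > _TIME_JITTER)[0]
        if bad.size:
            # +2: header line, 1-based file lines
            raise ValueError(
                f"non-uniform sampling at line {bad[0] + 2} "
                f"(time_s={t[bad[0]]!r}, expected {expected[bad[0]]!r})"
            )

    @property
    def channels(self) -> list[str]:
        return [c for c in self.data.columns if c != "time_s"]

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def n_optodes(self) -> int:
        return sum(1 for c in self.channels if c.endswith("_HbO2"))

    @property
    def duration(self) -> float:
        """Time of the last sample, seconds."""
        return (self.n_samples - 1) / self.fs

    @property
    def time(self) -> np.ndarray:
        return self.data["time_s"].to_numpy(dtype=float)

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def chromophore(self, which: str = "HbO2") -> np.ndarray:
        """(n_samples, n_optodes) matrix of one chromophore, optode order."""
        names = [f"O{k}_{which}" for k in range(1, self.n_optodes + 1)]
        return self.data[names].to_numpy(dtype=float)

    def with_channels(self, matrix: np.ndarray, which: str = "HbO2") -> "Recording":
        """Copy of the recording with one chromophore's channels replaced."""
        df = self.data.copy()
        for i in range(self.n_optodes):
            df[f"O{i + 1}_{which}"] = matrix[:, i]
        return Recording(data=df, fs=self.fs, subject_id=self.subject_id)


def write_recording(recording: Recording, path: str | Path) -> None:
    recording.data.to_csv(path, index=False)


def read_recording(
    path: str | Path,
    fs: float | None = None,
    subject_id: str | None = None,
) -> Recording:
    """Read a recording CSV, inferring fs from time_s unless given."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing time_s column")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            line = (int(np.nonzero(bad.to_numpy())[0][0]) + 2) if bad.any() else "?"
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at line {line}"
            )
    if fs is None:
        t = df["time_s"].to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError(f"{path}: need >= 2 samples to infer fs")
        fs = 1.0 / (t[1] - t[0])
    return Recording(data=df, fs=float(fs), subject_id=subject_id)


_EVENT_COLUMNS = ("onset", "duration", "condition")


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    """Read and validate an events TSV; returns the table sorted by onset."""
    ev = pd.read_csv(path, sep="\t")
    missing = [c for c in _EVENT_COLUMNS if c not in ev.columns]
    if missing:
        raise ValueError(f"{path}: missing event column(s) {missing}")
    extra = [c for c in ev.columns if c not in _EVENT_COLUMNS + ("subject_id",)]
    if extra:
        log.warning("%s: ignoring unknown event column(s) %s", path, extra)
    if (ev["onset"] < 0).any():
        line = int(ev.index[ev["onset"] < 0][0]) + 2
        raise ValueError(f"{path}: negative onset at line {line}")
    if (ev["duration"] <= 0).any():
        line = int(ev.index[ev["duration"] <= 0][0]) + 2
        raise ValueError(f"{path}: non-positive duration at line {line}")
    by = ["subject_id", "onset"] if "subject_id" in ev.columns else ["onset"]
    ev = ev.sort_values(by).reset_index(drop=True)
    grouped = ev.groupby("subject_id")["onset"] if "subject_id" in ev.columns \
        else ev["onset"]
    if "subject_id" in ev.columns:
        dup = grouped.apply(lambda s: s.duplicated().any()).any()
    else:
        dup = ev["onset"].duplicated().any()
    if dup:
        raise ValueError(f"{path}: duplicate onsets within a subject")
    return ev


def write_ground_truth(truth: dict, path: str | Path) -> None:
    """Serialize a simulator ground-truth record to JSON."""

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"cannot serialize {type(o).__name__}")

    Path(path).write_text(json.dumps(truth, indent=1, default=_default))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
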