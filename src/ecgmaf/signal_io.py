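"""Reading and writing synchronized ECG + acceleration records.

Handles the MHEALTH plain-text log dialect (one sample per line,
whitespace-separated floats, integer activity label in the last column)
and a simple CSV dialect for filtered output and R-peak annotations.
No numerical processing happens here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SignalRecord",
    "QRSAnnotation",
    "read_mhealth",
    "read_csv",
    "write_csv",
    "read_annotation",
    "DEFAULT_COLUMN_MAP",
]

#: 1-based column numbers, matching the MHEALTH README convention:
#: chest acceleration occupies columns 1-3, chest ECG lead 1 column 4,
#: and the activity label the last column (``None`` means "last").
DEFAULT_COLUMN_MAP = {"acc_x": 1, "acc_y": 2, "acc_z": 3, "ecg": 4, "label": None}


@dataclass
class SignalRecord:
    """Synchronized single-lead ECG and triaxial acceleration samples.

    Parameters
    ----------
    ecg : ndarray
        ECG potential samples (arbitrary amplitude units).
    acc_x, acc_y, acc_z : ndarray
        Acceleration samples (m/s²), same length as ``ecg``.
    fs : float
        Sampling rate in Hz (default 50).
    labels : ndarray or None
        Optional per-sample integer activity code.
    t0 : float
        Start offset in seconds.
    """

    ecg: np.ndarray
    acc_x: np.ndarray
    acc_y: np.ndarray
    acc_z: np.ndarray
    fs: float = 50.0
    labels: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.acc_x = np.asarray(self.acc_x, dtype=float)
        self.acc_y = np.asarray(self.acc_y, dtype=float)
        self.acc_z = np.asarray(self.acc_z, dtype=float)
        n = self.ecg.size
        if n < 1:
            raise ValueError("SignalRecord requires at least one sample")
        for name in ("acc_x", "acc_y", "acc_z"):
            if getattr(self, name).size != n:
                raise ValueError(f"channel {name} length != ecg length")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.size != n:
                raise ValueError("labels length != ecg length")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        for name in ("ecg", "acc_x", "acc_y", "acc_z"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in channel {name}")

    def __len__(self) -> int:
        return self.ecg.size

    @property
    def duration(self) -> float:
        return len(self) / self.fs

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(len(self)) / self.fs


@dataclass
class QRSAnnotation:
    """Detected R-peak sample indices with per-beat segment lengths."""

    r_peaks: np.ndarray
    per_beat_l: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.r_peaks = np.asarray(self.r_peaks, dtype=int)
        if self.r_peaks.size and np.any(np.diff(self.r_peaks) <= 0):
            raise ValueError("r_peaks must be strictly increasing")
        if self.per_beat_l is None:
            self.per_beat_l = np.zeros(self.r_peaks.size, dtype=int)
        else:
            self.per_beat_l = np.asarray(self.per_beat_l, dtype=int)
            if self.per_beat_l.size != self.r_peaks.size:
                raise ValueError("per_beat_l length != r_peaks length")

    def __len__(self) -> int:
        return self.r_peaks.size


def read_mhealth(
    path: str | os.PathLike,
    column_map: dict | None = None,
    fs: float = 50.0,
    nan_policy: str = "reject",
) -> SignalRecord:
    """Parse an MHEALTH-style whitespace-separated log file.

    ``column_map`` uses 1-based column numbers (the MHEALTH README numbers
    columns from 1); ``label: None`` maps the label to the last column.
    ``nan_policy`` is either ``"reject"`` (default) or ``"interpolate"``
    (linear interpolation over non-finite samples).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    rows: list[list[float]] = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                vals = [float(tok) for tok in line.split()]
            except ValueError as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from None
            if ncols is None:
                ncols = len(vals)
            elif len(vals) != ncols:
                raise ValueError(
                    f"{path}: line {lineno} has {len(vals)} columns, expected {ncols}"
                )
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: empty file")
    data = np.asarray(rows, dtype=float)

    def col(key: str, required: bool = True) -> np.ndarray | None:
        idx = cmap.get(key)
        if idx is None:
            if key == "label":
                return data[:, -1]
            if required:
                raise KeyError(f"column_map does not name the {key!r} column")
            return None
        if not 1 <= idx <= data.shape[1]:
            raise KeyError(f"column_map[{key!r}]={idx} outside 1..{data.shape[1]}")
        return data[:, idx - 1]

    channels = {k: col(k) for k in ("ecg", "acc_x", "acc_y", "acc_z")}
    labels = col("label", required=False)
    if labels is not None:
        labels = labels.astype(int)

    if nan_policy == "interpolate":
        for k, v in channels.items():
            bad = ~np.isfinite(v)
            if bad.any():
                good = ~bad
                if not good.any():
                    raise ValueError(f"{path}: channel {k} has no finite samples")
                v[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(good), v[good])
    return SignalRecord(
        ecg=channels["ecg"],
        acc_x=channels["acc_x"],
        acc_y=channels["acc_y"],
        acc_z=channels["acc_z"],
        fs=fs,
        labels=labels,
    )


def write_csv(
    record: SignalRecord,
    ann: QRSAnnotation | None,
    path: str | os.PathLike,
) -> None:
    """Write a record (and optionally its annotation) as CSV.

    The signal goes to ``path`` with header ``t,ecg,acc_x,acc_y,acc_z[,label]``;
    the annotation, when given, to ``path`` with suffix ``.ann.csv`` appended
    (header ``r_peak_index,l_samples``).
    """
    cols = {
        "t": record.t,
        "ecg": record.ecg,
        "acc_x": record.acc_x,
        "acc_y": record.acc_y,
        "acc_z": record.acc_z,
    }
    if record.labels is not None:
        cols["label"] = record.labels
    pd.DataFrame(cols).to_csv(path, index=False)
    if ann is not None:
        pd.DataFrame(
            {"r_peak_index": ann.r_peaks, "l_samples": ann.per_beat_l}
        ).to_csv(str(path) + ".ann.csv", index=False)


def read_csv(path: str | os.PathLike, fs: float | None = None) -> SignalRecord:
    """Read back a CSV written by :func:`write_csv`."""
    df = pd.read_csv(path)
    t = df["t"].to_numpy()
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 50.0
    return SignalRecord(
        ecg=df["ecg"].to_numpy(),
        acc_x=df["acc_x"].to_numpy(),
        acc_y=df["acc_y"].to_numpy(),
        acc_z=df["acc_z"].to_numpy(),
        fs=round(fs, 9),
        labels=df["label"].to_numpy(dtype=int) if "label" in df.columns else None,
        t0=float(t[0]) if len(t) else 0.0,
    )


def read_annotation(path: str | os.PathLike) -> QRSAnnotation:
    df = pd.read_csv(path)
    return QRSAnnotation(
        r_peaks=df["r_peak_index"].to_numpy(dtype=int),
        per_beat_l=df["l_samples"].to_numpy(dtype=int),
    )
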