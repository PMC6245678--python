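"""R-peak annotation and P-QRS-T segmentation into the segment buffer.

QRS detection is the classic Pan-Tompkins chain (bandpass, derivative,
squaring, moving-window integration, dual adaptive thresholds with
refractory period and search-back).  Detected beats are cut into
R-centered windows whose length follows the RR interval, clamped to
physiologic bounds (0.14 s at 300 bpm up to 1.2 s at 50 bpm), and stored
in a bounded buffer of the most recent cycles.  The buffer depth adapts
online from the column-wise interquartile range of the stored cycles and
from the Kullback-Leibler divergence between recent stretches of the
signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signal_io import QRSAnnotation

__all__ = [
    "SegmentBuffer",
    "BufferPolicy",
    "pan_tompkins",
    "estimate_l",
    "segment",
    "relative_entropy",
    "adapt_w",
    "default_l_bounds",
]

log = logging.getLogger(__name__)

#: Physiologic P-QRS-T duration bounds (seconds): 300 bpm down to 50 bpm.
L_MIN_S = 0.14
L_MAX_S = 1.2


def default_l_bounds(fs: float) -> tuple[int, int]:
    return int(round(L_MIN_S * fs)), int(round(L_MAX_S * fs))


# ---------------------------------------------------------------------------
# Pan-Tompkins QRS detection
# ---------------------------------------------------------------------------

def pan_tompkins(ecg: np.ndarray, fs: float) -> QRSAnnotation:
    """Pan-Tompkins R-peak detector.

    Stages: 5-15 Hz bandpass, five-point derivative, squaring, 150 ms
    moving-window integration, dual adaptive thresholds with a 200 ms
    refractory period and RR-based search-back.  Detections are localized
    to the raw-signal maximum within ±60 ms.
    """
    x = np.asarray(ecg, dtype=float)
    if fs < 40:
        raise ValueError("pan_tompkins requires fs >= 40 Hz")
    if x.size < 2 * fs:
        raise ValueError("signal shorter than 2 s")
    if not np.any(x):
        return QRSAnnotation(r_peaks=np.array([], dtype=int), per_beat_l=np.array([], dtype=int))

    high = min(15.0, 0.45 * fs)
    sos = sps.butter(2, [5.0, high], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)

    # Five-point derivative, centered so detections carry no kernel delay.
    kernel = np.array([1, 2, 0, -2, -1]) * (fs / 8.0)
    deriv = np.convolve(bp, kernel, mode="same")
    sq = deriv**2
    win = max(int(round(0.150 * fs)), 1)
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(0.2 * fs))
    peaks, _ = sps.find_peaks(mwi, distance=max(refractory, 1))
    if peaks.size == 0:
        return QRSAnnotation(r_peaks=np.array([], dtype=int), per_beat_l=np.array([], dtype=int))

    # Adaptive thresholding over the integrated signal.
    init = mwi[: int(2 * fs)]
    spki = float(np.max(init)) * 0.6
    npki = float(np.mean(init)) * 0.5
    thr1 = npki + 0.25 * (spki - npki)
    qrs: list[int] = []
    rr_hist: list[float] = []
    last_qrs_peakidx = None

    def accept(p: int, peak_val: float) -> None:
        nonlocal spki, thr1
        spki = 0.125 * peak_val + 0.875 * spki
        thr1 = npki + 0.25 * (spki - npki)
        qrs.append(p)

    i = 0
    while i < peaks.size:
        p = peaks[i]
        val = mwi[p]
        if val > thr1:
            if last_qrs_peakidx is not None:
                rr_hist.append(p - last_qrs_peakidx)
                if len(rr_hist) > 8:
                    rr_hist.pop(0)
            last_qrs_peakidx = p
            accept(p, val)
        else:
            npki = 0.125 * val + 0.875 * npki
            thr1 = npki + 0.25 * (spki - npki)
            # Search-back: long gap since the last beat -> re-examine this
            # stretch at half threshold.
            if rr_hist and last_qrs_peakidx is not None:
                rr_avg = float(np.mean(rr_hist))
                if p - last_qrs_peakidx > 1.66 * rr_avg and val > 0.5 * thr1:
                    rr_hist.append(p - last_qrs_peakidx)
                    if len(rr_hist) > 8:
                        rr_hist.pop(0)
                    last_qrs_peakidx = p
                    accept(p, val)
        i += 1

    # Localize each detection at the raw-signal maximum within ±60 ms.
    half = int(round(0.06 * fs))
    r_peaks = []
    for p in qrs:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        r_peaks.append(lo + int(np.argmax(x[lo:hi])))
    r_peaks = np.unique(np.asarray(r_peaks, dtype=int))
    # Enforce the refractory period on the localized peaks.
    if r_peaks.size:
        keep = [int(r_peaks[0])]
        for r in r_peaks[1:]:
            if r - keep[-1] >= refractory:
                keep.append(int(r))
            elif x[r] > x[keep[-1]]:
                keep[-1] = int(r)
        r_peaks = np.asarray(keep, dtype=int)
    l_min, l_max = default_l_bounds(fs)
    per_l = estimate_l(r_peaks, fs, l_min, l_max)
    return QRSAnnotation(r_peaks=r_peaks, per_beat_l=per_l)


def estimate_l(
    r_peaks: np.ndarray,
    fs: float,
    l_min: int | None = None,
    l_max: int | None = None,
) -> np.ndarray:
    """Per-beat segment length from successive RR intervals.

    ``l_i = clamp(r_i - r_{i-1}, l_min, l_max)``; the first beat takes the
    first available RR.  With fewer than two peaks the nominal resting
    cycle (0.8 s, clamped) is used.
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    lo = l_min if l_min is not None else int(round(L_MIN_S * fs))
    hi = l_max if l_max is not None else int(round(L_MAX_S * fs))
    if r_peaks.size < 2:
        fallback = int(np.clip(round(0.8 * fs), lo, hi))
        return np.full(r_peaks.size, fallback, dtype=int)
    rr = np.diff(r_peaks)
    l = np.concatenate([rr[:1], rr])
    return np.clip(l, lo, hi).astype(int)


# ---------------------------------------------------------------------------
# Segment buffer
# ---------------------------------------------------------------------------

@dataclass
class SegmentBuffer:
    """Bounded FIFO of R-peak-aligned P-QRS-T segments (most recent last).

    Rows are stored rectangular at length ``l_max`` with the R peak of
    every beat on the same center column (``l_max // 2``), padded on both
    sides with the row's edge samples; ``per_row_l`` records the true
    segment lengths.  Aligning on R keeps each column a single cardiac
    phase even when the RR interval (and hence the segment length) varies
    from beat to beat.
    """

    w: int
    l_min: int
    l_max: int
    rows: list = field(default_factory=list)
    per_row_l: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.l_min > self.l_max:
            raise ValueError("l_min must not exceed l_max")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def r_col(self) -> int:
        """Center column on which every row's R peak is aligned."""
        return self.l_max // 2

    def push(self, row: np.ndarray, l: int | None = None) -> None:
        """Store a segment whose R peak sits at index ``len(row) // 2``."""
        row = np.asarray(row, dtype=float)[: self.l_max]
        pad_left = self.r_col - row.size // 2
        pad_right = self.l_max - row.size - pad_left
        aligned = np.concatenate(
            [np.full(pad_left, row[0]), row, np.full(pad_right, row[-1])]
        )
        self.rows.append(aligned)
        self.per_row_l.append(row.size)
        while len(self.rows) > self.w:
            self.rows.pop(0)
            self.per_row_l.pop(0)

    def set_depth(self, w: int) -> None:
        """Change the depth, evicting oldest rows when shrinking."""
        self.w = int(w)
        while len(self.rows) > self.w:
            self.rows.pop(0)
            self.per_row_l.pop(0)

    def matrix(self) -> np.ndarray:
        if not self.rows:
            return np.empty((0, self.l_max))
        return np.vstack(self.rows)

    def valid_span(self) -> tuple[int, int]:
        """Column range [lo, hi) where every row holds real samples."""
        if not self.rows:
            return 0, 0
        lo = 0
        hi = self.l_max
        for l in self.per_row_l:
            pad_left = self.r_col - l // 2
            lo = max(lo, pad_left)
            hi = min(hi, pad_left + l)
        return lo, hi

    @property
    def valid_cols(self) -> int:
        """Width of the fully-valid column range (the shortest stored beat)."""
        lo, hi = self.valid_span()
        return hi - lo


@dataclass
class BufferPolicy:
    """Buffer-depth adaptation thresholds.

    The depth grows when the stored cycles disagree (large column IQR) or
    the signal's short-term distribution is drifting (KL divergence above
    threshold) and decays back toward ``w_init`` otherwise.
    """

    w_init: int = 8
    w_max: int = 32
    iqr_high: float = 0.25
    kl_bins: int = 16
    kl_threshold: float = 0.1
    kl_window: int = 200  # samples per distribution window (4 s at 50 Hz)

    def __post_init__(self) -> None:
        if self.w_init > self.w_max:
            raise ValueError("w_init must not exceed w_max")
        if self.kl_bins < 2:
            raise ValueError("kl_bins must be >= 2")


def segment(ecg: np.ndarray, ann: QRSAnnotation) -> tuple[list[np.ndarray], list[int], list[int]]:
    """Cut R-centered windows ``[r - l//2, r + l - l//2)`` out of the signal.

    Returns (rows, lengths, beat indices kept).  Edge beats whose window
    would leave the signal are skipped (logged).
    """
    x = np.asarray(ecg, dtype=float)
    rows, lengths, kept = [], [], []
    for i, (r, l) in enumerate(zip(ann.r_peaks, ann.per_beat_l)):
        l = int(l)
        lo = r - l // 2
        hi = lo + l
        if lo < 0 or hi > x.size:
            log.debug("skipping edge beat %d at sample %d (window %d..%d)", i, r, lo, hi)
            continue
        rows.append(x[lo:hi].copy())
        lengths.append(l)
        kept.append(i)
    return rows, lengths, kept


def relative_entropy(p: np.ndarray, q: np.ndarray, eps: float = 1e-12) -> float:
    """Kullback-Leibler divergence d(p, q) = sum p log2(p/q), in bits.

    Histograms are normalized to probability vectors; zero cells of q are
    regularized by ``eps``.  Non-negative by Gibbs' inequality, zero iff
    p == q (up to regularization).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("histograms must be non-negative")
    sp, sq = p.sum(), q.sum()
    if sp == 0 or sq == 0:
        raise ValueError("all-zero histogram")
    p = p / sp
    q = np.maximum(q / sq, eps)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / q[nz])))


def adapt_w(buffer: SegmentBuffer, policy: BufferPolicy, recent_ecg: np.ndarray) -> int:
    """Adapt the buffer depth from column IQR and signal KL divergence.

    Grow by 2 (capped at ``w_max``) when either the relative column IQR
    exceeds ``iqr_high`` or the divergence between the two most recent
    ``kl_window``-sample stretches exceeds ``kl_threshold``; otherwise
    decay by 1 toward ``w_init``.  Returns the new depth (eviction applied).
    """
    if len(buffer) < 2:
        raise ValueError("adapt_w needs a buffer with at least 2 rows")
    lo_col, hi_col = buffer.valid_span()
    mat = buffer.matrix()[:, lo_col:hi_col]
    iqr = np.subtract(*np.percentile(mat, [75, 25], axis=0))
    r_amp = float(np.median(np.max(np.abs(mat), axis=1)))
    rel_iqr = float(np.median(iqr)) / r_amp if r_amp > 0 else 0.0

    recent_ecg = np.asarray(recent_ecg, dtype=float)
    d = 0.0
    if recent_ecg.size >= 2 * policy.kl_window:
        w1 = recent_ecg[-2 * policy.kl_window : -policy.kl_window]
        w2 = recent_ecg[-policy.kl_window :]
        lo = min(w1.min(), w2.min())
        hi = max(w1.max(), w2.max())
        if hi > lo:
            edges = np.linspace(lo, hi, policy.kl_bins + 1)
            h1, _ = np.histogram(w1, bins=edges)
            h2, _ = np.histogram(w2, bins=edges)
            d = relative_entropy(h2, h1)

    if d > policy.kl_threshold or rel_iqr > policy.iqr_high:
        new_w = min(buffer.w + 2, policy.w_max)
    else:
        new_w = max(buffer.w - 1, policy.w_init)
    buffer.set_depth(new_w)
    return new_w
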