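"""Stage-2 segment-domain Hampel filtering (HFBE / RHFBE).

Each incoming P-QRS-T segment is compared column-wise against the buffer
of its predecessors: a sample is replaced by the column median only when
it falls outside median ± m × MAD (MAD scaled by 1.4826 to estimate sigma
for Gaussian data).  The non-recursive variant (HFBE) then stores the raw
segment in the buffer; the recursive variant (RHFBE) stores the filtered
segment, so later estimates condition on cleaned history.  When every
incoming cycle is corrupted the column medians themselves drift into the
noise and the filter degrades — the documented failure mode under
sustained contamination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .signal_io import QRSAnnotation
from .segmentation import SegmentBuffer, default_l_bounds, segment

__all__ = [
    "HampelParams",
    "hampel_params",
    "hampel_apply",
    "hfbe",
    "rhfbe",
    "reconstruct",
    "run_segment_filter",
]

log = logging.getLogger(__name__)

MAD_SCALE = 1.4826
MIN_ROWS = 3


@dataclass
class HampelParams:
    """Per-column robust statistics of the buffer.

    ``hub = median + m*mad`` and ``hlb = median - m*mad`` exactly; a
    constant column has mad 0, making any deviation an outlier.
    ``r_offset`` locates the first column relative to the R peak (0 for
    a buffer of equal-length rows, where columns and segment samples
    coincide one-to-one).
    """

    median_col: np.ndarray
    mad_col: np.ndarray
    hub: np.ndarray
    hlb: np.ndarray
    m: float
    r_offset: int = 0

    def __len__(self) -> int:
        return self.median_col.size


def hampel_params(buffer: SegmentBuffer, m: float = 3.0) -> HampelParams:
    """Column medians, scaled MADs and bounds over the buffer rows.

    Statistics are restricted to the columns where every row holds real
    (unpadded) samples, i.e. the span of the shortest stored beat around
    the shared R column.
    """
    if len(buffer) < MIN_ROWS:
        raise ValueError(f"hampel_params needs >= {MIN_ROWS} buffer rows")
    lo, hi = buffer.valid_span()
    mat = buffer.matrix()[:, lo:hi]
    med = np.median(mat, axis=0)
    mad = MAD_SCALE * np.median(np.abs(mat - med), axis=0)
    return HampelParams(
        median_col=med, mad_col=mad, hub=med + m * mad, hlb=med - m * mad,
        m=m, r_offset=lo - buffer.r_col,
    )


def hampel_apply(
    seg: np.ndarray, params: HampelParams, r_index: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional median replacement against the buffer statistics.

    Samples outside ``[hlb, hub]`` are replaced by the column median.
    ``r_index`` is the segment's R-peak sample (default ``len(seg) // 2``);
    parameter column ``i`` addresses segment sample
    ``r_index + params.r_offset + i``.  Samples outside the parameter span
    pass through.  Returns (filtered segment, outlier mask).
    """
    seg = np.asarray(seg, dtype=float)
    k = len(params)
    if seg.size < k:
        raise ValueError("segment shorter than the Hampel parameter vector")
    if r_index is None:
        r_index = seg.size // 2
    start = r_index + params.r_offset
    p_lo = max(0, -start)
    s_lo = max(0, start)
    width = min(k - p_lo, seg.size - s_lo)
    out = seg.copy()
    mask = np.zeros(seg.size, dtype=bool)
    if width > 0:
        window = seg[s_lo : s_lo + width]
        bad = (window < params.hlb[p_lo : p_lo + width]) | (
            window > params.hub[p_lo : p_lo + width]
        )
        out[s_lo : s_lo + width][bad] = params.median_col[p_lo : p_lo + width][bad]
        mask[s_lo : s_lo + width] = bad
    return out, mask


def _fit_params(buffer: SegmentBuffer, m: float, seg_len: int) -> HampelParams:
    # Restrict the parameter span to the incoming segment's own window
    # (offsets relative to its R peak at seg_len // 2).
    p = hampel_params(buffer, m)
    lo_off = max(p.r_offset, -(seg_len // 2))
    hi_off = min(p.r_offset + len(p), seg_len - seg_len // 2)
    i0 = lo_off - p.r_offset
    i1 = hi_off - p.r_offset
    if i0 == 0 and i1 == len(p):
        return p
    return HampelParams(
        median_col=p.median_col[i0:i1], mad_col=p.mad_col[i0:i1],
        hub=p.hub[i0:i1], hlb=p.hlb[i0:i1], m=p.m, r_offset=lo_off,
    )


def hfbe(buffer: SegmentBuffer, new_segment: np.ndarray, m: float = 3.0, l: int | None = None) -> np.ndarray:
    """Hampel-filter-based estimation: filter, then store the RAW segment."""
    new_segment = np.asarray(new_segment, dtype=float)
    params = _fit_params(buffer, m, new_segment.size)
    filtered, _ = hampel_apply(new_segment, params)
    buffer.push(new_segment, l if l is not None else new_segment.size)
    return filtered


def rhfbe(buffer: SegmentBuffer, new_segment: np.ndarray, m: float = 3.0, l: int | None = None) -> np.ndarray:
    """Recursive variant: the FILTERED segment replaces the raw row."""
    new_segment = np.asarray(new_segment, dtype=float)
    params = _fit_params(buffer, m, new_segment.size)
    filtered, _ = hampel_apply(new_segment, params)
    buffer.push(filtered, l if l is not None else new_segment.size)
    return filtered


def reconstruct(
    ecg: np.ndarray,
    ann: QRSAnnotation,
    filtered_segments: dict[int, np.ndarray],
) -> np.ndarray:
    """Stitch filtered segments back over the stage-1 signal.

    ``filtered_segments`` maps beat index -> filtered (unpadded) segment.
    Each segment overwrites its window ``[r - l//2, r + l - l//2)``;
    overlaps resolve in favor of the later beat.
    """
    out = np.asarray(ecg, dtype=float).copy()
    for i in sorted(filtered_segments):
        r = int(ann.r_peaks[i])
        seg = filtered_segments[i]
        l = seg.size
        lo = r - l // 2
        hi = lo + l
        if lo < 0 or hi > out.size:
            continue
        out[lo:hi] = seg
    return out


def run_segment_filter(
    ecg: np.ndarray,
    ann: QRSAnnotation,
    fs: float,
    w: int = 8,
    m: float = 3.0,
    recursive: bool = True,
) -> np.ndarray:
    """Full stage 2 over a signal: segment, Hampel-filter, reconstruct.

    Beats arriving before the buffer holds 3 rows pass through unfiltered
    (cold start, logged at debug level).
    """
    l_min, l_max = default_l_bounds(fs)
    if not len(ann):
        return np.asarray(ecg, dtype=float).copy()
    rows, lengths, kept = segment(ecg, ann)
    buffer = SegmentBuffer(w=w, l_min=l_min, l_max=l_max)
    filtered: dict[int, np.ndarray] = {}
    for row, l, beat in zip(rows, lengths, kept):
        if len(buffer) < MIN_ROWS:
            log.debug("cold start: beat %d passes through", beat)
            buffer.push(row, l)
            continue
        if recursive:
            filtered[beat] = rhfbe(buffer, row, m, l)
        else:
            filtered[beat] = hfbe(buffer, row, m, l)
    return reconstruct(ecg, ann, filtered)
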