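"""Evaluation quantities: power ratio, QRS detection scores, HBR error,
and the synthetic artefact-removal percentage.

The power ratio (mean-square power before / after) is ≈ 1 for a filter
that passes the signal through, > 1 when energy is removed.  Detection
scoring matches detected against reference R-peaks one-to-one within a
time tolerance (±75 ms by default).  The artefact-removal percentage
replaces expert labelling with the synthetic ground-truth corrupted-beat
mask and an RMSE-to-clean-template criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DetectionScore",
    "power_ratio",
    "match_detections",
    "heartbeat_rate_error",
    "rmse_per_beat",
    "corrupted_beats_by_rmse",
    "rmse_threshold",
    "artefact_removal_percentage",
]


@dataclass
class DetectionScore:
    """QRS detection counts and derived percentages (sensitivity SN,
    positive predictivity PP, harmonic-mean F-measure FM)."""

    tp: int
    fp: int
    fn: int
    sn: float
    pp: float
    fm: float
    degenerate: bool = False


def power_ratio(before: np.ndarray, after: np.ndarray) -> float:
    """Mean-square power of the input over that of the filtered output."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size == 0 or before.size != after.size:
        raise ValueError("series must be non-empty and of equal length")
    p_after = float(np.mean(after**2))
    if p_after == 0.0:
        raise ZeroDivisionError("output signal has zero power")
    return float(np.mean(before**2)) / p_after


def match_detections(
    detected: np.ndarray,
    truth: np.ndarray,
    fs: float,
    tol_s: float = 0.075,
) -> DetectionScore:
    """Greedy one-to-one matching of detections to reference beats.

    A detection within ``tol_s`` of an unmatched reference beat is a true
    positive; leftovers are false positives / negatives.  Zero-denominator
    rates are reported as 0 with the ``degenerate`` flag set.
    """
    detected = np.asarray(detected, dtype=int)
    truth = np.asarray(truth, dtype=int)
    tol = tol_s * fs
    used = np.zeros(truth.size, dtype=bool)
    tp = 0
    j = 0
    for d in detected:
        # Advance to the nearest candidate window.
        while j < truth.size and truth[j] < d - tol:
            j += 1
        best, best_dist = -1, tol + 1
        for k in range(j, truth.size):
            if truth[k] > d + tol:
                break
            if not used[k] and abs(truth[k] - d) < best_dist:
                best, best_dist = k, abs(truth[k] - d)
        if best >= 0:
            used[best] = True
            tp += 1
    fp = detected.size - tp
    fn = truth.size - tp
    degenerate = False
    if tp + fn > 0:
        sn = 100.0 * tp / (tp + fn)
    else:
        sn, degenerate = 0.0, True
    if tp + fp > 0:
        pp = 100.0 * tp / (tp + fp)
    else:
        pp, degenerate = 0.0, True
    fm = 2 * sn * pp / (sn + pp) if (sn + pp) > 0 else 0.0
    if (sn + pp) == 0:
        degenerate = True
    return DetectionScore(tp=tp, fp=fp, fn=fn, sn=sn, pp=pp, fm=fm, degenerate=degenerate)


def heartbeat_rate_error(
    detected: np.ndarray, truth_count: int, duration_s: float
) -> tuple[float, float]:
    """Estimated heartbeat rate (bpm) and its error against the reference.

    ``hbr_hat = 60 * n_detected / duration``; the error is
    ``hbr_hat - 60 * truth_count / duration``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = np.asarray(detected).size
    hbr_hat = 60.0 * n / duration_s
    return hbr_hat, hbr_hat - 60.0 * truth_count / duration_s


def rmse_per_beat(
    test_ecg: np.ndarray,
    clean_ecg: np.ndarray,
    r_peaks: np.ndarray,
    per_beat_l: np.ndarray,
) -> np.ndarray:
    """Per-beat RMSE between a signal and the clean reference over the
    R-centered window of each beat (NaN for edge beats)."""
    x = np.asarray(test_ecg, dtype=float)
    ref = np.asarray(clean_ecg, dtype=float)
    out = np.full(np.asarray(r_peaks).size, np.nan)
    for i, (r, l) in enumerate(zip(r_peaks, per_beat_l)):
        lo = int(r) - int(l) // 2
        hi = lo + int(l)
        if lo < 0 or hi > x.size:
            continue
        out[i] = np.sqrt(np.mean((x[lo:hi] - ref[lo:hi]) ** 2))
    return out


def corrupted_beats_by_rmse(
    test_ecg: np.ndarray,
    clean_ecg: np.ndarray,
    r_peaks: np.ndarray,
    per_beat_l: np.ndarray,
    threshold: float,
) -> np.ndarray:
    """Boolean mask of beats whose RMSE to the clean template exceeds
    ``threshold`` (edge beats with undefined RMSE count as uncorrupted)."""
    rmse = rmse_per_beat(test_ecg, clean_ecg, r_peaks, per_beat_l)
    return np.nan_to_num(rmse, nan=0.0) > threshold


def rmse_threshold(clean_beat_rmse: np.ndarray, factor: float = 3.0, q: float = 95.0) -> float:
    """Corruption threshold: ``factor`` times the ``q``-th percentile of
    the clean-beat RMSE distribution."""
    vals = np.asarray(clean_beat_rmse, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite clean-beat RMSE values")
    return factor * float(np.percentile(vals, q))


def artefact_removal_percentage(
    mask_before: np.ndarray, mask_after: np.ndarray
) -> float:
    """Percentage of corrupted beats removed by the filter.

    ``100 * (n_before - n_after) / n_before``; negative when the filter
    corrupted additional beats.  Undefined (raises) when nothing was
    corrupted before.
    """
    mb = np.asarray(mask_before, dtype=bool)
    ma = np.asarray(mask_after, dtype=bool)
    if mb.size != ma.size:
        raise ValueError("masks must have equal length")
    n_before = int(mb.sum())
    if n_before == 0:
        raise ValueError("no corrupted beats before filtering; percentage undefined")
    n_after = int(ma.sum())
    return 100.0 * (n_before - n_after) / n_before
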