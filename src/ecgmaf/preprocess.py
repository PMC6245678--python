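"""Stage-0 conditioning: bandpass, power-line notch, baseline-wander canceller.

The bandpass is a zero-phase Butterworth (nominally 0.05-130 Hz; the upper
edge is clipped below Nyquist, which matters at the 50 Hz rates typical of
wearable recorders).  The adaptive baseline-wander reduction filter (ABWRF)
is a one-weight LMS canceller whose reference input is the constant 1, i.e.
an adaptive DC/drift tracker subtracted from the signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["PreprocessConfig", "bandpass", "notch", "abwrf", "preprocess_chain"]

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    band_low: float = 0.05
    band_high: float = 130.0
    butter_order: int = 4
    notch_freq: float = 50.0
    notch_q: float = 30.0
    abwrf_mu: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("require 0 < band_low < band_high")


def bandpass(ecg: np.ndarray, fs: float, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Zero-phase Butterworth bandpass; high edge clipped to 0.45*fs."""
    cfg = cfg or PreprocessConfig()
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size <= 3 * cfg.butter_order:
        raise ValueError("signal too short for the bandpass filter")
    high = min(cfg.band_high, 0.45 * fs)
    if high <= cfg.band_low:
        raise ValueError("bandpass edges collapse at this sampling rate")
    sos = sps.butter(cfg.butter_order, [cfg.band_low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, ecg)


def notch(ecg: np.ndarray, fs: float, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Power-line notch; a pass-through (with a warning) when the mains
    frequency is at or above Nyquist, as at 50 Hz sampling."""
    cfg = cfg or PreprocessConfig()
    ecg = np.asarray(ecg, dtype=float)
    if cfg.notch_freq >= fs / 2:
        log.warning(
            "notch at %.0f Hz impossible at fs=%.0f Hz (Nyquist %.1f); passing through",
            cfg.notch_freq, fs, fs / 2,
        )
        return ecg.copy()
    b, a = sps.iirnotch(cfg.notch_freq, cfg.notch_q, fs=fs)
    return sps.filtfilt(b, a, ecg)


def abwrf(ecg: np.ndarray, mu: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """One-weight LMS baseline canceller with constant reference 1.

    Recursion: ``eps_k = x_k - w_k``; ``w_{k+1} = w_k + 2 mu eps_k`` with
    ``w_0 = 0``.  The weight is an exponential running baseline; the
    returned first array is the detrended signal ``eps``, the second the
    weight trace.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    x = np.asarray(ecg, dtype=float)
    n = x.size
    # w_{k+1} = (1-2mu) w_k + 2mu x_k  ->  first-order IIR, vectorized.
    w = np.zeros(n)
    if n > 1:
        w[1:] = sps.lfilter([2 * mu], [1.0, -(1.0 - 2 * mu)], x)[:-1]
    eps = x - w
    limit = 1e6 * max(np.max(np.abs(x)), 1e-30)
    if np.max(np.abs(w)) > limit or not np.all(np.isfinite(w)):
        raise FloatingPointError("ABWRF diverged; use a smaller mu")
    return eps, w


def preprocess_chain(
    ecg: np.ndarray, fs: float, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Bandpass -> notch -> ABWRF, returning the conditioned ECG."""
    cfg = cfg or PreprocessConfig()
    out = bandpass(ecg, fs, cfg)
    out = notch(out, fs, cfg)
    out, _ = abwrf(out, cfg.abwrf_mu)
    return out
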