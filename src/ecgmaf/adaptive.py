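"""Stage-1 adaptive noise cancelling: conventional AF and weighted WAF.

Both filters are normalized LMS cancellers whose reference is the signal
vector magnitude (SVM) of the triaxial accelerometer.  The weighted
variant (WAF) scales the noise estimate by the magnitude of the running
Pearson correlation between reference and ECG, so an uncorrelated
reference leaves the ECG essentially untouched instead of injecting
reference-shaped noise into it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FilterState",
    "AdaptiveResult",
    "svm_reference",
    "running_pearson",
    "lms_af",
    "lms_waf",
]


@dataclass
class FilterState:
    """LMS hyperparameters and tap weights.

    ``beta`` is the normalized step size (stable in (0, 2)); the default
    0.05 gives an adaptation time constant of n/beta = 160 samples (about
    four cardiac cycles at 70 bpm / 50 Hz), so the canceller adapts across
    beats rather than chasing morphology within one.  ``c`` regularizes
    the step when the reference is near zero; ``rho_window`` is the
    trailing-window length (samples) of the running correlation used by
    the WAF (default 2 s at 50 Hz).
    """

    n: int = 8
    beta: float = 0.05
    c: float = 1e-3
    rho_window: int = 100
    W: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0 <= self.beta < 2:
            raise ValueError("beta must lie in [0, 2)")
        if self.c <= 0:
            raise ValueError("c must be positive")
        if self.W is None:
            self.W = np.zeros(self.n)
        else:
            self.W = np.asarray(self.W, dtype=float)
            if self.W.size != self.n:
                raise ValueError("len(W) must equal n")


@dataclass
class AdaptiveResult:
    """Output of an adaptive run: ``filtered + noise_estimate == primary``."""

    filtered: np.ndarray
    noise_estimate: np.ndarray
    rho_trace: np.ndarray
    weight_trace: np.ndarray | None = None


def svm_reference(acc_x: np.ndarray, acc_y: np.ndarray, acc_z: np.ndarray) -> np.ndarray:
    """Signal vector magnitude sqrt(x^2 + y^2 + z^2) of the acceleration."""
    acc_x, acc_y, acc_z = (np.asarray(a, dtype=float) for a in (acc_x, acc_y, acc_z))
    if not acc_x.size == acc_y.size == acc_z.size:
        raise ValueError("acceleration channels must have equal length")
    return np.sqrt(acc_x**2 + acc_y**2 + acc_z**2)


def running_pearson(primary: np.ndarray, reference: np.ndarray, window: int = 100) -> np.ndarray:
    """Per-sample Pearson correlation over a trailing window.

    The window at sample k covers the last ``window`` samples (shorter at
    the start of the signal); zero-variance windows yield 0 by convention.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    x = np.asarray(reference, dtype=float)
    y = np.asarray(primary, dtype=float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    n = x.size
    # Trailing-window sums via cumulative sums.
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])
    k = np.arange(1, n + 1)
    m = np.minimum(k, window).astype(float)
    lo = k - m.astype(int)
    sx = cx[k] - cx[lo]
    sy = cy[k] - cy[lo]
    sxx = cxx[k] - cxx[lo]
    syy = cyy[k] - cyy[lo]
    sxy = cxy[k] - cxy[lo]
    cov = sxy - sx * sy / m
    vx = sxx - sx * sx / m
    vy = syy - sy * sy / m
    # Guard tiny/negative variances from float cancellation.
    scale_x = np.max(np.abs(x)) if n else 1.0
    scale_y = np.max(np.abs(y)) if n else 1.0
    tol_x = 1e-12 * max(scale_x, 1.0) ** 2
    tol_y = 1e-12 * max(scale_y, 1.0) ** 2
    ok = (vx > tol_x) & (vy > tol_y) & (m >= 2)
    rho = np.zeros(n)
    rho[ok] = cov[ok] / np.sqrt(vx[ok] * vy[ok])
    return np.clip(rho, -1.0, 1.0)


def _lms(
    primary: np.ndarray,
    reference: np.ndarray,
    state: FilterState,
    gain: np.ndarray | None,
    keep_weights: bool,
) -> AdaptiveResult:
    x = np.asarray(reference, dtype=float)
    d = np.asarray(primary, dtype=float)
    if x.size != d.size:
        raise ValueError("primary and reference must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(d))):
        raise ValueError("non-finite values in input")
    n_taps = state.n
    if d.size < n_taps:
        raise ValueError("signal shorter than the filter order")
    W = state.W.astype(float).copy()
    # X_r(k) = [x_k, x_{k-1}, ..., x_{k-n+1}], zero-padded before the start.
    xpad = np.concatenate([np.zeros(n_taps - 1), x])
    noise = np.empty(d.size)
    eps = np.empty(d.size)
    wtrace = np.empty((d.size, n_taps)) if keep_weights else None
    beta, c = state.beta, state.c
    for k in range(d.size):
        X = xpad[k : k + n_taps][::-1]
        y = W @ X
        g = 1.0 if gain is None else gain[k]
        n_hat = g * y
        e = d[k] - n_hat
        # Normalized LMS step (the update's conventional factor 2 is
        # absorbed into mu so that beta in (0,2) is the stability range).
        mu = beta / (X @ X + c)
        W = W + mu * e * X
        noise[k] = n_hat
        eps[k] = e
        if keep_weights:
            wtrace[k] = W
    state.W = W
    rho = np.ones(d.size) if gain is None else np.asarray(gain, dtype=float)
    return AdaptiveResult(filtered=eps, noise_estimate=noise, rho_trace=rho, weight_trace=wtrace)


def lms_af(
    primary: np.ndarray,
    reference: np.ndarray,
    state: FilterState | None = None,
    keep_weights: bool = False,
) -> AdaptiveResult:
    """Conventional normalized-LMS adaptive noise canceller.

    At each sample the noise estimate is ``W . X_r`` over the last ``n``
    reference samples, the emitted signal is ``primary - noise``, and the
    weights follow the normalized-LMS update driven by that error.
    """
    state = state or FilterState()
    return _lms(primary, reference, state, gain=None, keep_weights=keep_weights)


def lms_waf(
    primary: np.ndarray,
    reference: np.ndarray,
    state: FilterState | None = None,
    keep_weights: bool = False,
) -> AdaptiveResult:
    """Correlation-weighted adaptive noise canceller.

    Identical recursion to :func:`lms_af` except that the noise estimate
    is scaled by ``|rho_k|`` (running Pearson correlation of reference and
    primary, clipped to [0, 1]); the weight update uses the same emitted
    error.  Anti-correlation still counts as correlation for cancellation.
    """
    state = state or FilterState()
    rho = running_pearson(primary, reference, state.rho_window)
    gain = np.clip(np.abs(rho), 0.0, 1.0)
    res = _lms(primary, reference, state, gain=gain, keep_weights=keep_weights)
    res.rho_trace = rho
    return res
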