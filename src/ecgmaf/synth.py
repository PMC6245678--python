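"""Seeded synthetic ECG / motion-artefact / acceleration generator.

The clean ECG is a concatenation of P-QRS-T cycles, each a sum of five
Gaussian bumps with fixed relative timings and amplitudes (R dominant at
amplitude 1.0), which gives exact ground-truth fiducials.  Motion
artefacts are a seeded mixture of an accelerometer-derived component
(controlled by the mixing coefficient ``kappa``) and reference-independent
raised-cosine baseline transients that hit a controllable fraction of
cardiac cycles.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .signal_io import QRSAnnotation, SignalRecord

__all__ = [
    "SynthConfig",
    "generate_clean_ecg",
    "generate_acceleration",
    "generate_artefact",
    "contaminate",
    "make_contaminated_record",
]

# Gaussian template: (offset from R in seconds, amplitude rel. R, sigma s).
# Conventional textbook morphology; R amplitude fixed at 1.0.
_WAVES = (
    ("P", -0.20, 0.15, 0.035),
    ("Q", -0.05, -0.10, 0.015),
    ("R", 0.00, 1.00, 0.018),
    ("S", 0.05, -0.20, 0.015),
    ("T", 0.25, 0.30, 0.070),
)

_STEP_FREQ = {"rest": 0.0, "walk": 1.8, "run": 2.8}
_STEP_AMP = {"rest": 0.0, "walk": 2.0, "run": 4.0}
_GRAVITY = 9.81


@dataclass
class SynthConfig:
    """Study conditions for the synthetic test bed.

    Defaults mirror a 50 Hz chest-worn recording: one-minute records,
    70 bpm with mild RR variability, transient artefacts whose peak is
    twice the R amplitude, and a weak accelerometer-artefact coupling.
    """

    fs: float = 50.0
    duration: float = 60.0
    heart_rate: float = 70.0
    hr_jitter: float = 0.03
    artefact_fraction: float = 0.2
    artefact_amplitude: float = 2.0
    kappa: float = 0.2
    noise_sd: float = 0.03  # sensor noise floor, fraction of R amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.artefact_fraction <= 1.0:
            raise ValueError("artefact_fraction must be in [0, 1]")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must be in [0, 1]")
        if self.fs <= 0 or self.duration <= 0 or self.heart_rate <= 0:
            raise ValueError("fs, duration and heart_rate must be positive")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))


def generate_clean_ecg(cfg: SynthConfig) -> tuple[SignalRecord, QRSAnnotation]:
    """Clean synthetic ECG plus ground-truth R-peak annotation.

    R-peaks land exactly on sample indices; with zero jitter they are
    spaced exactly ``round(fs * 60 / heart_rate)`` samples apart.
    """
    n = int(round(cfg.duration * cfg.fs))
    rr_nominal = cfg.fs * 60.0 / cfg.heart_rate
    if n < rr_nominal:
        raise ValueError("duration shorter than one cardiac cycle")
    rng = cfg.rng(salt=1)

    # First R a quarter-cycle in; integer RR intervals keep peaks on samples.
    r_peaks = []
    pos = float(round(0.25 * rr_nominal))
    while pos < n:
        r_peaks.append(int(round(pos)))
        rr = rr_nominal
        if cfg.hr_jitter > 0:
            rr *= 1.0 + cfg.hr_jitter * rng.standard_normal()
        pos += max(round(rr), 2)
    r_peaks = np.asarray(r_peaks, dtype=int)
    r_peaks = r_peaks[r_peaks < n]

    t = np.arange(n) / cfg.fs
    ecg = np.zeros(n)
    for r in r_peaks:
        tr = r / cfg.fs
        for _, off, amp, sig in _WAVES:
            lo = max(0, int((tr + off - 5 * sig) * cfg.fs))
            hi = min(n, int((tr + off + 5 * sig) * cfg.fs) + 1)
            ecg[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - tr - off) / sig) ** 2)

    if cfg.noise_sd > 0:
        # Separate stream so the noise floor never perturbs the fiducials.
        ecg = ecg + cfg.noise_sd * cfg.rng(salt=4).standard_normal(n)

    zeros = np.zeros(n)
    rec = SignalRecord(ecg=ecg, acc_x=zeros, acc_y=zeros.copy(), acc_z=zeros.copy(), fs=cfg.fs)
    rr_all = np.diff(r_peaks)
    per_l = np.concatenate([rr_all[:1], rr_all]) if rr_all.size else np.array([int(rr_nominal)])
    return rec, QRSAnnotation(r_peaks=r_peaks, per_beat_l=per_l[: r_peaks.size])


def generate_acceleration(cfg: SynthConfig, activity: str = "walk") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Triaxial acceleration for a rest / walk / run activity regime.

    Rest is low-variance noise around gravity on the z axis; walking and
    running add a sinusoid at the step frequency (≈1.8 / 2.8 Hz) with
    axis-specific phases, plus sensor noise.
    """
    if activity not in _STEP_FREQ:
        raise ValueError(f"unknown activity {activity!r}; expected rest|walk|run")
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    rng = cfg.rng(salt=2)
    f, a = _STEP_FREQ[activity], _STEP_AMP[activity]
    noise_sd = 0.05 if activity == "rest" else 0.1
    phases = rng.uniform(0, 2 * np.pi, size=3)
    axis_gain = np.array([1.0, 0.4, 0.7])
    out = []
    for ax in range(3):
        sig = a * axis_gain[ax] * np.sin(2 * np.pi * f * t + phases[ax]) if f > 0 else np.zeros(n)
        sig = sig + noise_sd * rng.standard_normal(n)
        if ax == 2:
            sig = sig + _GRAVITY
        out.append(sig)
    return out[0], out[1], out[2]


def _raised_cosine(width: int) -> np.ndarray:
    # Smooth 0->1->0 bump (Hann window); matches a transient baseline change.
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / (width - 1)))


def generate_artefact(
    cfg: SynthConfig,
    acc: tuple[np.ndarray, np.ndarray, np.ndarray],
    r_peaks: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Additive motion-artefact signal plus the corrupted-beat mask.

    The artefact is ``kappa`` times a seeded 5-tap FIR filtering of the
    acceleration signal-vector magnitude (mean-removed, peak-normalized)
    plus ``1 - kappa`` times reference-independent raised-cosine transients
    of 0.2-1.0 s placed so that exactly ``round(artefact_fraction *
    n_beats)`` beats intersect a transient; the total is scaled to a peak
    of ``artefact_amplitude`` times the R amplitude (1.0).  The mask marks
    the beats selected for transients.
    """
    acc_x, acc_y, acc_z = acc
    n = acc_x.size
    r_peaks = np.asarray(r_peaks, dtype=int)
    n_beats = r_peaks.size
    mask = np.zeros(n_beats, dtype=bool)
    if cfg.artefact_fraction == 0.0 or n_beats == 0:
        return np.zeros(n), mask

    rng = cfg.rng(salt=3)
    n_hit = int(round(cfg.artefact_fraction * n_beats))
    if n_hit < 1:
        warnings.warn("artefact_fraction too small for this record; placing one artefact")
        n_hit = 1
    hit = np.sort(rng.choice(n_beats, size=n_hit, replace=False))
    mask[hit] = True

    # Reference-correlated component: random FIR of the SVM, mean-removed.
    svm = np.sqrt(acc_x**2 + acc_y**2 + acc_z**2)
    taps = rng.standard_normal(5)
    ref = np.convolve(svm - svm.mean(), taps, mode="same")
    peak = np.max(np.abs(ref))
    if peak > 0:
        ref = ref / peak

    # Reference-independent transients, each confined to its beat's window
    # (midpoints to the neighboring beats) so exactly the selected beats
    # intersect a transient.  Durations are 0.2-1.0 s, truncated to the
    # window when the cardiac cycle is shorter.
    bounds_lo = np.empty(n_beats, dtype=int)
    bounds_hi = np.empty(n_beats, dtype=int)
    for b in range(n_beats):
        bounds_lo[b] = 0 if b == 0 else (r_peaks[b - 1] + r_peaks[b]) // 2 + 1
        bounds_hi[b] = n if b == n_beats - 1 else (r_peaks[b] + r_peaks[b + 1]) // 2
    bumps = np.zeros(n)
    for b in hit:
        lo_b, hi_b = int(bounds_lo[b]), int(bounds_hi[b])
        width = int(round(rng.uniform(0.2, 1.0) * cfg.fs))
        width = int(np.clip(width, 3, hi_b - lo_b))
        start = int(rng.integers(lo_b, hi_b - width + 1))
        bumps[start : start + width] += (
            rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.0) * _raised_cosine(width)
        )
    bpeak = np.max(np.abs(bumps))
    if bpeak > 0:
        bumps = bumps / bpeak

    artefact = cfg.kappa * ref + (1.0 - cfg.kappa) * bumps
    apeak = np.max(np.abs(artefact))
    if apeak > 0:
        artefact = artefact * (cfg.artefact_amplitude / apeak)
    return artefact, mask


def contaminate(clean: SignalRecord, artefact: np.ndarray) -> SignalRecord:
    """Additive noise model: corrupted ECG = clean ECG + artefact."""
    artefact = np.asarray(artefact, dtype=float)
    if artefact.size != len(clean):
        raise ValueError("artefact length does not match record length")
    return SignalRecord(
        ecg=clean.ecg + artefact,
        acc_x=clean.acc_x,
        acc_y=clean.acc_y,
        acc_z=clean.acc_z,
        fs=clean.fs,
        labels=clean.labels,
        t0=clean.t0,
    )


def make_contaminated_record(
    cfg: SynthConfig, activity: str = "walk"
) -> tuple[SignalRecord, SignalRecord, QRSAnnotation, np.ndarray]:
    """Convenience bundle: (contaminated record, clean record, truth annotation, beat mask).

    The contaminated record carries the generated acceleration channels.
    """
    clean, ann = generate_clean_ecg(cfg)
    acc = generate_acceleration(cfg, activity)
    clean = replace_acc(clean, acc)
    artefact, mask = generate_artefact(cfg, acc, ann.r_peaks)
    return contaminate(clean, artefact), clean, ann, mask


def replace_acc(rec: SignalRecord, acc: tuple[np.ndarray, np.ndarray, np.ndarray]) -> SignalRecord:
    return SignalRecord(
        ecg=rec.ecg, acc_x=acc[0], acc_y=acc[1], acc_z=acc[2],
        fs=rec.fs, labels=rec.labels, t0=rec.t0,
    )
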