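"""Synthetic motor-EEG generator with controllable ERD/ERS structure.

Each trial is a spatial mixture of band-limited mu (~10 Hz) and beta (~20 Hz)
oscillators riding on 1/f background noise.  Class identity enters as
multiplicative amplitude attenuation of the rhythms inside a task window
(event-related desynchronization): source channels assigned to a class lose
``erd_depth`` of their rhythm amplitude while the task is "performed".  A
seeded random orthonormal matrix mixes sources into sensor channels so that
spatial filtering (CSP) has recoverable structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .resample import make_lss_hss_pair  # re-exported pairing protocol  # noqa: F401
from .trialset import EEGTrialSet, clip_to_scope, quantize_sensitivity

__all__ = ["SynthConfig", "generate_erders_trialset", "make_lss_hss_pair", "lateralized_erd_depth"]


def lateralized_erd_depth(n_classes: int, n_channels: int, depth: float = 0.5) -> np.ndarray:
    """Class-lateralized ERD profile: disjoint channel groups per class."""
    prof = np.zeros((n_classes, n_channels))
    group = max(1, n_channels // n_classes)
    for c in range(n_classes):
        prof[c, c * group : (c + 1) * group] = depth
    return prof


@dataclass
class SynthConfig:
    """Study conditions for the ERD/ERS simulator.

    ``erd_depth`` is (n_classes, n_channels) in [0, 1]: the fractional rhythm
    amplitude attenuation on each source channel during the task window.
    """

    n_classes: int = 2
    trials_per_class: int = 100
    n_channels: int = 8
    fs_hss: float = 250.0
    trial_duration: float = 2.0
    mu_freq: float = 10.0
    beta_freq: float = 20.0
    mu_amp: float = 10.0  # uV, resting rhythm amplitude
    beta_amp: float = 5.0  # uV
    erd_depth: np.ndarray | None = None  # default: lateralized, depth 0.5
    task_window: tuple = (0.5, 1.5)  # seconds
    pink_noise_sd: float = 5.0  # uV at the sensors
    mixing_seed: int = 0
    scope: tuple = (-100.0, 100.0)
    sensitivity_step: float = 0.1  # uV/bit

    def resolved_erd(self) -> np.ndarray:
        if self.erd_depth is None:
            return lateralized_erd_depth(self.n_classes, self.n_channels)
        return np.asarray(self.erd_depth, dtype=np.float64)

    def validate(self):
        problems = []
        if not 2 <= self.n_classes <= 6:
            problems.append("n_classes must be in [2, 6]")
        if self.trials_per_class < 1:
            problems.append("trials_per_class must be >= 1")
        if self.n_channels < 1:
            problems.append("n_channels must be >= 1")
        if self.fs_hss / 2.0 <= self.beta_freq:
            problems.append("fs_hss/2 must exceed beta_freq")
        erd = self.resolved_erd()
        if erd.shape != (self.n_classes, self.n_channels):
            problems.append("erd_depth must be (n_classes, n_channels)")
        elif not ((erd >= 0) & (erd <= 1)).all():
            problems.append("erd_depth entries must lie in [0, 1]")
        w0, w1 = self.task_window
        if not (0 <= w0 < w1 <= self.trial_duration):
            problems.append("task_window must lie inside the trial")
        if self.pink_noise_sd < 0:
            problems.append("pink_noise_sd must be >= 0")
        lo, hi = self.scope
        if not lo < hi:
            problems.append("scope must satisfy lo < hi")
        if problems:
            raise ValueError("invalid SynthConfig: " + "; ".join(problems))


def _pink_noise(rng: np.random.Generator, shape, fs: float, sd: float) -> np.ndarray:
    """1/f (power) noise by spectral shaping of white noise, unit-free then
    rescaled to the requested standard deviation."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])  # amplitude ~ f^-1/2 -> power ~ 1/f
    shaping[0] = 0.0  # no DC drift
    pink = np.fft.irfft(spec * shaping, n=n, axis=-1)
    std = pink.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return sd * pink / std


def _task_envelope(t: np.ndarray, window: tuple, edge: float = 0.1) -> np.ndarray:
    """Smooth 0->1->0 gate over the task window (raised-cosine edges)."""
    w0, w1 = window
    env = np.zeros_like(t)
    core = (t >= w0 + edge) & (t <= w1 - edge)
    env[core] = 1.0
    rise = (t >= w0) & (t < w0 + edge)
    env[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - w0) / edge))
    fall = (t > w1 - edge) & (t <= w1)
    env[fall] = 0.5 * (1 - np.cos(np.pi * (w1 - t[fall]) / edge))
    return env


def generate_erders_trialset(cfg: SynthConfig, seed: int = 0) -> EEGTrialSet:
    """Simulate a labeled trial set with class-dependent ERD structure.

    Deterministic for a fixed (cfg, seed); labels are balanced; amplitudes
    are scope-clipped and quantized to the configured sensitivity.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    n_trials = cfg.n_classes * cfg.trials_per_class
    n_samples = int(round(cfg.fs_hss * cfg.trial_duration))
    t = np.arange(n_samples) / cfg.fs_hss
    erd = cfg.resolved_erd()
    env = _task_envelope(t, cfg.task_window)

    labels = np.repeat(np.arange(cfg.n_classes), cfg.trials_per_class)

    # seeded random orthonormal mixing from source space to sensor space
    mix_rng = np.random.default_rng(cfg.mixing_seed)
    mixing, _ = np.linalg.qr(mix_rng.standard_normal((cfg.n_channels, cfg.n_channels)))

    data = np.empty((n_trials, cfg.n_channels, n_samples))
    for i, cls in enumerate(labels):
        # per-trial random phases and mild (10%) amplitude variability
        phases = rng.uniform(0, 2 * np.pi, size=(2, cfg.n_channels))
        amp_jitter = rng.lognormal(mean=0.0, sigma=0.1, size=(2, cfg.n_channels))
        atten = 1.0 - erd[cls][:, None] * env[None, :]  # (ch, t)
        mu = (
            cfg.mu_amp
            * amp_jitter[0][:, None]
            * np.sin(2 * np.pi * cfg.mu_freq * t[None, :] + phases[0][:, None])
        )
        beta = (
            cfg.beta_amp
            * amp_jitter[1][:, None]
            * np.sin(2 * np.pi * cfg.beta_freq * t[None, :] + phases[1][:, None])
        )
        sources = (mu + beta) * atten
        sensors = mixing @ sources
        sensors += _pink_noise(rng, (cfg.n_channels, n_samples), cfg.fs_hss, cfg.pink_noise_sd)
        data[i] = sensors

    ts = EEGTrialSet(
        data=data,
        fs=cfg.fs_hss,
        labels=labels,
        sensitivity=cfg.sensitivity_step,
        scope=tuple(cfg.scope),
        subject_id=f"synth-seed{seed}",
    )
    ts = clip_to_scope(ts)
    if cfg.sensitivity_step and cfg.sensitivity_step > 0:
        ts = quantize_sensitivity(ts, cfg.sensitivity_step)
    return ts
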