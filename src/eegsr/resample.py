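"""Sampling-rate conversion and training patch-pair extraction.

Decimation models the low-rate acquisition path (anti-alias low-pass, then
keep every k-th sample); cubic-spline upsampling is the non-learned
reconstruction baseline the adversarial generator is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .trialset import EEGTrialSet, quantize_sensitivity

__all__ = [
    "PatchPair",
    "decimate_trials",
    "spline_upsample",
    "extract_patch_pairs",
]

# the mu/beta analysis band tops out at 30 Hz; decimation must keep it intact
ANALYSIS_BAND_HZ = 30.0


@dataclass(frozen=True)
class PatchPair:
    """An aligned low-rate / high-rate training patch pair.

    ``lss_patch`` is (n_channels, tau), ``hss_patch`` is (n_channels, 2*tau);
    ``origin`` is (trial index, start sample in the high-rate timebase).
    """

    lss_patch: np.ndarray
    hss_patch: np.ndarray
    origin: tuple

    def __post_init__(self):
        if self.hss_patch.shape[-1] != 2 * self.lss_patch.shape[-1]:
            raise ValueError("hss patch must be exactly twice the lss patch length")
        if self.hss_patch.shape[0] != self.lss_patch.shape[0]:
            raise ValueError("patch channel counts differ")
        if self.origin[1] % 2 != 0:
            raise ValueError("hss start sample must be even (2x the lss start)")


def decimate_trials(ts: EEGTrialSet, factor: int) -> EEGTrialSet:
    """Anti-aliased integer-factor downsampling of every trial.

    An 8th-order Butterworth low-pass at 0.8x the target Nyquist is applied
    forward-backward (zero phase), then every ``factor``-th sample is kept.
    """
    factor = int(factor)
    if factor < 2:
        raise ValueError("decimation factor must be >= 2")
    if ts.n_samples % factor != 0:
        raise ValueError(
            f"trial length {ts.n_samples} not divisible by factor {factor}"
        )
    new_fs = ts.fs / factor
    if new_fs / 2.0 <= ANALYSIS_BAND_HZ:
        raise ValueError(
            f"decimation to {new_fs} Hz puts Nyquist at {new_fs / 2} Hz, "
            f"inside the {ANALYSIS_BAND_HZ} Hz analysis band"
        )
    cutoff = 0.8 * (new_fs / 2.0)
    sos = signal.butter(8, cutoff, btype="low", fs=ts.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, ts.data, axis=-1)
    return ts.with_data(filtered[:, :, ::factor], fs=new_fs)


def spline_upsample(ts: EEGTrialSet, factor: int) -> EEGTrialSet:
    """Cubic-spline interpolation onto a ``factor``-times finer uniform grid."""
    factor = int(factor)
    if factor < 2:
        raise ValueError("upsampling factor must be >= 2")
    if ts.n_samples < 4:
        raise ValueError("cubic spline interpolation needs at least 4 samples")
    t_old = np.arange(ts.n_samples) / ts.fs
    t_new = np.arange(ts.n_samples * factor) / (ts.fs * factor)
    cs = CubicSpline(t_old, ts.data, axis=-1)
    return ts.with_data(cs(t_new), fs=ts.fs * factor)


def extract_patch_pairs(
    lss: EEGTrialSet,
    hss: EEGTrialSet,
    tau: int = 12,
    n: int = 1024,
    seed: int = 0,
) -> list[PatchPair]:
    """Draw ``n`` aligned patch pairs uniformly over (trial, start).

    A low-rate start sample ``s`` maps to high-rate start ``2 s``; sampling is
    uniform with replacement and reproducible for a fixed seed.
    """
    if lss.n_trials != hss.n_trials:
        raise ValueError(
            f"trial counts differ: lss {lss.n_trials} vs hss {hss.n_trials}"
        )
    if hss.n_samples != 2 * lss.n_samples:
        raise ValueError("hss must have exactly twice the lss sample count")
    tau = int(tau)
    if tau > lss.n_samples:
        raise ValueError(f"tau={tau} longer than trial ({lss.n_samples} samples)")
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(int(n)):
        trial = int(rng.integers(0, lss.n_trials))
        start = int(rng.integers(0, lss.n_samples - tau + 1))
        pairs.append(
            PatchPair(
                lss_patch=lss.data[trial, :, start : start + tau].copy(),
                hss_patch=hss.data[trial, :, 2 * start : 2 * start + 2 * tau].copy(),
                origin=(trial, 2 * start),
            )
        )
    return pairs


def make_lss_hss_pair(
    hss: EEGTrialSet, factor: int = 2, sensitivity_step: float | None = None
) -> tuple[EEGTrialSet, EEGTrialSet]:
    """Build the training pairing: LSS = quantized decimation of the HSS set."""
    lss = decimate_trials(hss, factor)
    if sensitivity_step is not None:
        lss = quantize_sensitivity(lss, sensitivity_step)
    return lss, hss
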