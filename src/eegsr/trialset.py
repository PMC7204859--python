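"""Labeled multichannel EEG trial sets and amplitude-scope utilities.

The container keeps amplitudes in microvolts throughout the pipeline;
mapping to the network's normalized [-1, 1] units happens only at the
network boundary via :func:`normalize_scope`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "EEGTrialSet",
    "normalize_scope",
    "denormalize_scope",
    "clip_to_scope",
    "quantize_sensitivity",
]


@dataclass
class EEGTrialSet:
    """A set of labeled EEG trials.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz.
    labels : ndarray, shape (n_trials,)
        Integer class identifier per trial.
    sensitivity : float
        Amplitude resolution of the recording device in microvolts per bit.
    scope : tuple (lo, hi)
        Declared amplitude bounds in microvolts.
    channel_names : list of str
    subject_id : str
        Provenance tag.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    sensitivity: float = 1.0
    scope: tuple = (-100.0, 100.0)
    channel_names: list = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("amplitudes must be finite")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"labels length {len(self.labels)} != n_trials {self.data.shape[0]}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        lo, hi = self.scope
        if not lo < hi:
            raise ValueError(f"degenerate scope {self.scope}: need lo < hi")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length != n_channels")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data, **changes) -> "EEGTrialSet":
        return replace(self, data=np.asarray(data, dtype=np.float64), **changes)

    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


def normalize_scope(values: np.ndarray, scope) -> np.ndarray:
    """Affine map of microvolt amplitudes onto [-1, 1]: lo -> -1, hi -> +1."""
    lo, hi = scope
    if not lo < hi:
        raise ValueError(f"degenerate scope {scope}: need lo < hi")
    return (np.asarray(values, dtype=np.float64) - lo) * (2.0 / (hi - lo)) - 1.0


def denormalize_scope(values: np.ndarray, scope) -> np.ndarray:
    """Inverse of :func:`normalize_scope`: -1 -> lo, +1 -> hi."""
    lo, hi = scope
    if not lo < hi:
        raise ValueError(f"degenerate scope {scope}: need lo < hi")
    return (np.asarray(values, dtype=np.float64) + 1.0) * ((hi - lo) / 2.0) + lo


def clip_to_scope(ts: EEGTrialSet) -> EEGTrialSet:
    """Clamp every amplitude into the declared scope (idempotent)."""
    lo, hi = ts.scope
    return ts.with_data(np.clip(ts.data, lo, hi))


def quantize_sensitivity(ts: EEGTrialSet, step: float) -> EEGTrialSet:
    """Emulate an amplifier's amplitude resolution by uniform quantization.

    Each amplitude becomes ``round(value / step) * step``; the quantization
    error is bounded by step/2 per sample.
    """
    if step <= 0:
        raise ValueError("sensitivity step must be positive")
    q = np.round(ts.data / step) * step
    return ts.with_data(q, sensitivity=float(step))
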