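"""Whole-trial application of a trained generator.

Training happens on short patches, but the generator is fully convolutional,
so at inference it is applied to each whole trial in one pass (no patch
tiling, hence no seam artifacts).  Output sample count and sampling rate
double; amplitudes are clipped into the declared scope.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .nn import Generator
from .trialset import EEGTrialSet, denormalize_scope, normalize_scope

__all__ = ["reconstruct_trialset", "cross_reconstruct"]


def reconstruct_trialset(
    gen: Generator,
    lss: EEGTrialSet,
    target_fs: float | None = None,
    target_scope=None,
    chunk: int = 16,
) -> EEGTrialSet:
    """Apply the generator to every trial of a low-rate set.

    ``target_fs`` defaults to twice the input rate and must equal it;
    ``target_scope`` defaults to the input set's scope.  Labels, trial order,
    sensitivity and channel names are preserved.
    """
    factor = gen.upsample_factor()
    if target_fs is None:
        target_fs = lss.fs * factor
    if abs(target_fs - lss.fs * factor) > 1e-9:
        raise ValueError(
            f"target_fs {target_fs} must be {factor}x the input rate {lss.fs}"
        )
    if lss.n_samples < gen.spec.min_tau:
        raise ValueError(
            f"trials of {lss.n_samples} samples are shorter than the "
            f"generator minimum ({gen.spec.min_tau})"
        )
    scope = tuple(target_scope if target_scope is not None else lss.scope)
    z = normalize_scope(lss.data, lss.scope)
    out = np.empty((lss.n_trials, lss.n_channels, lss.n_samples * factor))
    for i in range(0, lss.n_trials, chunk):
        block = z[i : i + chunk]
        y = gen(Tensor(block), training=False).data
        out[i : i + chunk] = y
    out = denormalize_scope(out, scope)
    out = np.clip(out, scope[0], scope[1])
    return lss.with_data(out, fs=target_fs, scope=scope)


def cross_reconstruct(
    gen: Generator,
    lss: EEGTrialSet,
    model_scope=None,
    use_model_scope: bool = False,
    chunk: int = 16,
) -> EEGTrialSet:
    """Apply a generator trained on one recording setup to another.

    The generator is fully convolutional, so channel count and trial length
    may differ from training.  By default amplitudes are normalized by the
    *data's* declared scope on the way in and denormalized/clipped to the
    same scope on the way out; ``use_model_scope=True`` instead maps through
    the scope the model was trained with (``model_scope`` or the generator's
    stored scope), which rescales amplitudes across sensitivities.
    """
    if not use_model_scope:
        return reconstruct_trialset(gen, lss, chunk=chunk)
    scope_model = tuple(model_scope if model_scope is not None else gen.scope)
    z = normalize_scope(lss.data, scope_model)
    factor = gen.upsample_factor()
    out = np.empty((lss.n_trials, lss.n_channels, lss.n_samples * factor))
    for i in range(0, lss.n_trials, chunk):
        y = gen(Tensor(z[i : i + chunk]), training=False).data
        out[i : i + chunk] = y
    out = denormalize_scope(out, scope_model)
    lo, hi = lss.scope
    return lss.with_data(np.clip(out, lo, hi), fs=lss.fs * factor)
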