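"""The end-to-end super-resolution estimator.

:class:`EEGSuperResolver` packages the whole method behind a scikit-learn
style interface: ``fit`` extracts aligned patch pairs from a high-rate trial
set and its decimated/quantized twin, fits the CSP filters that parameterize
the spatial loss term, builds the generator and critic, and runs adversarial
training; ``transform`` reconstructs a low-rate trial set at twice its
sampling rate.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .features import CSP, bandpass
from .losses import LossWeights, loss_weight_preset
from .nn import CriticSpec, GeneratorSpec, build_critic, build_generator
from .reconstruction import cross_reconstruct, reconstruct_trialset
from .resample import extract_patch_pairs, make_lss_hss_pair
from .training import TrainConfig, train
from .trialset import EEGTrialSet

__all__ = ["EEGSuperResolver"]


class EEGSuperResolver(BaseEstimator, TransformerMixin):
    """Adversarial EEG sampling-rate/sensitivity super-resolution.

    Parameters mirror the training protocol: the ``wgan`` variant trains a
    Wasserstein critic with gradient penalty under RMSprop, the ``gan``
    variant a sigmoid discriminator under Adam; both share the joint
    generator objective (TSF-MSE + adversarial + total variation).

    Fitted attributes: ``generator_``, ``critic_``, ``records_`` (convergence
    snapshots), ``csp_`` (frozen loss-term CSP), ``scope_``.
    """

    def __init__(
        self,
        variant: str = "wgan",
        epochs: int = 5,
        batch_size: int = 32,
        tau: int = 12,
        n_pairs: int = 3584,
        n_val_pairs: int = 128,
        n_blocks: int = 4,
        n_maps: int = 16,
        critic_base_maps: int = 8,
        critic_dense_units: int = 64,
        n_critic: int = 1,
        lr: float = 1e-5,
        weights: LossWeights | str = "default",
        loss_csp_m: int = 2,
        records_per_epoch: int = 10,
        sensitivity_step: float | None = None,
        seed: int = 0,
    ):
        self.variant = variant
        self.epochs = epochs
        self.batch_size = batch_size
        self.tau = tau
        self.n_pairs = n_pairs
        self.n_val_pairs = n_val_pairs
        self.n_blocks = n_blocks
        self.n_maps = n_maps
        self.critic_base_maps = critic_base_maps
        self.critic_dense_units = critic_dense_units
        self.n_critic = n_critic
        self.lr = lr
        self.weights = weights
        self.loss_csp_m = loss_csp_m
        self.records_per_epoch = records_per_epoch
        self.sensitivity_step = sensitivity_step
        self.seed = seed

    # -- fitting -----------------------------------------------------------
    def _weights(self) -> LossWeights:
        if isinstance(self.weights, str):
            return loss_weight_preset(self.weights)
        return self.weights

    def fit(self, hss: EEGTrialSet, lss: EEGTrialSet | None = None):
        """Fit on a high-rate trial set and (optionally) its low-rate twin.

        When ``lss`` is omitted it is derived by the standard pairing
        protocol: anti-aliased factor-2 decimation followed by sensitivity
        quantization (``sensitivity_step``).
        """
        if lss is None:
            lss, hss = make_lss_hss_pair(hss, 2, self.sensitivity_step)
        if hss.n_samples != 2 * lss.n_samples:
            raise ValueError("hss must have exactly twice the lss sample count")

        rng = np.random.default_rng(self.seed)
        seed_pairs, seed_val, seed_gen, seed_crit, seed_train = rng.integers(
            0, 2**31 - 1, size=5
        )
        pairs = extract_patch_pairs(lss, hss, self.tau, self.n_pairs, int(seed_pairs))
        val_pairs = extract_patch_pairs(
            lss, hss, self.tau, self.n_val_pairs, int(seed_val)
        )

        # frozen CSP filters for the spatial loss: fitted on broadband-
        # filtered (8-30 Hz) real high-rate training trials
        try:
            self.csp_ = CSP(m=self.loss_csp_m).fit(
                bandpass(hss, (8.0, 30.0)).data, hss.labels
            )
            csp = self.csp_
        except ValueError:
            self.csp_ = None  # single-class or too-few-trial data: no spatial term
            csp = None

        scope = tuple(hss.scope)
        gen = build_generator(
            GeneratorSpec(n_blocks=self.n_blocks, n_maps=self.n_maps),
            seed=int(seed_gen),
            scope=scope,
        )
        critic = build_critic(
            CriticSpec(
                base_maps=self.critic_base_maps,
                dense_units=self.critic_dense_units,
                use_batchnorm=(self.variant == "gan"),
                sigmoid_head=(self.variant == "gan"),
            ),
            n_channels=hss.n_channels,
            patch_len=2 * self.tau,
            seed=int(seed_crit),
        )
        cfg = TrainConfig(
            variant=self.variant,
            epochs=self.epochs,
            batch_size=self.batch_size,
            tau=self.tau,
            n_critic=self.n_critic,
            lr=self.lr,
            weights=self._weights(),
            records_per_epoch=self.records_per_epoch,
            fs_hss=hss.fs,
            scope=scope,
            seed=int(seed_train),
        )
        self.generator_, self.critic_, self.records_ = train(
            pairs, gen, critic, cfg, val_pairs, csp=csp
        )
        self.scope_ = scope
        self.fs_hss_ = hss.fs
        return self

    # -- application -------------------------------------------------------
    def transform(self, lss: EEGTrialSet) -> EEGTrialSet:
        """Reconstruct a low-rate trial set at twice its sampling rate."""
        check_is_fitted(self, "generator_")
        if tuple(lss.scope) == tuple(self.scope_):
            return reconstruct_trialset(self.generator_, lss)
        return cross_reconstruct(self.generator_, lss)
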