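"""Alternating adversarial optimization for both GAN variants.

The loop follows the standard alternating scheme: for each minibatch the
discriminator/critic takes a step on its adversarial loss (plus gradient
penalty for the Wasserstein variant), then the generator takes a step on the
joint objective (TSF-MSE + adversarial + total variation).  The classic GAN
variant is optimized with Adam (alpha=1e-5, beta1=0.5, beta2=0.9), the
Wasserstein variant with RMSprop (alpha=1e-5, beta=0.9).

Convergence is tracked on a held-out set of validation patch pairs:
``records_per_epoch`` snapshots per epoch of the temporal, spatial, frequency
and combined TSF validation losses plus the Wasserstein surrogate
-E[D(x)] + E[D(G(z))] (unnormalized, as tracked in training diagnostics).
All losses in the records are computed in the network's normalized [-1, 1]
amplitude units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .losses import (
    LossWeights,
    gan_losses,
    gradient_penalty,
    joint_generator_loss,
    tsf_mse,
    tv_loss,
    wgan_losses,
)
from .nn import Adam, Critic, Generator, RMSprop
from .resample import PatchPair
from .trialset import normalize_scope

__all__ = [
    "TrainConfig",
    "ConvergenceRecord",
    "TrainingDiverged",
    "leave_one_rest_split",
    "train",
]


@dataclass
class TrainConfig:
    """Hyperparameters of the adversarial training loop."""

    variant: str = "wgan"  # "gan" | "wgan"
    epochs: int = 30
    batch_size: int = 32
    tau: int = 12
    n_critic: int = 1  # critic updates per generator update
    lr: float = 1e-5
    adam_beta1: float = 0.5
    adam_beta2: float = 0.9
    rmsprop_beta: float = 0.9
    weights: LossWeights = field(default_factory=LossWeights)
    records_per_epoch: int = 10
    fs_hss: float = 250.0
    psd_nfft: int = 256
    scope: tuple = (-100.0, 100.0)
    seed: int = 0

    def __post_init__(self):
        if self.variant not in ("gan", "wgan"):
            raise ValueError("variant must be 'gan' or 'wgan'")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.records_per_epoch < 1:
            raise ValueError("records_per_epoch must be >= 1")


@dataclass(frozen=True)
class ConvergenceRecord:
    """One validation snapshot during training."""

    epoch: int
    checkpoint: int
    l_t: float
    l_s: float
    l_f: float
    l_tsf: float
    wasserstein: float

    def __post_init__(self):
        for name in ("l_t", "l_s", "l_f", "l_tsf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class TrainingDiverged(RuntimeError):
    """Raised when a non-finite loss appears; carries the diagnostic record."""

    def __init__(self, message, record=None):
        super().__init__(message)
        self.record = record


def leave_one_rest_split(units, held_out, k: int, seed: int = 0):
    """Hold one unit out, sample ``k`` of the rest for training.

    Returns (train_ids, held_out).  Sampling is uniform without replacement
    and reproducible for a fixed seed.
    """
    units = list(units)
    if held_out not in units:
        raise ValueError(f"held-out unit {held_out!r} not among units")
    rest = [u for u in units if u != held_out]
    if k > len(rest):
        raise ValueError(f"k={k} exceeds the {len(rest)} remaining units")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rest), size=k, replace=False)
    return [rest[i] for i in sorted(idx)], held_out


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _stack_pairs(pairs: list[PatchPair], scope):
    lss = normalize_scope(np.stack([p.lss_patch for p in pairs]), scope)
    hss = normalize_scope(np.stack([p.hss_patch for p in pairs]), scope)
    return lss, hss


def _validation_record(
    gen, critic, lss_val, hss_val, cfg, csp, epoch, checkpoint
) -> ConvergenceRecord:
    fake = gen(Tensor(lss_val), training=False)
    real = Tensor(hss_val)
    _, lt, ls, lf = tsf_mse(
        fake,
        real,
        csp,
        fs=cfg.fs_hss,
        nfft=cfg.psd_nfft,
        weights=cfg.weights,
        return_components=True,
    )
    w = cfg.weights
    l_tsf = w.lambda_t * lt.item() + w.lambda_s * ls.item() + w.lambda_f * lf.item()
    d_real = critic(real, training=False)
    d_fake = critic(fake.detach(), training=False)
    surrogate = float(-d_real.data.mean() + d_fake.data.mean())
    return ConvergenceRecord(
        epoch=epoch,
        checkpoint=checkpoint,
        l_t=lt.item(),
        l_s=ls.item(),
        l_f=lf.item(),
        l_tsf=l_tsf,
        wasserstein=surrogate,
    )


def train(
    pairs: list[PatchPair],
    gen: Generator,
    critic: Critic,
    cfg: TrainConfig,
    validation_pairs: list[PatchPair] | None = None,
    csp=None,
    callback=None,
):
    """Train generator and critic on extracted patch pairs.

    ``csp`` is a CSP model (or filter matrix) fitted beforehand on real
    high-rate training trials; it parameterizes the spatial MSE term and is
    frozen during training.  Returns ``(gen, critic, records)``.
    """
    if len(pairs) < cfg.batch_size:
        raise ValueError(
            f"need at least one batch of pairs ({cfg.batch_size}), got {len(pairs)}"
        )
    rng = np.random.default_rng(cfg.seed)
    lss_all, hss_all = _stack_pairs(pairs, cfg.scope)
    if validation_pairs:
        lss_val, hss_val = _stack_pairs(validation_pairs, cfg.scope)
    else:
        lss_val, hss_val = lss_all[: cfg.batch_size], hss_all[: cfg.batch_size]

    csp_filters = getattr(csp, "filters_", csp)

    if cfg.variant == "gan":
        opt_d = Adam(critic.parameters(), cfg.lr, cfg.adam_beta1, cfg.adam_beta2)
        opt_g = Adam(gen.parameters(), cfg.lr, cfg.adam_beta1, cfg.adam_beta2)
    else:
        opt_d = RMSprop(critic.parameters(), cfg.lr, cfg.rmsprop_beta)
        opt_g = RMSprop(gen.parameters(), cfg.lr, cfg.rmsprop_beta)

    n = len(pairs)
    n_batches = n // cfg.batch_size
    rec_every = max(1, n_batches // cfg.records_per_epoch)
    records: list[ConvergenceRecord] = []
    step = 0

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        checkpoint = 0
        for b in range(n_batches):
            idx = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            lss_b = Tensor(lss_all[idx])
            hss_b = Tensor(hss_all[idx])

            # ---- critic/discriminator step -----------------------------
            fake = gen(lss_b, training=True)
            fake_d = fake.detach()
            d_real = critic(hss_b, training=True)
            d_fake = critic(fake_d, training=True)
            if cfg.variant == "wgan":
                gp = gradient_penalty(
                    critic, hss_b, fake_d, cfg.weights.lambda_gp, rng=rng
                )
                d_loss, _, _ = wgan_losses(d_real, d_fake, gp)
            else:
                d_loss, _ = gan_losses(d_real, d_fake)
            if not np.isfinite(d_loss.item()):
                raise TrainingDiverged(
                    f"non-finite critic loss at epoch {epoch}, batch {b}",
                    record=records[-1] if records else None,
                )
            opt_d.step(ad.grad(d_loss, opt_d.params))

            # ---- generator step (every n_critic batches) ---------------
            step += 1
            if step % cfg.n_critic == 0:
                d_fake_g = critic(fake, training=True)
                if cfg.variant == "wgan":
                    _, g_adv, _ = wgan_losses(
                        d_real.detach(), d_fake_g, 0.0
                    )
                else:
                    _, g_adv = gan_losses(d_real.detach(), d_fake_g)
                tsf = tsf_mse(
                    fake,
                    hss_b,
                    csp_filters,
                    fs=cfg.fs_hss,
                    nfft=cfg.psd_nfft,
                    weights=cfg.weights,
                )
                tv = tv_loss(fake)
                g_loss = joint_generator_loss(tsf, g_adv, tv, cfg.weights)
                if not np.isfinite(g_loss.item()):
                    raise TrainingDiverged(
                        f"non-finite generator loss at epoch {epoch}, batch {b}",
                        record=records[-1] if records else None,
                    )
                opt_g.step(ad.grad(g_loss, opt_g.params))

            # ---- convergence snapshot ----------------------------------
            if (b + 1) % rec_every == 0 and checkpoint < cfg.records_per_epoch:
                rec = _validation_record(
                    gen, critic, lss_val, hss_val, cfg, csp_filters, epoch, checkpoint
                )
                records.append(rec)
                checkpoint += 1
                if callback is not None:
                    callback(rec)
    return gen, critic, records
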