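import numpy as np
import pytest

from eegsr import autodiff as ad
from eegsr.autodiff import Tensor
from eegsr.features import CSP, compute_psd
from eegsr.losses import (
    LossWeights,
    differentiable_csp_features,
    frequency_mse,
    gan_losses,
    gradient_penalty,
    joint_generator_loss,
    loss_weight_preset,
    spatial_mse,
    temporal_mse,
    tsf_mse,
    tv_loss,
    wgan_losses,
)

RNG = np.random.default_rng(0)


@pytest.fixture()
def batch():
    return RNG.normal(size=(6, 4, 24))


@pytest.fixture()
def csp_model():
    X = np.concatenate(
        [
            np.einsum("ij,tjs->tis", np.diag([3.0, 1, 1, 1]), RNG.normal(size=(8, 4, 100))),
            np.einsum("ij,tjs->tis", np.diag([1.0, 1, 1, 3]), RNG.normal(size=(8, 4, 100))),
        ]
    )
    y = np.array([0] * 8 + [1] * 8)
    return CSP(m=1).fit(X, y)


class TestTemporal:
    def test_identical_batches_give_zero(self, batch):
        assert temporal_mse(batch, batch).item() == 0.0

    def test_constant_offset_closed_form(self, batch):
        c = 0.37
        assert temporal_mse(batch + c, batch).item() == pytest.approx(c**2)

    def test_toy_hand_computation(self):
        gen = np.array([[1.0, 2.0]])
        real = np.zeros((1, 2))
        assert temporal_mse(gen, real).item() == pytest.approx(2.5)

    def test_shape_mismatch_rejected(self, batch):
        with pytest.raises(ValueError, match="mismatch"):
            temporal_mse(batch, batch[:, :, :12])


class TestSpatial:
    def test_identical_batches_give_zero(self, batch, csp_model):
        assert spatial_mse(batch, batch, csp_model).item() == pytest.approx(0.0)

    def test_time_permutation_invariant(self, batch, csp_model):
        perm = RNG.permutation(batch.shape[-1])
        assert spatial_mse(batch[:, :, perm], batch, csp_model).item() == pytest.approx(
            0.0, abs=1e-18
        )

    def test_matches_per_patch_feature_loop(self, batch, csp_model):
        gen = batch + RNG.normal(0, 0.5, size=batch.shape)
        got = spatial_mse(gen, batch, csp_model).item()
        # naive oracle: per-patch feature vectors through the fitted model
        fg = np.stack([csp_model.transform(p) for p in gen])
        fr = np.stack([csp_model.transform(p) for p in batch])
        expected = np.mean((fg - fr) ** 2)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_channel_mismatch_rejected(self, csp_model):
        with pytest.raises(ValueError, match="channels"):
            spatial_mse(np.zeros((2, 3, 24)), np.zeros((2, 3, 24)), csp_model)


class TestFrequency:
    def test_identical_batches_give_zero(self, batch):
        assert frequency_mse(batch, batch, fs=250.0).item() == 0.0

    def test_phase_shift_of_pure_tone_is_invisible(self):
        fs, T = 250.0, 64
        t = np.arange(T) / fs
        gen = np.sin(2 * np.pi * 10 * t + np.pi / 2)[None, None, :]
        real = np.sin(2 * np.pi * 10 * t)[None, None, :]
        rel = frequency_mse(gen, real, fs=fs).item() / frequency_mse(
            2 * real, real, fs=fs
        ).item()
        assert rel < 0.02

    def test_amplitude_change_matches_periodogram_oracle(self):
        fs, T = 250.0, 24
        t = np.arange(T) / fs
        real = np.sin(2 * np.pi * 10 * t)[None, None, :]
        gen = 2 * real
        got = frequency_mse(gen, real, fs=fs, nfft=256).item()
        pg = compute_psd(gen, fs, nfft=256).power
        pr = compute_psd(real, fs, nfft=256).power
        expected = np.mean((pg - pr) ** 2)
        assert got == pytest.approx(expected, rel=1e-9)
        assert got > 0


class TestTSF:
    def test_temporal_only_weights(self, batch, csp_model):
        gen = batch + 0.1
        w = LossWeights(1.0, 0.0, 0.0)
        assert tsf_mse(gen, batch, csp_model, weights=w).item() == pytest.approx(
            temporal_mse(gen, batch).item()
        )

    def test_same_sensitivity_preset_weights(self):
        w = loss_weight_preset("AO->AO")
        assert (w.lambda_t, w.lambda_s, w.lambda_f) == (0.46, 0.23, 0.30)
        # default adversarial/TV trade-offs
        assert w.lambda_1 == pytest.approx(1e-3)
        assert w.lambda_2 == pytest.approx(2e-8)
        assert w.lambda_gp == 10.0

    def test_linearity_in_weights(self, batch, csp_model):
        gen = batch + RNG.normal(0, 0.2, size=batch.shape)
        w1 = LossWeights(0.4, 0.3, 0.3)
        w2 = LossWeights(0.8, 0.6, 0.6)
        l1 = tsf_mse(gen, batch, csp_model, weights=w1).item()
        l2 = tsf_mse(gen, batch, csp_model, weights=w2).item()
        assert l2 == pytest.approx(2 * l1, rel=1e-9)

    def test_self_loss_is_zero_for_any_weights(self, batch, csp_model):
        w = LossWeights(0.7, 1.3, 2.9)
        assert tsf_mse(batch, batch, csp_model, weights=w).item() == pytest.approx(0.0)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(lambda_t=-0.1)


class TestTV:
    def test_constant_patch_gives_zero(self):
        assert tv_loss(np.full((2, 3, 10), 4.2)).item() == 0.0

    def test_ramp_closed_form(self):
        T, s = 16, 0.25
        ramp = (np.arange(T) * s)[None, None, :]
        assert tv_loss(ramp).item() == pytest.approx((T - 1) * abs(s) / T)

    def test_offset_invariant(self, batch):
        assert tv_loss(batch + 5.0).item() == pytest.approx(tv_loss(batch).item())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tv_loss(np.zeros((0, 2, 4)))


class TestGANLosses:
    def test_perfect_discrimination_loss_vanishes(self):
        d, g = gan_losses(np.full(4, 1 - 1e-9), np.full(4, 1e-9))
        assert d.item() < 1e-6

    def test_maximal_confusion_closed_form(self):
        d, g = gan_losses(np.full(4, 0.5), np.full(4, 0.5))
        assert d.item() == pytest.approx(2 * np.log(2))
        assert g.item() == pytest.approx(np.log(2))

    def test_scores_at_bounds_are_clamped(self):
        d, g = gan_losses(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert np.isfinite(d.item()) and np.isfinite(g.item())


class TestWGANLosses:
    def test_equal_means_give_zero_surrogate(self):
        c, g, s = wgan_losses(np.array([1.0, 3.0]), np.array([2.0, 2.0]), 0.0)
        assert s.item() == pytest.approx(0.0)

    def test_hand_computation(self):
        c, g, s = wgan_losses(np.array([2.0, 4.0]), np.array([1.0, 1.0]), 0.0)
        assert c.item() == pytest.approx(-2.0)
        assert g.item() == pytest.approx(-1.0)
        assert s.item() == pytest.approx(-2.0)

    def test_penalty_added_to_critic_only(self):
        c0, g0, s0 = wgan_losses(np.array([2.0, 4.0]), np.array([1.0, 1.0]), 0.0)
        c1, g1, s1 = wgan_losses(np.array([2.0, 4.0]), np.array([1.0, 1.0]), 5.0)
        assert c1.item() - c0.item() == pytest.approx(5.0)
        assert g1.item() == g0.item()
        assert s1.item() == s0.item()


class TestGradientPenalty:
    @staticmethod
    def _linear_critic(w):
        wt = Tensor(w)
        return lambda x: ad.tsum(x * wt, axis=tuple(range(1, x.ndim)))

    def test_unit_gradient_critic_incurs_no_penalty(self):
        w = np.zeros((3, 8))
        w[0, 0] = 1.0
        critic = self._linear_critic(w)
        gp = gradient_penalty(
            critic, RNG.normal(size=(5, 3, 8)), RNG.normal(size=(5, 3, 8)), 10.0, seed=0
        )
        assert gp.item() == pytest.approx(0.0, abs=1e-9)

    def test_norm_three_critic_closed_form(self):
        w = np.zeros((3, 8))
        w[1, 2] = 3.0
        critic = self._linear_critic(w)
        gp = gradient_penalty(
            critic, RNG.normal(size=(4, 3, 8)), RNG.normal(size=(4, 3, 8)), 10.0, seed=1
        )
        assert gp.item() == pytest.approx(40.0, abs=1e-6)

    def test_default_penalty_weight_is_ten(self):
        assert LossWeights().lambda_gp == 10.0

    def test_penalty_differentiable_wrt_critic_parameters(self):
        w = Tensor(RNG.normal(size=(3, 8)), requires_grad=True)
        critic = lambda x: ad.tsum(x * w, axis=(1, 2))
        gp = gradient_penalty(
            critic, RNG.normal(size=(4, 3, 8)), RNG.normal(size=(4, 3, 8)), 10.0, seed=2
        )
        (gw,) = ad.grad(gp, [w])
        # analytic: gp = 10*(||w||-1)^2 -> d/dw = 20*(||w||-1) * w/||w||
        n = np.linalg.norm(w.data)
        expected = 20 * (n - 1) * w.data / n
        assert np.abs(gw.data - expected).max() < 1e-8


def test_joint_loss_is_additive():
    w = LossWeights(lambda_1=1e-3, lambda_2=2e-8)
    total = joint_generator_loss(0.5, 2.0, 3.0, w).item()
    assert total == pytest.approx(0.5 + 1e-3 * 2.0 + 2e-8 * 3.0)
    only_tsf = joint_generator_loss(0.5, 2.0, 3.0, LossWeights(lambda_1=0, lambda_2=0))
    assert only_tsf.item() == pytest.approx(0.5)
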