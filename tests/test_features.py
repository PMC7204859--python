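import numpy as np
import pytest
from scipy import linalg

from eegsr.features import (
    CSP,
    bandpass,
    build_filter_bank,
    compute_psd,
    csp_features,
    extract_fbcsp,
    fit_csp,
)
from eegsr.trialset import EEGTrialSet

RNG = np.random.default_rng(0)


class TestFilterBank:
    def test_default_bank_is_the_ten_mu_beta_subbands(self):
        fb = build_filter_bank(8, 30, 4, 2)
        assert fb.bands == (
            (8.0, 12.0), (10.0, 14.0), (12.0, 16.0), (14.0, 18.0), (16.0, 20.0),
            (18.0, 22.0), (20.0, 24.0), (22.0, 26.0), (24.0, 28.0), (26.0, 30.0),
        )

    def test_single_band_when_width_spans_range(self):
        assert build_filter_bank(8, 30, 22, 0).bands == ((8.0, 30.0),)

    @pytest.mark.parametrize(
        "lo,hi,width,overlap",
        [(8, 30, 4, 2), (8, 30, 4, 0), (5, 45, 10, 5), (8, 28, 4, 2)],
    )
    def test_band_count_arithmetic(self, lo, hi, width, overlap):
        fb = build_filter_bank(lo, hi, width, overlap)
        expected = int((hi - lo - width) / (width - overlap)) + 1
        assert len(fb) == expected

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError):
            build_filter_bank(8, 30, 2, 2)
        with pytest.raises(ValueError):
            build_filter_bank(8, 10, 4, 2)


class TestBandpass:
    def test_dc_offset_removed(self):
        ts = EEGTrialSet(np.full((1, 2, 500), 10.0), fs=250.0, labels=[0])
        out = bandpass(ts, (8, 12))
        assert np.abs(out.data).max() < 1e-6

    def test_in_band_tone_retained(self):
        t = np.arange(1000) / 250.0
        ts = EEGTrialSet(
            np.sin(2 * np.pi * 10 * t)[None, None, :], fs=250.0, labels=[0]
        )
        out = bandpass(ts, (8, 12))
        mid = out.data[0, 0, 200:-200]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_out_of_band_tone_attenuated(self):
        t = np.arange(1000) / 250.0
        ts = EEGTrialSet(
            np.sin(2 * np.pi * 25 * t)[None, None, :], fs=250.0, labels=[0]
        )
        out = bandpass(ts, (8, 12))
        mid = out.data[0, 0, 200:-200]
        assert 20 * np.log10(np.abs(mid).max()) < -20

    def test_band_above_nyquist_rejected(self):
        ts = EEGTrialSet(np.zeros((1, 1, 100)), fs=50.0, labels=[0])
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(ts, (8, 30))


def _two_class_data(rng, n_per_class=8, n_channels=4, T=100, gains=(3.0, 1.0)):
    A = np.diag([gains[0]] + [1.0] * (n_channels - 1))
    B = np.diag([1.0] * (n_channels - 1) + [gains[1]])
    X1 = np.einsum("ij,tjs->tis", A, rng.normal(size=(n_per_class, n_channels, T)))
    X2 = np.einsum("ij,tjs->tis", B, rng.normal(size=(n_per_class, n_channels, T)))
    X = np.concatenate([X1, X2])
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return X, y, X1, X2


class TestCSP:
    def test_filters_match_generalized_eig_oracle(self):
        """Whitening-based fit agrees with a brute-force generalized
        eigendecomposition of (C1, C1+C2) up to sign/scale."""
        max_angle = 0.0
        for trial in range(50):
            r = np.random.default_rng(trial)
            A = r.normal(size=(4, 4))
            B = r.normal(size=(4, 4))
            X1 = np.einsum("ij,tjs->tis", A, r.normal(size=(6, 4, 100)))
            X2 = np.einsum("ij,tjs->tis", B, r.normal(size=(6, 4, 100)))
            X = np.concatenate([X1, X2])
            y = np.array([0] * 6 + [1] * 6)
            model = CSP(m=2).fit(X, y)

            def avg_cov(Z):
                C = np.einsum("tcs,tds->tcd", Z, Z) / Z.shape[-1]
                C = C / np.trace(C, axis1=1, axis2=2)[:, None, None]
                return C.mean(0)

            C1, C2 = avg_cov(X1), avg_cov(X2)
            w, v = linalg.eigh(C1, C1 + C2)
            v = v[:, np.argsort(w)[::-1]]
            for i in range(4):
                a, b = model.filters_[i], v[:, i]
                cosa = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
                max_angle = max(max_angle, np.arccos(np.clip(cosa, -1, 1)))
        assert max_angle < 1e-6

    def test_identical_class_distributions_give_half_eigenvalues(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 4, 200))
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        model = CSP(m=2).fit(X, y)
        assert np.abs(model.eigenvalues_ - 0.5).max() < 0.1

    def test_eigenvalue_pairing_under_composite_whitening(self):
        """For every filter, variance ratios w.r.t. the two classes sum to 1."""
        X, y, X1, X2 = _two_class_data(np.random.default_rng(6))
        model = CSP(m=2).fit(X, y)

        def avg_cov(Z):
            C = np.einsum("tcs,tds->tcd", Z, Z) / Z.shape[-1]
            C = C / np.trace(C, axis1=1, axis2=2)[:, None, None]
            return C.mean(0)

        C1, C2 = avg_cov(X1), avg_cov(X2)
        lam1 = np.einsum("fc,cd,fd->f", model.filters_, C1, model.filters_)
        lam2 = np.einsum("fc,cd,fd->f", model.filters_, C2, model.filters_)
        assert np.abs(lam1 / (lam1 + lam2) - model.eigenvalues_).max() < 1e-9
        assert np.all((model.eigenvalues_ >= 0) & (model.eigenvalues_ <= 1))

    def test_m_too_large_rejected(self):
        X, y, *_ = _two_class_data(np.random.default_rng(7))
        with pytest.raises(ValueError, match="2m"):
            CSP(m=3).fit(X, y)

    def test_rank_deficient_covariance_suggests_regularization(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(8, 1, 50))
        X = np.repeat(base, 4, axis=1)  # perfectly correlated channels
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        with pytest.raises(np.linalg.LinAlgError, match="reg"):
            CSP(m=2).fit(X, y)
        CSP(m=2, reg=1e-6).fit(X, y)  # shrinkage restores solvability


class TestCSPFeatures:
    @pytest.fixture()
    def model(self):
        X, y, *_ = _two_class_data(np.random.default_rng(9))
        return CSP(m=2).fit(X, y)

    def test_feature_length_is_2m(self, model):
        trial = RNG.normal(size=(4, 60))
        assert csp_features(model, trial).shape == (4,)

    def test_scale_invariant(self, model):
        trial = RNG.normal(size=(4, 60))
        f1 = csp_features(model, trial)
        f2 = csp_features(model, 2.0 * trial)
        assert np.abs(f1 - f2).max() < 1e-12

    def test_time_permutation_invariant(self, model):
        trial = RNG.normal(size=(4, 60))
        perm = RNG.permutation(60)
        assert np.allclose(csp_features(model, trial), csp_features(model, trial[:, perm]))

    def test_zero_variance_trial_rejected(self, model):
        with pytest.raises(ValueError, match="variance"):
            csp_features(model, np.zeros((4, 60)))


class TestPSD:
    def test_zero_signal_zero_power(self):
        spec = compute_psd(np.zeros((2, 64)), fs=250.0)
        assert np.all(spec.power == 0)

    def test_pure_tone_peaks_at_nearest_bin(self):
        t = np.arange(512) / 250.0
        spec = compute_psd(np.sin(2 * np.pi * 10 * t)[None, :], 250.0, nfft=512)
        peak = spec.freqs[np.argmax(spec.power[0])]
        df = spec.freqs[1] - spec.freqs[0]
        assert abs(peak - 10.0) <= df / 2 + 1e-9

    def test_parseval_on_white_noise(self):
        x = np.random.default_rng(11).normal(size=(1, 1024))
        spec = compute_psd(x, fs=250.0, nfft=1024)
        df = spec.freqs[1] - spec.freqs[0]
        assert spec.power.sum() * df == pytest.approx(x.var(), rel=0.05)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            compute_psd(np.zeros((2, 1)), 250.0)


class TestFBCSP:
    @pytest.fixture()
    def sets(self, small_synth):
        train = EEGTrialSet(
            small_synth.data[::2], fs=small_synth.fs, labels=small_synth.labels[::2]
        )
        test = EEGTrialSet(
            small_synth.data[1::2], fs=small_synth.fs, labels=small_synth.labels[1::2]
        )
        return train, test

    def test_binary_feature_count(self, sets):
        train, test = sets
        bank = build_filter_bank()
        f_tr, f_te, models = extract_fbcsp(train, test, bank, m=4)
        assert f_tr.shape == (train.n_trials, 2 * 4 * 10)
        assert f_te.shape == (test.n_trials, 80)
        assert len(models) == 10

    def test_apply_to_train_reproduces_fit_features(self, sets):
        train, _ = sets
        bank = build_filter_bank(8, 16, 4, 0)
        f_tr, f_ap, _ = extract_fbcsp(train, train, bank, m=2)
        assert np.array_equal(f_tr, f_ap)

    def test_no_leakage_from_apply_set(self, sets):
        """Perturbing the apply-to trials must leave the fitted filters
        unchanged (filters depend on training trials only)."""
        train, test = sets
        bank = build_filter_bank(8, 16, 4, 0)
        _, _, models_a = extract_fbcsp(train, test, bank, m=2)
        noisy = EEGTrialSet(
            test.data + RNG.normal(0, 50, test.data.shape),
            fs=test.fs,
            labels=test.labels,
        )
        _, _, models_b = extract_fbcsp(train, noisy, bank, m=2)
        for (_, _, ma), (_, _, mb) in zip(models_a, models_b):
            assert np.array_equal(ma.filters_, mb.filters_)

    def test_filters_stable_under_trial_reordering(self, sets):
        train, _ = sets
        bank = build_filter_bank(8, 12, 4, 0)
        _, _, models = extract_fbcsp(train, train, bank, m=2)
        perm = np.random.default_rng(3).permutation(train.n_trials)
        shuffled = EEGTrialSet(
            train.data[perm], fs=train.fs, labels=train.labels[perm]
        )
        _, _, models_p = extract_fbcsp(shuffled, shuffled, bank, m=2)
        for (_, _, ma), (_, _, mb) in zip(models, models_p):
            # same subspace up to per-filter sign
            dots = np.abs(
                np.sum(
                    ma.filters_ / np.linalg.norm(ma.filters_, axis=1, keepdims=True)
                    * mb.filters_ / np.linalg.norm(mb.filters_, axis=1, keepdims=True),
                    axis=1,
                )
            )
            assert np.all(dots > 1 - 1e-6)


def test_fit_csp_wrapper_on_trialset(small_synth):
    model = fit_csp(bandpass(small_synth, (8, 12)), m=2)
    assert model.filters_.shape == (4, small_synth.n_channels)
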