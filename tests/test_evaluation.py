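import numpy as np
import pytest

from eegsr.evaluation import (
    ClassifierConfig,
    EvalReport,
    FBCSPClassifier,
    beam_power_map,
    classify_fbcsp_svm,
    mean_spectra_difference,
    mean_temporal_error,
    paired_ttest,
    repeated_kfold,
)
from eegsr.features import build_filter_bank
from eegsr.trialset import EEGTrialSet


class TestClassifier:
    def test_single_class_training_rejected(self, small_synth):
        ts = small_synth
        one = EEGTrialSet(
            ts.data[ts.labels == 0], fs=ts.fs, labels=ts.labels[ts.labels == 0]
        )
        with pytest.raises(ValueError, match="single class"):
            classify_fbcsp_svm(one, ts, ClassifierConfig(m=2))

    def test_resubstitution_bounds_heldout(self, small_synth):
        ts = small_synth
        cfg = ClassifierConfig(m=2, bank=build_filter_bank(8, 16, 4, 0))
        train = EEGTrialSet(ts.data[::2], fs=ts.fs, labels=ts.labels[::2])
        test = EEGTrialSet(ts.data[1::2], fs=ts.fs, labels=ts.labels[1::2])
        acc_train = classify_fbcsp_svm(train, train, cfg)
        acc_test = classify_fbcsp_svm(train, test, cfg)
        assert acc_train >= acc_test - 1e-9

    def test_separable_synthetic_data_classified(self, small_synth):
        cfg = ClassifierConfig(m=2)
        train = EEGTrialSet(
            small_synth.data[::2], fs=small_synth.fs, labels=small_synth.labels[::2]
        )
        test = EEGTrialSet(
            small_synth.data[1::2], fs=small_synth.fs, labels=small_synth.labels[1::2]
        )
        assert classify_fbcsp_svm(train, test, cfg) > 80.0


class TestRepeatedKFold:
    def test_fold_count(self, small_synth):
        rep = repeated_kfold(
            small_synth, folds=4, repeats=2, cfg=ClassifierConfig(m=1,
            bank=build_filter_bank(8, 12, 4, 0)), seed=0,
        )
        assert len(rep.fold_accuracies) == 8
        assert 0 <= rep.mean_accuracy <= 100

    def test_each_trial_tested_once_per_repeat(self, small_synth):
        from sklearn.model_selection import RepeatedStratifiedKFold

        splitter = RepeatedStratifiedKFold(n_splits=4, n_repeats=3, random_state=0)
        counts = np.zeros(small_synth.n_trials, dtype=int)
        for _, test_idx in splitter.split(small_synth.data, small_synth.labels):
            counts[test_idx] += 1
        assert np.all(counts == 3)

    def test_two_folds_partition_trials(self, small_synth):
        from sklearn.model_selection import RepeatedStratifiedKFold

        splitter = RepeatedStratifiedKFold(n_splits=2, n_repeats=1, random_state=0)
        seen = []
        for _, test_idx in splitter.split(small_synth.data, small_synth.labels):
            seen.extend(test_idx)
        assert sorted(seen) == list(range(small_synth.n_trials))

    def test_too_few_trials_rejected(self, small_synth):
        with pytest.raises(ValueError, match="trials per class"):
            repeated_kfold(small_synth, folds=50, repeats=1)


class TestPairedTTest:
    def test_identical_vectors_give_zero_t(self):
        t, p = paired_ttest([60.0, 62.0, 64.0], [60.0, 62.0, 64.0])
        assert t == 0.0 or np.isnan(t)  # zero difference variance

    def test_textbook_hand_computation(self):
        # differences (1, 2, 3): t = mean/ (sd/sqrt(3)) = 2 / (1/sqrt(3))
        t, p = paired_ttest([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(2 * np.sqrt(3), rel=1e-6)
        assert 0 <= p <= 1

    def test_significance_flags(self):
        rep = EvalReport(np.array([60.0]), 60.0, p_value=0.03)
        assert rep.significance == "*"
        rep2 = EvalReport(np.array([60.0]), 60.0, p_value=0.005)
        assert rep2.significance == "**"
        rep3 = EvalReport(np.array([60.0]), 60.0, p_value=0.2)
        assert rep3.significance == ""

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            paired_ttest([1.0, 2.0], [1.0])


def _pair_of_sets(seed=0, delta=0.0, n=6, ch=3, T=128, fs=250.0):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n, ch, T))
    a = EEGTrialSet(base, fs=fs, labels=np.arange(n) % 2)
    b = EEGTrialSet(base + delta, fs=fs, labels=np.arange(n) % 2)
    return a, b


class TestErrorCurves:
    def test_identical_sets_zero_curve(self):
        a, b = _pair_of_sets()
        assert np.all(mean_temporal_error(a, a) == 0)

    def test_constant_offset_curve(self):
        a, b = _pair_of_sets(delta=0.7)
        curve = mean_temporal_error(a, b)
        assert curve.shape == (a.n_samples,)
        assert np.allclose(curve, 0.7)

    def test_shape_mismatch_rejected(self):
        a, _ = _pair_of_sets()
        short = EEGTrialSet(a.data[:, :, :64], fs=a.fs, labels=a.labels)
        with pytest.raises(ValueError, match="shapes"):
            mean_temporal_error(a, short)


class TestSpectraDifference:
    def test_identical_sets_zero(self):
        a, _ = _pair_of_sets()
        freqs, diff = mean_spectra_difference(a, a)
        assert np.abs(diff).max() < 1e-12
        assert freqs.min() >= 1.0 and freqs.max() <= 45.0

    def test_antisymmetric_under_argument_swap(self):
        a, b = _pair_of_sets(delta=0.3)
        _, d1 = mean_spectra_difference(a, b)
        _, d2 = mean_spectra_difference(b, a)
        assert np.allclose(d1, -d2)

    def test_boosted_tone_shows_up_at_its_frequency(self):
        fs, T = 250.0, 512
        t = np.arange(T) / fs
        tone = np.sin(2 * np.pi * 10 * t)
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 0.1, (4, 2, T))
        orig = EEGTrialSet(noise + tone, fs=fs, labels=[0, 1, 0, 1])
        recon = EEGTrialSet(noise + 2 * tone, fs=fs, labels=[0, 1, 0, 1])
        freqs, diff = mean_spectra_difference(orig, recon)
        assert freqs[np.argmax(diff)] == pytest.approx(10.0, abs=1.0)

    def test_rate_mismatch_rejected(self):
        a, _ = _pair_of_sets()
        b = EEGTrialSet(a.data, fs=125.0, labels=a.labels)
        with pytest.raises(ValueError, match="rates"):
            mean_spectra_difference(a, b)


class TestBeamMap:
    def _set(self, powers, fs=250.0, T=512):
        t = np.arange(T) / fs
        names = ["C3", "Cz", "C4", "Pz"]
        data = np.stack(
            [np.sqrt(p) * np.sin(2 * np.pi * 12 * t) for p in powers]
        )[None, :, :]
        return EEGTrialSet(data, fs=fs, labels=[0], channel_names=names)

    def test_uniform_power_gives_flat_map(self):
        ts = self._set([4.0, 4.0, 4.0, 4.0])
        gx, gy, gp, chan = beam_power_map(ts, freq=12.0)
        inside = ~np.isnan(gp)
        assert np.nanstd(gp[inside]) / np.nanmean(gp[inside]) < 0.05
        assert np.allclose(chan, chan[0], rtol=1e-6)

    def test_map_peaks_at_hot_channel(self):
        ts = self._set([0.1, 0.1, 9.0, 0.1])  # C4 hot
        gx, gy, gp, chan = beam_power_map(ts, freq=12.0)
        i, j = np.unravel_index(np.nanargmax(gp), gp.shape)
        from eegsr.evaluation import STANDARD_1020_POSITIONS

        x4, y4 = STANDARD_1020_POSITIONS["C4"]
        assert abs(gx[i, j] - x4) < 0.25 and abs(gy[i, j] - y4) < 0.25

    def test_missing_positions_rejected(self):
        ts = self._set([1.0, 1.0, 1.0, 1.0])
        ts.channel_names[0] = "NOPE"
        with pytest.raises(ValueError, match="NOPE"):
            beam_power_map(ts)
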