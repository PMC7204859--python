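"""Quantitative and qualitative comparison suite for reconstructions.

The quantitative yardstick is the motor-BCI standard pipeline: filter-bank
CSP features plus a linear support-vector machine, scored with repeated
stratified cross-validation and compared across signal variants with a
paired t-test.  Qualitative diagnostics are the mean temporal error curve,
the mean spectra difference, and scalp band-power maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import RBFInterpolator
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .features import CSP, FilterBank, _contrasts_for, bandpass, build_filter_bank, compute_psd
from .trialset import EEGTrialSet

__all__ = [
    "ClassifierConfig",
    "EvalReport",
    "FBCSPClassifier",
    "classify_fbcsp_svm",
    "repeated_kfold",
    "paired_ttest",
    "mean_temporal_error",
    "mean_spectra_difference",
    "beam_power_map",
    "STANDARD_1020_POSITIONS",
]


@dataclass
class ClassifierConfig:
    """FBCSP + SVM settings.

    ``g`` is recorded for completeness but inert under a linear kernel.
    """

    kernel: str = "linear"
    c: float = 0.01
    g: float = 2.0
    m: int = 4
    bank: FilterBank = field(default_factory=build_filter_bank)
    reg: float = 0.0

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("c must be positive")


@dataclass
class EvalReport:
    """Cross-validated accuracies plus optional paired-test statistics."""

    fold_accuracies: np.ndarray  # percent, one per fold
    mean_accuracy: float  # percent
    label: str = ""
    t_statistic: float | None = None
    p_value: float | None = None

    def __post_init__(self):
        acc = np.asarray(self.fold_accuracies, dtype=np.float64)
        if np.any((acc < 0) | (acc > 100)):
            raise ValueError("accuracies must lie in [0, 100]")
        if self.p_value is not None and not 0 <= self.p_value <= 1:
            raise ValueError("p-value must lie in [0, 1]")
        self.fold_accuracies = acc

    @property
    def significance(self) -> str:
        if self.p_value is None:
            return ""
        return "**" if self.p_value < 0.01 else "*" if self.p_value < 0.05 else ""


class FBCSPClassifier(BaseEstimator, ClassifierMixin):
    """Filter-bank CSP features with a linear SVM.

    Operates on raw trial arrays (n_trials, n_channels, n_samples); the
    sampling rate is a constructor argument because the filter bank needs it.
    Band-pass filtering, CSP fitting and the SVM fit all use training trials
    only.
    """

    def __init__(self, fs: float = 250.0, m: int = 4, bank: FilterBank | None = None,
                 C: float = 0.01, reg: float = 0.0):
        self.fs = fs
        self.m = m
        self.bank = bank
        self.C = C
        self.reg = reg

    def _bank(self) -> FilterBank:
        return self.bank if self.bank is not None else build_filter_bank()

    def _filter_bands(self, X) -> list[np.ndarray]:
        from scipy import signal as sps

        out = []
        for band in self._bank():
            sos = sps.butter(4, band, btype="bandpass", fs=self.fs, output="sos")
            out.append(sps.sosfiltfilt(sos, X, axis=-1))
        return out

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        return self.fit_banded(self._filter_bands(X), y)

    def fit_banded(self, Xb_list, y):
        """Fit from per-band filtered copies (band filtering is per-trial and
        label-free, so it may be shared across cross-validation folds)."""
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training set contains a single class")
        self.contrasts_ = _contrasts_for(y)
        self.models_ = []
        feats = []
        for Xb in Xb_list:
            for contrast in self.contrasts_:
                model = CSP(m=self.m, contrast=contrast, reg=self.reg)
                model.fit(Xb, y)
                self.models_.append(model)
                feats.append(model.transform(Xb))
        F = np.hstack(feats)
        self.svm_ = SVC(kernel="linear", C=self.C)
        self.svm_.fit(F, y)
        self.classes_ = self.svm_.classes_
        return self

    def _features_banded(self, Xb_list) -> np.ndarray:
        check_is_fitted(self, "svm_")
        feats, k = [], 0
        for Xb in Xb_list:
            for _ in self.contrasts_:
                feats.append(self.models_[k].transform(Xb))
                k += 1
        return np.hstack(feats)

    def predict(self, X):
        check_is_fitted(self, "svm_")
        X = np.asarray(X, dtype=np.float64)
        return self.svm_.predict(self._features_banded(self._filter_bands(X)))

    def predict_banded(self, Xb_list):
        return self.svm_.predict(self._features_banded(Xb_list))

    def score_percent(self, X, y) -> float:
        return 100.0 * float(np.mean(self.predict(X) == np.asarray(y)))


def classify_fbcsp_svm(
    train: EEGTrialSet, test: EEGTrialSet, cfg: ClassifierConfig | None = None
) -> float:
    """Train FBCSP+SVM on one set, return accuracy (percent) on another."""
    cfg = cfg or ClassifierConfig()
    if train.n_channels != test.n_channels:
        raise ValueError("channel layouts differ")
    clf = FBCSPClassifier(fs=train.fs, m=cfg.m, bank=cfg.bank, C=cfg.c, reg=cfg.reg)
    clf.fit(train.data, train.labels)
    return clf.score_percent(test.data, test.labels)


def repeated_kfold(
    ts: EEGTrialSet,
    folds: int = 8,
    repeats: int = 8,
    cfg: ClassifierConfig | None = None,
    seed: int = 0,
    label: str = "",
) -> EvalReport:
    """Stratified k-fold cross-validation repeated with reshuffling.

    Returns ``folds * repeats`` fold accuracies and their mean (percent).
    """
    cfg = cfg or ClassifierConfig()
    counts = np.bincount(np.unique(ts.labels, return_inverse=True)[1])
    if counts.min() < folds:
        raise ValueError(
            f"need at least {folds} trials per class, smallest class has {counts.min()}"
        )
    splitter = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=seed
    )
    proto = FBCSPClassifier(fs=ts.fs, m=cfg.m, bank=cfg.bank, C=cfg.c, reg=cfg.reg)
    banded = proto._filter_bands(ts.data)  # per-trial, label-free: shareable
    y = ts.labels
    accs = []
    for train_idx, test_idx in splitter.split(ts.data, y):
        clf = FBCSPClassifier(fs=ts.fs, m=cfg.m, bank=cfg.bank, C=cfg.c, reg=cfg.reg)
        clf.fit_banded([Xb[train_idx] for Xb in banded], y[train_idx])
        pred = clf.predict_banded([Xb[test_idx] for Xb in banded])
        accs.append(100.0 * float(np.mean(pred == y[test_idx])))
    accs = np.asarray(accs)
    return EvalReport(fold_accuracies=accs, mean_accuracy=float(accs.mean()), label=label)


def paired_ttest(acc_a, acc_b) -> tuple[float, float]:
    """Two-sided paired t-test between per-unit accuracy vectors."""
    acc_a = np.asarray(acc_a, dtype=np.float64)
    acc_b = np.asarray(acc_b, dtype=np.float64)
    if acc_a.shape != acc_b.shape:
        raise ValueError("accuracy vectors must have equal length")
    if len(acc_a) < 2:
        raise ValueError("need at least two paired observations")
    t, p = stats.ttest_rel(acc_a, acc_b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# qualitative diagnostics
# ---------------------------------------------------------------------------


def mean_temporal_error(orig: EEGTrialSet, recon: EEGTrialSet) -> np.ndarray:
    """Mean over trials and channels of (recon - orig) per time sample."""
    if orig.data.shape != recon.data.shape:
        raise ValueError("trial sets must have matching shapes")
    return (recon.data - orig.data).mean(axis=(0, 1))


def mean_spectra_difference(
    orig: EEGTrialSet, recon: EEGTrialSet, f_lo: float = 1.0, f_hi: float = 45.0
) -> tuple[np.ndarray, np.ndarray]:
    """Mean over trials/channels of PSD(recon) - PSD(orig) per frequency.

    Returns (freqs, difference) restricted to [f_lo, f_hi] Hz.
    """
    if orig.fs != recon.fs:
        raise ValueError("sampling rates differ")
    if orig.data.shape != recon.data.shape:
        raise ValueError("trial sets must have matching shapes")
    p_o = compute_psd(orig.data, orig.fs, nfft=max(256, orig.n_samples), window="hann")
    p_r = compute_psd(recon.data, recon.fs, nfft=max(256, recon.n_samples), window="hann")
    keep = (p_o.freqs >= f_lo) & (p_o.freqs <= f_hi)
    diff = (p_r.power - p_o.power).mean(axis=(0, 1))
    return p_o.freqs[keep], diff[keep]


# unit-disk 2-D projections of standard 10-20 electrode positions (x: right,
# y: front); enough coverage for scalp maps of the montages used here
STANDARD_1020_POSITIONS = {
    "Fp1": (-0.22, 0.72), "Fpz": (0.0, 0.75), "Fp2": (0.22, 0.72),
    "F7": (-0.59, 0.44), "F3": (-0.34, 0.41), "Fz": (0.0, 0.40),
    "F4": (0.34, 0.41), "F8": (0.59, 0.44),
    "FC5": (-0.55, 0.22), "FC1": (-0.19, 0.21), "FCz": (0.0, 0.20),
    "FC2": (0.19, 0.21), "FC6": (0.55, 0.22),
    "T7": (-0.73, 0.0), "C3": (-0.38, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.38, 0.0), "T8": (0.73, 0.0),
    "CP5": (-0.55, -0.22), "CP1": (-0.19, -0.21), "CPz": (0.0, -0.20),
    "CP2": (0.19, -0.21), "CP6": (0.55, -0.22),
    "P7": (-0.59, -0.44), "P3": (-0.34, -0.41), "Pz": (0.0, -0.40),
    "P4": (0.34, -0.41), "P8": (0.59, -0.44),
    "O1": (-0.22, -0.72), "Oz": (0.0, -0.75), "O2": (0.22, -0.72),
}


def beam_power_map(
    ts: EEGTrialSet,
    freq: float = 12.0,
    positions: dict | None = None,
    half_width: float = 1.0,
    grid_n: int = 64,
):
    """Scalp map of band power at ``freq`` +/- ``half_width`` Hz.

    Channel positions come from ``positions`` (name -> (x, y) on the unit
    head disk) or, by default, a bundled standard 10-20 table keyed by the
    set's channel names.  Power is interpolated onto a grid with a
    thin-plate radial basis; points outside the head circle are NaN.

    Returns (grid_x, grid_y, grid_power, channel_power).
    """
    table = positions if positions is not None else STANDARD_1020_POSITIONS
    missing = [c for c in ts.channel_names if c not in table]
    if missing:
        raise ValueError(f"no head positions for channels: {missing}")
    xy = np.array([table[c] for c in ts.channel_names], dtype=np.float64)

    spec = compute_psd(ts.data, ts.fs, nfft=max(256, ts.n_samples))
    band = (spec.freqs >= freq - half_width) & (spec.freqs <= freq + half_width)
    if not band.any():
        raise ValueError(f"no PSD bins inside {freq}+/-{half_width} Hz")
    df = spec.freqs[1] - spec.freqs[0]
    chan_power = spec.power[..., band].sum(axis=-1).mean(axis=0) * df  # (n_channels,)

    interp = RBFInterpolator(xy, chan_power, kernel="thin_plate_spline")
    g = np.linspace(-1.0, 1.0, grid_n)
    gx, gy = np.meshgrid(g, g)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    gp = interp(pts).reshape(grid_n, grid_n)
    # keep the map inside the head circle and near sensor support: radial
    # basis extrapolation far beyond the outermost electrode is unreliable
    r_max = min(1.0, np.sqrt((xy**2).sum(axis=1)).max() + 0.15)
    gp[gx**2 + gy**2 > r_max**2] = np.nan
    return gx, gy, gp, chan_power
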