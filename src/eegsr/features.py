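"""Feature extractors: filter bank, common spatial patterns, and PSD.

These feed two consumers with the same primitives: the spatial/frequency
terms of the generator's training loss, and the FBCSP+SVM evaluation
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, signal
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .trialset import EEGTrialSet

__all__ = [
    "FilterBank",
    "build_filter_bank",
    "bandpass",
    "CSP",
    "fit_csp",
    "csp_features",
    "PSDSpectrum",
    "PSDConfig",
    "compute_psd",
    "extract_fbcsp",
]


# ---------------------------------------------------------------------------
# filter bank
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterBank:
    """An ordered list of (lo, hi) band edges in Hz."""

    bands: tuple

    def __post_init__(self):
        for lo, hi in self.bands:
            if not lo < hi:
                raise ValueError(f"band ({lo}, {hi}) must satisfy lo < hi")

    def __len__(self):
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)


def build_filter_bank(
    lo: float = 8.0, hi: float = 30.0, width: float = 4.0, overlap: float = 2.0
) -> FilterBank:
    """Sliding sub-bands covering [lo, hi]: step = width - overlap.

    Defaults give the ten mu/beta sub-bands [8,12], [10,14], ..., [26,30].
    """
    if not width > overlap >= 0:
        raise ValueError("need width > overlap >= 0")
    if hi - lo < width:
        raise ValueError("band [lo, hi] narrower than one sub-band")
    step = width - overlap
    bands = []
    k = 0
    while True:
        b_lo = lo + k * step
        b_hi = b_lo + width
        if b_hi > hi + 1e-9:
            break
        bands.append((float(b_lo), float(b_hi)))
        k += 1
    return FilterBank(tuple(bands))


def bandpass(ts: EEGTrialSet, band) -> EEGTrialSet:
    """Zero-phase 4th-order Butterworth band-pass per channel."""
    lo, hi = band
    if hi >= ts.fs / 2.0:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist ({ts.fs / 2} Hz)")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=ts.fs, output="sos")
    return ts.with_data(signal.sosfiltfilt(sos, ts.data, axis=-1))


# ---------------------------------------------------------------------------
# common spatial patterns
# ---------------------------------------------------------------------------


def _trial_covariances(data: np.ndarray) -> np.ndarray:
    """Trace-normalized spatial covariance per trial (zero-mean convention:
    band-passed signals, second-moment covariance)."""
    cov = np.einsum("tcs,tds->tcd", data, data) / data.shape[-1]
    tr = np.trace(cov, axis1=1, axis2=2)
    return cov / tr[:, None, None]


class CSP(BaseEstimator, TransformerMixin):
    """Common spatial patterns for a two-sided class contrast.

    Fits spatial filters that extremize the variance ratio between the two
    sides of ``contrast`` via whitening of the composite covariance followed
    by an eigendecomposition of the whitened class covariance.  Keeps the
    ``m`` most and ``m`` least discriminative directions (2m filters).

    Attributes (after fit)
    ----------------------
    filters_ : ndarray (2m, n_channels)
        Projection matrix; first m rows favour the first side.
    eigenvalues_ : ndarray (2m,)
        Power ratios in [0, 1], first m largest, last m smallest.
    """

    def __init__(self, m: int = 4, contrast=None, reg: float = 0.0):
        self.m = m
        self.contrast = contrast
        self.reg = reg

    def fit(self, X, y):
        """X: (n_trials, n_channels, n_samples); y: trial labels."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        n_channels = X.shape[1]
        if 2 * self.m > n_channels:
            raise ValueError(f"2m={2 * self.m} exceeds channel count {n_channels}")
        if self.contrast is None:
            classes = np.unique(y)
            if len(classes) != 2:
                raise ValueError(
                    "contrast must be given explicitly for non-binary labels"
                )
            side_a = y == classes[0]
        elif np.isscalar(self.contrast):
            side_a = y == self.contrast  # one-vs-rest
        else:
            a, b = self.contrast
            keep = (y == a) | (y == b)
            X, y = X[keep], y[keep]
            side_a = y == a
        if side_a.sum() < 2 or (~side_a).sum() < 2:
            raise ValueError("need at least 2 trials on each side of the contrast")

        cov = _trial_covariances(X)
        c1 = cov[side_a].mean(axis=0)
        c2 = cov[~side_a].mean(axis=0)
        composite = c1 + c2
        if self.reg:
            composite = composite + self.reg * np.eye(n_channels)
        evals, evecs = np.linalg.eigh(composite)
        if evals[0] < 1e-10 * evals[-1]:
            raise np.linalg.LinAlgError(
                "composite covariance is rank deficient; consider the `reg` "
                "shrinkage parameter"
            )
        whiten = (evecs / np.sqrt(evals)).T  # P: P @ composite @ P.T = I
        s1 = whiten @ c1 @ whiten.T
        lam, u = np.linalg.eigh(s1)  # ascending in [0, 1]
        order = np.argsort(lam)[::-1]
        lam, u = lam[order], u[:, order]
        sel = np.r_[np.arange(self.m), np.arange(len(lam) - self.m, len(lam))]
        self.filters_ = (u[:, sel].T @ whiten)
        self.eigenvalues_ = np.clip(lam[sel], 0.0, 1.0)
        self.n_channels_ = n_channels
        return self

    def transform(self, X) -> np.ndarray:
        """Normalized log-variance features, (n_trials, 2m)."""
        check_is_fitted(self, "filters_")
        X = np.asarray(X, dtype=np.float64)
        single = X.ndim == 2
        if single:
            X = X[None]
        if X.shape[1] != self.n_channels_:
            raise ValueError(
                f"fitted on {self.n_channels_} channels, got {X.shape[1]}"
            )
        proj = np.einsum("fc,tcs->tfs", self.filters_, X)
        var = np.var(proj, axis=-1)  # central variance: shift/scale of the raw
        # amplitudes cancels in the normalized log features
        tot = var.sum(axis=-1, keepdims=True)
        if np.any(tot <= 0):
            raise ValueError("zero total variance in a trial")
        feats = np.log(var / tot)
        return feats[0] if single else feats


def fit_csp(ts: EEGTrialSet, contrast=None, m: int = 4, reg: float = 0.0) -> CSP:
    """Fit a CSP model on a trial set (thin wrapper over :class:`CSP`)."""
    return CSP(m=m, contrast=contrast, reg=reg).fit(ts.data, ts.labels)


def csp_features(model: CSP, trial: np.ndarray) -> np.ndarray:
    """Length-2m normalized log-variance feature vector of one trial."""
    return model.transform(trial)


# ---------------------------------------------------------------------------
# power spectral density
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSDSpectrum:
    """Per-channel power spectral density (uV^2/Hz) on a frequency grid."""

    freqs: np.ndarray
    power: np.ndarray  # (..., n_channels, n_freqs)


@dataclass(frozen=True)
class PSDConfig:
    """Periodogram settings used for short training patches: Hann window,
    zero-padding to ``nfft`` for frequency-grid stability on tau-length
    snippets."""

    nfft: int = 256
    window: str = "hann"


def compute_psd(
    segment: np.ndarray, fs: float, nfft: int | None = None, window: str = "hann"
) -> PSDSpectrum:
    """Hann-windowed periodogram density per channel.

    Satisfies Parseval within windowing tolerance: sum(power) * df ~ signal
    variance.  Short segments may be zero-padded to ``nfft``.
    """
    segment = np.asarray(segment, dtype=np.float64)
    T = segment.shape[-1]
    if T < 2:
        raise ValueError("need at least 2 samples for a PSD")
    nfft = max(nfft or T, T)
    freqs, power = signal.periodogram(
        segment, fs=fs, window=window, nfft=nfft, detrend=False, axis=-1
    )
    return PSDSpectrum(freqs=freqs, power=power)


# ---------------------------------------------------------------------------
# FBCSP
# ---------------------------------------------------------------------------


def _contrasts_for(labels: np.ndarray) -> list:
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("FBCSP needs at least two classes")
    if len(classes) == 2:
        return [(classes[0], classes[1])]
    return [int(c) if np.issubdtype(classes.dtype, np.integer) else c for c in classes]


def extract_fbcsp(
    train: EEGTrialSet,
    apply_to: EEGTrialSet,
    bank: FilterBank,
    m: int = 4,
    reg: float = 0.0,
):
    """Band-wise CSP features, fitted on ``train`` only.

    For a binary problem one CSP per band; for multi-class, one-vs-rest CSP
    per class per band.  Feature ordering is (band-major, contrast, then the
    2m filter outputs) and stable across calls.

    Returns (train_features, apply_features, fitted_models) with features of
    shape (n_trials, 2m * n_bands * n_contrasts).
    """
    if train.n_channels != apply_to.n_channels:
        raise ValueError("channel layouts differ between train and apply sets")
    contrasts = _contrasts_for(train.labels)
    f_train, f_apply, models = [], [], []
    for band in bank:
        tr_b = bandpass(train, band)
        ap_b = bandpass(apply_to, band)
        for contrast in contrasts:
            model = CSP(m=m, contrast=contrast, reg=reg).fit(tr_b.data, tr_b.labels)
            f_train.append(model.transform(tr_b.data))
            f_apply.append(model.transform(ap_b.data))
            models.append((band, contrast, model))
    return np.hstack(f_train), np.hstack(f_apply), models
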