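"""Source Power Comodulation (SPoC) spatial filtering and band-power features.

SPoC finds, per frequency band, the spatial filter w whose per-epoch
projected variance covaries maximally with a continuous, z-scored label.
With per-epoch channel covariances C_e, grand mean C and label-weighted
mean C_z = mean_e(z_e C_e), the filters solve the generalized symmetric
eigenproblem

    C_z w = lambda C w,

where lambda equals the covariance between the projected power w' C_e w and
z for w normalized to unit power (w' C w = 1). Only the component with the
largest |lambda| is kept — a deliberately parsimonious choice for small
epoch counts. The forward-model pattern a = C w / (w' C w) is the
interpretable scalp topography of the extracted source.

The per-band feature is the log-variance of the spatially filtered epoch, a
band-power estimate on an approximately Gaussian scale.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["epoch_covariances", "SpocFilter", "compute_pattern",
           "extract_features", "log_variance"]


def epoch_covariances(X: np.ndarray) -> np.ndarray:
    """Per-epoch channel covariances of (epochs x channels x samples) data.

    Channels are mean-centered within each epoch (removes DC offsets from
    filtering edge effects); the estimator divides by T - 1.
    """
    X = np.asarray(X, float)
    if not np.all(np.isfinite(X)):
        raise ValueError("epoch data contains non-finite values")
    Xc = X - X.mean(axis=2, keepdims=True)
    T = X.shape[2]
    return np.einsum("ect,edt->ecd", Xc, Xc) / (T - 1)


def compute_pattern(w: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Forward-model pattern a = C w / (w' C w).

    The filter is first normalized to unit projected power (w' C w = 1), so
    the result is invariant to positive rescaling of w.
    """
    w = np.asarray(w, float)
    w = w / np.sqrt(w @ C @ w)
    return C @ w


def log_variance(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-epoch log-variance of the spatially filtered signal."""
    y = np.einsum("c,ect->et", w, np.asarray(X, float))
    v = y.var(axis=1, ddof=1)
    return np.log(v)


class SpocFilter(BaseEstimator, TransformerMixin):
    """Single-component SPoC estimator for one frequency band.

    Parameters
    ----------
    shrinkage : float
        Ridge toward the scaled identity applied to the grand-mean
        covariance, C <- (1-g) C + g tr(C)/n I, for numerical invertibility.

    Attributes (after fit)
    ----------------------
    filter_ : (n_channels,) spatial filter, normalized to w' C w = 1 and
        sign-fixed so the largest-|.| pattern entry is positive.
    pattern_ : forward-model topography.
    eigenvalue_ : generalized eigenvalue of the kept component (signed).
    """

    def __init__(self, shrinkage: float = 1e-6):
        self.shrinkage = shrinkage

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SpocFilter":
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if X.ndim != 3 or len(y) != X.shape[0]:
            raise ValueError("X must be (epochs, channels, samples) aligned with y")
        sd = y.std()
        if sd == 0:
            raise ValueError("labels have zero variance")
        z = (y - y.mean()) / sd  # population z-score inside SPoC
        covs = epoch_covariances(X)
        C = covs.mean(axis=0)
        Cz = np.einsum("e,ecd->cd", z, covs) / len(z)
        n = C.shape[0]
        Creg = (1 - self.shrinkage) * C + self.shrinkage * (np.trace(C) / n) * np.eye(n)
        try:
            eigvals, eigvecs = scipy.linalg.eigh(Cz, Creg)
        except scipy.linalg.LinAlgError as exc:
            raise ValueError("grand-mean covariance singular beyond "
                             "regularization") from exc
        k = int(np.argmax(np.abs(eigvals)))
        w = eigvecs[:, k]
        w = w / np.sqrt(w @ Creg @ w)
        a = compute_pattern(w, C)
        if a[int(np.argmax(np.abs(a)))] < 0:
            w, a = -w, -a
        self.filter_ = w
        self.pattern_ = a
        self.eigenvalue_ = float(eigvals[k])
        self.mean_cov_ = C
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Log-variance feature of each epoch under the fitted filter."""
        X = np.asarray(X, float)
        if X.shape[1] != self.filter_.shape[0]:
            raise ValueError("channel count mismatch with fitted filter")
        return log_variance(X, self.filter_)


def extract_features(epochs, filters: dict[int, SpocFilter]) -> np.ndarray:
    """Epochs x bands feature matrix from per-band fitted SPoC filters.

    ``epochs`` is an EpochSet; filters must cover exactly its bands. Filters
    fitted on a training set are applied unchanged to hold-out epochs.
    """
    if set(filters) != set(epochs.bands):
        raise ValueError("filters do not match the epoch set's bands")
    cols = [filters[b].transform(epochs.bands[b]) for b in sorted(epochs.bands)]
    F = np.column_stack(cols)
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite feature values")
    return F
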