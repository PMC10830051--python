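"""Closed-form ridge regression with chronological sliding-window CV.

The penalty lambda is tuned on three overlapping, chronologically ordered
windows of the training set. Each window trains on its initial 55% and
validates on the remaining 45%; validation blocks of the three windows are
pairwise disjoint, so no sample is ever validated twice, and every window's
training samples precede its validation samples — respecting EEG
nonstationarity. The lambda minimizing the mean validation MAE (ties ->
smaller lambda) is used to refit on the full training set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["FeatureScaler", "RidgeDecoder", "SlidingWindowCV", "make_windows",
           "default_grid", "cross_validate_lambda", "CvReport", "mae"]


def default_grid(n: int = 25) -> np.ndarray:
    """Exponentially spaced penalty grid on [1e-1, 1e4]."""
    return np.logspace(-1, 4, n)


def mae(pred, y) -> float:
    pred, y = np.asarray(pred, float), np.asarray(y, float)
    if pred.shape != y.shape:
        raise ValueError("prediction/label length mismatch")
    return float(np.mean(np.abs(pred - y)))


class FeatureScaler(BaseEstimator):
    """Per-feature standardizer (training mean, population SD)."""

    def fit(self, X):
        X = np.asarray(X, float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0)
        if np.any(self.scale_ <= 0):
            raise ValueError("feature with zero variance")
        return self

    def transform(self, X):
        return (np.asarray(X, float) - self.mean_) / self.scale_


class RidgeDecoder(BaseEstimator, RegressorMixin):
    """Exact closed-form ridge with an unpenalized intercept.

    beta = (X' X + lambda I)^-1 X' (y - ybar) on (optionally standardized)
    features; the intercept is beta0 = ybar. ``standardize=True`` fits an
    internal FeatureScaler on the training features; pass False when the
    features are standardized externally (e.g. with a bundle's scaler).
    """

    def __init__(self, alpha: float = 1.0, standardize: bool = True):
        self.alpha = alpha
        self.standardize = standardize

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if X.ndim != 2 or len(y) != X.shape[0] or X.shape[0] < 2:
            raise ValueError("X must be 2-D with >= 2 rows aligned with y")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite inputs")
        self.scaler_ = FeatureScaler().fit(X) if self.standardize else None
        Xs = self.scaler_.transform(X) if self.scaler_ else X
        ybar = y.mean()
        p = Xs.shape[1]
        A = Xs.T @ Xs + self.alpha * np.eye(p)
        self.coef_ = np.linalg.solve(A, Xs.T @ (y - ybar))
        self.intercept_ = float(ybar)
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        if X.shape[1] != self.coef_.shape[0]:
            raise ValueError("feature count mismatch")
        Xs = self.scaler_.transform(X) if self.scaler_ else X
        return self.intercept_ + Xs @ self.coef_


def make_windows(n_train: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Three overlapping chronological windows of a training set.

    Window length L = floor(n/1.9) and stride S = floor(0.45 L) place
    windows at 0, S and 2S; within each, the first ceil(0.55 L) samples
    train and the rest validate. The last window's validation end is
    anchored to n so rounding remainders are absorbed. Validation blocks
    are pairwise disjoint because S + ceil(0.55 L) >= L.
    """
    n = int(n_train)
    if n < 20:
        raise ValueError(f"n_train={n} too small for sliding-window CV")
    L = 10 * n // 19  # floor(n / 1.9)
    S = 45 * L // 100
    tr = -(-55 * L // 100)  # ceil(0.55 L)
    windows = []
    for i in range(3):
        start = i * S
        end = n if i == 2 else start + L
        train = np.arange(start, start + tr)
        val = np.arange(start + tr, end)
        if len(val) == 0 or train[-1] >= n:
            raise ValueError(f"n_train={n} leaves an empty CV window")
        windows.append((train, val))
    return windows


class SlidingWindowCV:
    """sklearn-style splitter over the three chronological windows."""

    def split(self, X, y=None, groups=None):
        yield from make_windows(len(X))

    def get_n_splits(self, X=None, y=None, groups=None):
        return 3


@dataclass
class CvReport:
    grid: np.ndarray
    window_mae: np.ndarray  # 3 x len(grid)
    mean_mae: np.ndarray
    best_lambda: float
    best_index: int


def cross_validate_lambda(X, y, grid: np.ndarray | None = None) -> CvReport:
    """Tune lambda on the sliding windows.

    The feature scaler is refit on each window's training part; SPoC filters
    and label statistics are assumed fitted once on the full training set
    upstream (only lambda is tuned here).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if grid is None:
        grid = default_grid()
    windows = make_windows(len(y))
    surface = np.empty((len(windows), len(grid)))
    for wi, (tr, va) in enumerate(windows):
        for gi, lam in enumerate(grid):
            model = RidgeDecoder(alpha=lam, standardize=True).fit(X[tr], y[tr])
            surface[wi, gi] = mae(model.predict(X[va]), y[va])
    mean_mae = surface.mean(axis=0)
    best = int(np.argmin(mean_mae))  # ties resolve to the smaller lambda
    return CvReport(np.asarray(grid, float), surface, mean_mae,
                    float(grid[best]), best)
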