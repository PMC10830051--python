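"""Model interpretation: exact linear SHAP, importance summaries, patterns.

For a linear model with independent-feature (interventional) value function,
the Shapley value of feature b at input x is exactly

    phi_b(x) = beta_b * (x_b - mean background x_b)

in the model's standardized feature space, with base value the mean model
prediction over the training background. Additivity
base + sum_b phi_b = f(x) holds to machine precision.

Global importance is the per-participant mean |phi| per band; the group
summary is the median and MAD of those means across participants, plus a
band x band table of mean absolute pairwise importance differences.
Forward-model patterns are sign-indeterminate, so cross-participant
averaging first aligns each pattern's sign with the running mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ridge import RidgeDecoder

__all__ = ["ShapMatrix", "linear_shap", "ImportanceSummary",
           "summarize_importance", "average_patterns"]


@dataclass
class ShapMatrix:
    values: np.ndarray  # epochs x features
    base_value: float

    def predictions(self) -> np.ndarray:
        return self.base_value + self.values.sum(axis=1)


def linear_shap(model: RidgeDecoder, X_holdout: np.ndarray,
                X_background: np.ndarray) -> ShapMatrix:
    """Exact SHAP values of hold-out epochs against a training background.

    Inputs are in the same space the model consumes; if the model carries an
    internal feature scaler it is applied here, so contributions live in
    standardized feature space either way.
    """
    X_holdout = np.asarray(X_holdout, float)
    X_background = np.asarray(X_background, float)
    if X_background.size == 0:
        raise ValueError("empty background set")
    scaler = getattr(model, "scaler_", None)
    if scaler is not None:
        X_holdout = scaler.transform(X_holdout)
        X_background = scaler.transform(X_background)
    bg_mean = X_background.mean(axis=0)
    phi = model.coef_ * (X_holdout - bg_mean)
    base = float(model.intercept_ + model.coef_ @ bg_mean)
    return ShapMatrix(phi, base)


@dataclass
class ImportanceSummary:
    per_participant: np.ndarray  # participants x bands, mean |phi|
    group_median: np.ndarray
    group_mad: np.ndarray
    pairwise_diff: np.ndarray  # bands x bands


def summarize_importance(shap_matrices: list[ShapMatrix]) -> ImportanceSummary:
    """Aggregate per-participant mean-|SHAP| importances to the group level."""
    if not shap_matrices:
        raise ValueError("need at least one participant")
    m = np.vstack([np.abs(s.values).mean(axis=0) for s in shap_matrices])
    med = np.median(m, axis=0)
    mad = np.median(np.abs(m - med), axis=0)
    diff = np.abs(m[:, :, None] - m[:, None, :]).mean(axis=0)
    return ImportanceSummary(m, med, mad, diff)


def average_patterns(patterns: list[np.ndarray],
                     normalize: bool = True) -> np.ndarray:
    """Sign-aligned average of one band's patterns (unit-norm by default).

    Each participant's pattern is flipped, if needed, to correlate
    positively with the running mean before it is added. With
    ``normalize=False`` the raw aligned mean is returned, whose norm shrinks
    toward 0 when patterns are mutually unrelated.
    """
    if not patterns:
        raise ValueError("no patterns to average")
    n_ch = {np.asarray(p).shape for p in patterns}
    if len(n_ch) != 1:
        raise ValueError("montage mismatch across participants")
    acc = np.asarray(patterns[0], float).copy()
    for p in patterns[1:]:
        p = np.asarray(p, float)
        if acc @ p < 0:
            p = -p
        acc += p
    mean = acc / len(patterns)
    if not normalize:
        return mean
    norm = np.linalg.norm(mean)
    return mean / norm if norm > 0 else mean
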