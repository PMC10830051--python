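"""Model evaluation: intra/inter-individual transfer and the bootstrap test.

Intra-individual: the EEG model's hold-out MAE is compared with an
"RT model" baseline that predicts the training-set mean standardized
reaction time per angle — which is 0 by construction — for every hold-out
epoch. Both are also reported in milliseconds after inverting the label
transform.

Inter-individual: one participant's ridge coefficients predict another
participant's hold-out epochs. The "pre-processor bundle" (label scaler,
SPoC filters, feature scaler) used for feature extraction can come from the
train participant or from the test participant; swapping it isolates how
much transfer loss is due to person-specific scaling/topography rather than
the regression weights.

Differences across participants are tested with a percentile bootstrap
paired test (resampling participants with replacement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labels import LabelScaler, mae_ms
from .ridge import FeatureScaler, RidgeDecoder, CvReport, mae
from .spoc import SpocFilter, extract_features

__all__ = ["PreprocessorBundle", "ParticipantModel", "epoch_labels",
           "evaluate_intra", "evaluate_inter", "bootstrap_paired_test",
           "BootstrapResult"]


@dataclass
class PreprocessorBundle:
    """Person-specific pre-processors fitted on one training set."""

    label_scaler: LabelScaler
    spoc_filters: dict[int, SpocFilter]
    feature_scaler: FeatureScaler

    def validate(self) -> None:
        n_ch = {f.filter_.shape[0] for f in self.spoc_filters.values()}
        if len(n_ch) != 1:
            raise ValueError("inconsistent channel counts across band filters")
        if len(self.feature_scaler.mean_) != len(self.spoc_filters):
            raise ValueError("feature scaler does not match band count")


@dataclass
class ParticipantModel:
    """Fitted per-participant artifacts: bundle + ridge + CV report."""

    bundle: PreprocessorBundle
    ridge: RidgeDecoder  # fitted on externally standardized features
    cv_report: CvReport | None = None
    info: dict = field(default_factory=dict)


def epoch_labels(epochs, scaler: LabelScaler) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(z, rt_ms, angles) of an EpochSet under a label scaler."""
    rt = epochs.metadata["reaction_time_ms"].to_numpy(float)
    angles = epochs.metadata["angle"].to_numpy(float)
    return scaler.transform(rt, angles), rt, angles


def _predict(model: ParticipantModel, epochs,
             bundle: PreprocessorBundle) -> np.ndarray:
    F = extract_features(epochs, bundle.spoc_filters)
    return model.ridge.predict(bundle.feature_scaler.transform(F))


def evaluate_intra(model: ParticipantModel, holdout) -> dict[str, float]:
    """Hold-out MAEs of the EEG model and the RT baseline (z and ms)."""
    if holdout.n_epochs == 0:
        raise ValueError("empty hold-out set")
    scaler = model.bundle.label_scaler
    z, rt, angles = epoch_labels(holdout, scaler)
    pred = _predict(model, holdout, model.bundle)
    baseline = np.zeros_like(z)  # training-set mean standardized RT per angle
    return {
        "mae_eeg": mae(pred, z),
        "mae_baseline": mae(baseline, z),
        "mae_eeg_ms": mae_ms(pred, rt, angles, scaler),
        "mae_baseline_ms": mae_ms(baseline, rt, angles, scaler),
    }


def evaluate_inter(train_model: ParticipantModel,
                   test_model: ParticipantModel, test_holdout,
                   bundle_source: str = "train") -> float:
    """MAE of the train participant's ridge on the test participant's data.

    ``bundle_source`` selects whose pre-processors extract features and
    standardize the labels ("train" or "test"). With bundle_source="train"
    and test == train participant this reduces exactly to the intra MAE.
    """
    if bundle_source not in ("train", "test"):
        raise ValueError("bundle_source must be 'train' or 'test'")
    bundle = (train_model if bundle_source == "train" else test_model).bundle
    n_train = next(iter(train_model.bundle.spoc_filters.values())).filter_.shape[0]
    n_test = next(iter(bundle.spoc_filters.values())).filter_.shape[0]
    if n_train != n_test or set(train_model.bundle.spoc_filters) != set(
            bundle.spoc_filters):
        raise ValueError("channel/band mismatch between participants")
    z, _, _ = epoch_labels(test_holdout, bundle.label_scaler)
    pred = _predict(train_model, test_holdout, bundle)
    return mae(pred, z)


@dataclass
class BootstrapResult:
    mean_diff: float
    ci_low: float
    ci_high: float
    p_value: float
    iterations: int
    seed: int


def bootstrap_paired_test(a, b, iterations: int = 9999,
                          seed: int = 0) -> BootstrapResult:
    """Percentile-bootstrap paired test of mean(a - b) != 0.

    Participants are resampled with replacement; the two-sided p-value uses
    the +1 small-sample correction
    p = 2 min(#{mean d* <= 0} + 1, #{mean d* >= 0} + 1) / (iterations + 1),
    capped at 1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    n = len(a)
    if n < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(iterations, n))
    means = d[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    p = 2 * min((means <= 0).sum() + 1, (means >= 0).sum() + 1) / (iterations + 1)
    return BootstrapResult(float(d.mean()), float(lo), float(hi),
                           float(min(p, 1.0)), iterations, seed)
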