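"""Reaction-time label transforms.

Reaction times are log-transformed (they are positively skewed) and
standardized per angular disparity, because raw RT mixes task difficulty
with trial-to-trial fluctuation: 800 ms is slow at 0 deg but fast at
150 deg. Statistics are always fitted on training epochs only and applied
unchanged to validation/hold-out epochs.

Outliers are removed from the *training* labels with the 2.5 x MAD rule on
log RT per angle (unscaled MAD, no 1.4826 consistency factor; MAD = 0
removes nothing).
"""

from __future__ import annotations

import json
import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["LabelScaler", "mad_outlier_mask", "mae_ms"]


class LabelScaler(BaseEstimator, TransformerMixin):
    """Per-angle standardizer of log reaction times.

    fit(rt_ms, angles) learns mean and population SD (denominator n) of
    log RT for each angle; transform maps RT to z; inverse_transform maps z
    back to milliseconds exactly.
    """

    def fit(self, rt_ms, angles):
        rt_ms = np.asarray(rt_ms, float)
        angles = np.asarray(angles, float)
        if rt_ms.shape != angles.shape:
            raise ValueError("rt_ms and angles length mismatch")
        if np.any(rt_ms <= 0) or not np.all(np.isfinite(rt_ms)):
            raise ValueError("reaction times must be positive and finite")
        log_rt = np.log(rt_ms)
        self.mean_, self.scale_ = {}, {}
        for a in np.unique(angles):
            x = log_rt[angles == a]
            if len(x) < 2:
                raise ValueError(f"angle {a} has fewer than 2 epochs")
            sd = x.std()  # population SD
            if sd == 0:
                raise ValueError(f"angle {a} has zero label variance")
            self.mean_[float(a)] = float(x.mean())
            self.scale_[float(a)] = float(sd)
        return self

    def _check(self, angles):
        angles = np.asarray(angles, float)
        unseen = set(np.unique(angles)) - set(self.mean_)
        if unseen:
            raise ValueError(f"angles not seen during fit: {sorted(unseen)}")
        return angles

    def transform(self, rt_ms, angles):
        angles = self._check(angles)
        rt_ms = np.asarray(rt_ms, float)
        mu = np.array([self.mean_[a] for a in angles])
        sd = np.array([self.scale_[a] for a in angles])
        return (np.log(rt_ms) - mu) / sd

    def inverse_transform(self, z, angles):
        angles = self._check(angles)
        z = np.asarray(z, float)
        mu = np.array([self.mean_[a] for a in angles])
        sd = np.array([self.scale_[a] for a in angles])
        return np.exp(z * sd + mu)

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean_, "scale": self.scale_})

    @classmethod
    def from_json(cls, text: str) -> "LabelScaler":
        d = json.loads(text)
        s = cls()
        s.mean_ = {float(k): v for k, v in d["mean"].items()}
        s.scale_ = {float(k): v for k, v in d["scale"].items()}
        return s


def mad_outlier_mask(rt_ms, angles, threshold: float = 2.5) -> np.ndarray:
    """Retention mask under the per-angle 2.5 x MAD rule on log RT.

    An epoch is dropped when |log RT - median| > threshold * MAD within its
    angle group, with MAD the unscaled median absolute deviation. A zero MAD
    (e.g. many tied values) disables removal for that group. Warns if more
    than half of a group would be dropped, then proceeds.
    """
    rt_ms = np.asarray(rt_ms, float)
    angles = np.asarray(angles, float)
    x = np.log(rt_ms)
    keep = np.ones(len(x), bool)
    for a in np.unique(angles):
        g = angles == a
        med = np.median(x[g])
        mad = np.median(np.abs(x[g] - med))
        if mad == 0:
            continue
        drop = np.abs(x - med) > threshold * mad
        keep[g & drop] = False
        if (g & drop).sum() > 0.5 * g.sum():
            warnings.warn(f"MAD rule removed more than half of angle {a} "
                          "epochs", stacklevel=2)
    return keep


def mae_ms(z_pred, rt_true_ms, angles, scaler: LabelScaler) -> float:
    """MAE in milliseconds of back-transformed standardized predictions."""
    pred_ms = scaler.inverse_transform(z_pred, angles)
    return float(np.mean(np.abs(pred_ms - np.asarray(rt_true_ms, float))))
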