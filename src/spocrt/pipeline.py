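"""End-to-end orchestration: simulate -> preprocess -> fit -> evaluate -> interpret.

``run_full`` executes the whole study design for a cohort of simulated
participants: per-participant fitting (chronological 75/25 split, MAD
outlier removal on the training labels, per-band SPoC, sliding-window
lambda tuning, final ridge), the intra- and inter-individual evaluation
matrix with pre-processor swapping, the bootstrap paired test, SHAP
importance summaries and cross-participant pattern averaging. All
randomness derives from one seed; identical configs produce byte-identical
reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import (ParticipantModel, PreprocessorBundle,
                         bootstrap_paired_test, epoch_labels, evaluate_inter,
                         evaluate_intra)
from .interpretation import average_patterns, linear_shap, summarize_importance
from .labels import LabelScaler, mad_outlier_mask
from .preprocess import DEFAULT_CENTERS, EpochSet, preprocess_session
from .ridge import FeatureScaler, RidgeDecoder, cross_validate_lambda, default_grid
from .simdata import BlinkSpec, RTModel, SimConfig, SourceSpec, simulate_participant
from .spoc import SpocFilter, extract_features

__all__ = ["RunConfig", "fit_participant", "run_full", "CohortReport"]

log = logging.getLogger("spocrt")

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}


@dataclass
class RunConfig:
    """Validated configuration for a full cohort run."""

    n_participants: int = 20
    seed: int = 0
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    ica_mode: str = "auto"  # auto | list | none
    ica_reject: list[int] | None = None
    band_centers: tuple[float, ...] = DEFAULT_CENTERS
    grid_size: int = 25
    holdout_fraction: float = 0.25
    bootstrap_iterations: int = 9999
    share_topographies: bool = False
    comodulation: float = 0.8
    comodulation_band: float = 10.0

    def __post_init__(self) -> None:
        unknown = set(self.sim) - _SIM_FIELDS
        if unknown:
            raise ValueError(f"unknown sim config keys: {sorted(unknown)}")
        if self.ica_mode not in ("auto", "list", "none"):
            raise ValueError(f"invalid ica_mode: {self.ica_mode}")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "band_centers" in data:
            data["band_centers"] = tuple(data["band_centers"])
        return cls(**data)

    def sim_config(self, participant: int) -> SimConfig:
        """Per-participant SimConfig with a derived seed substream."""
        seed_p = int(np.random.SeedSequence([self.seed, participant])
                     .generate_state(1)[0] % (2**31))
        kwargs = dict(self.sim)
        if "rt_model" in kwargs and isinstance(kwargs["rt_model"], dict):
            kwargs["rt_model"] = RTModel(**kwargs["rt_model"])
        if "blink" in kwargs and isinstance(kwargs["blink"], dict):
            kwargs["blink"] = BlinkSpec(**kwargs["blink"])
        cfg = SimConfig(seed=seed_p, **kwargs)
        rng_topo = np.random.default_rng(
            self.seed if self.share_topographies else seed_p)
        topo = rng_topo.standard_normal(cfg.n_channels)
        topo /= np.linalg.norm(topo)
        if cfg.source_specs is None:
            cfg.source_specs = [SourceSpec(band_center=self.comodulation_band,
                                           comodulation=self.comodulation,
                                           topography=topo)]
        return cfg


def fit_participant(epochs: EpochSet, holdout_fraction: float = 0.25,
                    grid: np.ndarray | None = None
                    ) -> tuple[ParticipantModel, EpochSet, EpochSet]:
    """Fit one participant; returns (model, retained train set, hold-out set).

    Chronological split at floor((1 - holdout_fraction) * n); MAD outlier
    removal applies to training labels only; label scaler, SPoC filters and
    feature scaler are fitted once on the retained training epochs; the
    sliding-window CV tunes lambda only.
    """
    n = epochs.n_epochs
    split = int(np.floor((1 - holdout_fraction) * n))
    if split < 2 or split >= n:
        raise ValueError(f"cannot split {n} epochs into train/hold-out")
    train = epochs.select(np.arange(split))
    holdout = epochs.select(np.arange(split, n))

    rt = train.metadata["reaction_time_ms"].to_numpy(float)
    angles = train.metadata["angle"].to_numpy(float)
    keep = mad_outlier_mask(rt, angles)
    kept = train.select(np.where(keep)[0])
    log.info("outlier removal: %d of %d training epochs dropped",
             int((~keep).sum()), len(keep))

    scaler = LabelScaler().fit(kept.metadata["reaction_time_ms"].to_numpy(float),
                               kept.metadata["angle"].to_numpy(float))
    z, _, _ = epoch_labels(kept, scaler)

    filters = {b: SpocFilter().fit(kept.bands[b], z) for b in sorted(kept.bands)}
    F = extract_features(kept, filters)
    if grid is None:
        grid = default_grid()
    cv = cross_validate_lambda(F, z, grid)
    fscaler = FeatureScaler().fit(F)
    ridge = RidgeDecoder(alpha=cv.best_lambda, standardize=False)
    ridge.fit(fscaler.transform(F), z)

    bundle = PreprocessorBundle(scaler, filters, fscaler)
    bundle.validate()
    info = {"n_train": int(kept.n_epochs), "n_holdout": int(holdout.n_epochs),
            "n_outliers": int((~keep).sum()),
            "removal_counts": dict(epochs.removal_counts)}
    return ParticipantModel(bundle, ridge, cv, info), kept, holdout


@dataclass
class CohortReport:
    evaluation: pd.DataFrame  # tidy: participant, metric, scope, bundle_source, value
    bootstrap: dict
    importance: dict
    patterns: dict[int, np.ndarray]
    summary: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.evaluation.to_csv(out / "evaluation.tsv", sep="\t", index=False)
        imp = self.importance
        bands = list(range(len(imp["group_median"])))
        pd.DataFrame({
            "band": bands,
            "group_median_abs_shap": imp["group_median"],
            "group_mad_abs_shap": imp["group_mad"],
        }).to_csv(out / "importance.tsv", sep="\t", index=False)
        pd.DataFrame(imp["pairwise_diff"]).to_csv(
            out / "importance_pairwise.tsv", sep="\t", index=False)
        pat = pd.DataFrame({f"band_{b:02d}": v for b, v in self.patterns.items()})
        pat.to_csv(out / "mean_patterns.tsv", sep="\t", index=False)
        payload = {"bootstrap": self.bootstrap, "summary": self.summary}
        (out / "summary.json").write_text(json.dumps(payload, indent=2,
                                                     sort_keys=True))


def run_full(config: RunConfig, out_dir=None) -> CohortReport:
    """Execute the full study design for a simulated cohort."""
    models, holdouts, backgrounds = [], [], []
    rows = []
    for p in range(config.n_participants):
        try:
            cfg = config.sim_config(p)
            log.info("participant %d: simulate (seed %d)", p, cfg.seed)
            task, rest = simulate_participant(cfg)
            epochs = preprocess_session(
                task, rest if config.ica_mode != "none" else None,
                ica_reject=config.ica_reject, ica_mode=config.ica_mode,
                centers=config.band_centers, seed=cfg.seed)
            log.info("participant %d: removal counts %s", p,
                     epochs.removal_counts)
            model, kept, holdout = fit_participant(
                epochs, holdout_fraction=config.holdout_fraction,
                grid=default_grid(config.grid_size))
        except Exception as exc:
            raise RuntimeError(
                f"stage failure for participant {p}: {exc}") from exc
        models.append(model)
        holdouts.append(holdout)
        backgrounds.append(extract_features(kept, model.bundle.spoc_filters))
        intra = evaluate_intra(model, holdout)
        for metric, value in intra.items():
            rows.append((p, metric, "intra", "train", value))

    # inter-individual matrix under both bundle sources
    inter = {"train": np.full((len(models), len(models)), np.nan),
             "test": np.full((len(models), len(models)), np.nan)}
    if len(models) > 1:
        for i, train_model in enumerate(models):
            for j, test_model in enumerate(models):
                if i == j:
                    continue
                for src in ("train", "test"):
                    inter[src][i, j] = evaluate_inter(
                        train_model, test_model, holdouts[j], bundle_source=src)
        for src in ("train", "test"):
            per_train = np.nanmean(inter[src], axis=1)
            for i, v in enumerate(per_train):
                rows.append((i, "mae_eeg", "inter", src, float(v)))

    ev = pd.DataFrame(rows, columns=["participant", "metric", "scope",
                                     "bundle_source", "value"])

    intra_eeg = ev.query("metric == 'mae_eeg' and scope == 'intra'")\
        .sort_values("participant")["value"].to_numpy()
    intra_base = ev.query("metric == 'mae_baseline' and scope == 'intra'")\
        .sort_values("participant")["value"].to_numpy()
    boot = None
    if len(models) >= 5:
        boot = bootstrap_paired_test(intra_eeg, intra_base,
                                     iterations=config.bootstrap_iterations,
                                     seed=config.seed)

    shap_list = []
    for model, holdout, bg in zip(models, holdouts, backgrounds):
        F = extract_features(holdout, model.bundle.spoc_filters)
        shap_list.append(linear_shap(
            model.ridge, model.bundle.feature_scaler.transform(F),
            model.bundle.feature_scaler.transform(bg)))
    imp = summarize_importance(shap_list)

    bands = sorted(models[0].bundle.spoc_filters)
    patterns = {b: average_patterns([m.bundle.spoc_filters[b].pattern_
                                     for m in models]) for b in bands}

    summary = {
        "n_participants": len(models),
        "mean_intra_mae_eeg": float(np.mean(intra_eeg)),
        "mean_intra_mae_baseline": float(np.mean(intra_base)),
        "fraction_eeg_beats_baseline": float(np.mean(intra_eeg < intra_base)),
        "median_lambda": float(np.median([m.ridge.alpha for m in models])),
        "mean_intra_mae_eeg_ms": float(ev.query(
            "metric == 'mae_eeg_ms' and scope == 'intra'")["value"].mean()),
        "mean_intra_mae_baseline_ms": float(ev.query(
            "metric == 'mae_baseline_ms' and scope == 'intra'")["value"].mean()),
    }
    if len(models) > 1:
        summary["mean_inter_mae_train_bundle"] = float(
            np.nanmean(inter["train"]))
        summary["mean_inter_mae_test_bundle"] = float(np.nanmean(inter["test"]))
    report = CohortReport(
        evaluation=ev,
        bootstrap=dataclasses.asdict(boot) if boot else {},
        importance={"per_participant": imp.per_participant.tolist(),
                    "group_median": imp.group_median.tolist(),
                    "group_mad": imp.group_mad.tolist(),
                    "pairwise_diff": imp.pairwise_diff.tolist()},
        patterns=patterns,
        summary=summary,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
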