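"""End-to-end runs: extract → normalize → estimate every method → compare.

The canonical workflow mirrors how an array would be characterized for one
substance: take the (reference-corrected) feature matrix, z-score it, pick
the Student-t detection multiplier from the blank count, choose PCR/PLSR
component counts by repeated stratified CV, then produce the full method ×
deviation grid of LOD and LOQ estimates — seven LOD columns (PCA I with
s_blank only; PCA II, PCR and PLSR each with s_blank and RMSE) plus the
matching LOQ row — and a comparison table of the estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import features, io, surrogate, synthetic
from .errors import ConfigurationError
from .features import FeatureMatrix
from .limits import KFactorSpec, LimitEstimate, k_factor, loq_factor

DEFAULT_METHODS = ("PCA_I", "PCA_II", "PCR", "PLSR")
DEFAULT_DEVIATIONS = ("s_blank", "rmse")


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    # input: either a feature table, day recordings + annotations, or a simulation
    feature_table: str | None = None
    day_files: list[str] = field(default_factory=list)
    annotation_file: str | None = None
    schedule: list[tuple[str, float]] = field(default_factory=lambda: list(io.DEFAULT_SCHEDULE))
    simulate: bool = False
    sim_model: dict = field(default_factory=dict)
    sim_design: dict = field(default_factory=dict)
    # estimation
    methods: tuple[str, ...] = DEFAULT_METHODS
    deviations: tuple[str, ...] = DEFAULT_DEVIATIONS
    alpha: float = 0.05
    beta: float = 0.05
    k_distribution: str = "student_t"
    leverage_variant: str = "as_printed"
    include_loq: bool = True
    cv_folds: int = 5
    cv_repeats: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        bad = [m for m in cfg.methods if m not in DEFAULT_METHODS]
        if bad:
            raise ConfigurationError(
                f"unknown methods {bad}; valid methods are {list(DEFAULT_METHODS)}"
            )
        return cfg


@dataclass
class PipelineResult:
    """Estimates, comparison table and provenance of one run."""

    estimates: list[LimitEstimate]
    table: pd.DataFrame
    provenance: dict
    feature_matrix: FeatureMatrix

    def records(self) -> list[dict]:
        return [e.to_dict() for e in self.estimates]


def _load_features(cfg: RunConfig) -> FeatureMatrix:
    if cfg.simulate:
        model = synthetic.SensorModelSpec(**cfg.sim_model)
        design = synthetic.StudyDesign(seed=cfg.seed, **cfg.sim_design)
        raw = synthetic.simulate_features(model, design)
        return features.subtract_ethanol_reference(raw)
    if cfg.feature_table:
        return features.read_feature_table(cfg.feature_table)
    if cfg.day_files and cfg.annotation_file:
        ann = io.read_annotations(cfg.annotation_file)
        cycles = []
        for day, path in enumerate(cfg.day_files, start=1):
            rec = io.load_day_recording(path, day=day)
            cycles.extend(io.segment_cycles(rec, cfg.schedule, annotations=ann))
        return features.extract_features(cycles, features.WindowSpec())
    raise ConfigurationError("config names no input: set feature_table, day_files or simulate")


def resolve_k(cfg: RunConfig, n_blanks: int) -> KFactorSpec:
    if cfg.k_distribution == "student_t":
        return k_factor(cfg.alpha, cfg.beta, "student_t", n_blanks=n_blanks)
    return k_factor(cfg.alpha, cfg.beta, "normal")


def estimate_all(
    fm: FeatureMatrix,
    k: KFactorSpec,
    methods: tuple[str, ...] = DEFAULT_METHODS,
    deviations: tuple[str, ...] = DEFAULT_DEVIATIONS,
    leverage_variant: str = "as_printed",
    include_loq: bool = True,
    cv_folds: int = 5,
    cv_repeats: int = 10,
    seed: int = 0,
) -> tuple[list[LimitEstimate], dict]:
    """Run every requested method × deviation for LOD (and LOQ).

    ``fm`` must already be z-score normalized. Returns the estimates plus a
    provenance dict (chosen component counts, seeds, k factor).
    """
    estimates: list[LimitEstimate] = []
    provenance: dict[str, Any] = {
        "k": k.value, "k_distribution": k.distribution, "seed": seed,
        "leverage_variant": leverage_variant, "n_samples": fm.n_samples,
        "n_blanks": int(fm.is_blank.sum()),
    }
    k_specs = [k] + ([loq_factor()] if include_loq else [])

    pc1 = None
    if "PCA_I" in methods or "PCA_II" in methods:
        pc1 = surrogate.pc1_surrogate(fm)
        provenance["explained_variance_pc1"] = pc1.explained_variance_pc1
    n_comp: dict[str, int] = {}
    for model in ("PCR", "PLSR"):
        if model in methods:
            report = surrogate.select_n_components(
                fm, model=model, folds=cv_folds, repeats=cv_repeats, seed=seed
            )
            n_comp[model] = report.chosen
            provenance[f"n_components_{model}"] = report.chosen
            provenance[f"cv_rmse_{model}"] = report.mean_rmse[report.chosen]

    for spec in k_specs:
        for method in methods:
            if method == "PCA_I":
                estimates.append(surrogate.pca_threshold_lod(pc1, spec))
                continue
            for dev in deviations:
                if method == "PCA_II":
                    estimates.append(
                        surrogate.pca_calibration_lod(
                            pc1, spec, deviation=dev, leverage_variant=leverage_variant
                        )
                    )
                else:
                    estimates.append(
                        surrogate.regression_surrogate_lod(
                            fm, method, n_comp[method], spec,
                            deviation=dev, leverage_variant=leverage_variant,
                        )
                    )
    return estimates, provenance


def comparison_table(estimates: list[LimitEstimate], substance: str = "") -> pd.DataFrame:
    """Method × deviation table of formatted limits, one row per kind.

    Mirrors the conventional report layout: columns PCA I (s_blank),
    PCA II / PCR / PLSR each with s_blank and RMSE; invalid estimates are
    annotated with an asterisk.
    """
    cells: dict[tuple[str, str], dict[str, str]] = {}
    for est in estimates:
        col = (est.method, est.deviation)
        text = est.formatted()
        if not est.valid:
            text += " *"
        cells.setdefault(col, {})[est.kind] = text
    table = pd.DataFrame(cells)
    table.index.name = "kind"
    if substance:
        table.insert(0, ("substance", ""), substance)
    return table


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Configuration-driven end-to-end run; deterministic given ``cfg.seed``."""
    fm = _load_features(cfg)
    if fm.normalization is None:
        fm = features.zscore_normalize(fm)
    k = resolve_k(cfg, n_blanks=int(fm.is_blank.sum()))
    estimates, provenance = estimate_all(
        fm, k, methods=tuple(cfg.methods), deviations=tuple(cfg.deviations),
        leverage_variant=cfg.leverage_variant, include_loq=cfg.include_loq,
        cv_folds=cfg.cv_folds, cv_repeats=cfg.cv_repeats, seed=cfg.seed,
    )
    provenance["config"] = {
        key: value for key, value in asdict(cfg).items()
        if not isinstance(value, (list, dict)) or value
    }
    substance = str(fm.annotations["substance"].iloc[0]) if fm.n_samples else ""
    table = comparison_table(estimates, substance=substance)
    return PipelineResult(estimates=estimates, table=table,
                          provenance=provenance, feature_matrix=fm)
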