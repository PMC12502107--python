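"""End-to-end study pipeline: simulate or load spectra, preprocess, split,
fit the model menu, validate, and write reports.

All randomness flows from one pipeline seed through named sub-streams
(simulator, ga, mccv), so a run is a pure function of (input data, config,
seed).
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

from . import io as gio
from .classifiers import fit_pca, pca_transform
from .dataset import GROUPS, AcquisitionGrid
from .ga import GAConfig, galda_to_dict
from .menu import GALDA, FixedSelectionLDA, build_model
from .preprocess import PreprocessConfig, mean_center, run_preprocessing
from .split import SplitConfig, split
from .stats import report_selected_variables
from .synthetic import CohortConfig, simulate_cohort
from .validation import (MCCVConfig, external_test, leave_one_patient_out_cv,
                         metrics_from_confusion, monte_carlo_cv, confusion)

log = logging.getLogger("galda")

DEFAULT_MODELS = ("pca_lda", "pca_qda", "pls_da", "svm", "ga_lda")


@dataclass
class PipelineConfig:
    input: str = "simulate"            # "simulate" or a spectra file path
    grid: AcquisitionGrid = field(default_factory=AcquisitionGrid)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    ga: GAConfig = field(default_factory=GAConfig.smoke)
    mccv: MCCVConfig = field(default_factory=lambda: MCCVConfig(n_iterations=100))
    models: tuple = ("ga_lda",)
    output_dir: str = "galda_run"
    seed: int = 7
    log_level: str = "INFO"
    full_scale: bool = False          # full-scale GA (200x400) and 1000-iter MCCV
    nested_cv: bool = False            # refit GA selection inside every CV fold
    annotation_tolerance: float = 0.03

    def resolved(self) -> "PipelineConfig":
        """Apply the full-scale switch and propagate named sub-seeds."""
        cfg = dataclasses.replace(self)
        seeds = derive_seeds(cfg.seed)
        cfg.cohort = dataclasses.replace(cfg.cohort, seed=seeds["simulator"])
        ga_kwargs = dataclasses.asdict(cfg.ga)
        ga_kwargs["seed"] = seeds["ga"]
        if cfg.full_scale:
            ga_kwargs.update(n_generations=200, population_size=400)
            cfg.mccv = dataclasses.replace(cfg.mccv, n_iterations=1000,
                                           seed=seeds["mccv"])
        else:
            cfg.mccv = dataclasses.replace(cfg.mccv, seed=seeds["mccv"])
        cfg.ga = GAConfig(**ga_kwargs)
        return cfg


def derive_seeds(seed: int) -> dict:
    """Named 31-bit sub-seeds derived from the single pipeline seed."""
    names = ("simulator", "ga", "mccv")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: int(child.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
            for name, child in zip(names, children)}


def config_from_yaml(path) -> PipelineConfig:
    payload = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(payload)


def config_from_dict(payload: dict) -> PipelineConfig:
    kwargs = dict(payload)
    if "grid" in kwargs:
        kwargs["grid"] = AcquisitionGrid(**kwargs["grid"])
    if "cohort" in kwargs:
        c = dict(kwargs["cohort"])
        if "water_band" in c and isinstance(c["water_band"], dict):
            from .synthetic import WaterBand
            c["water_band"] = WaterBand(**c["water_band"])
        kwargs["cohort"] = CohortConfig(**c)
    if "preprocess" in kwargs:
        kwargs["preprocess"] = PreprocessConfig(**kwargs["preprocess"])
    if "split" in kwargs:
        kwargs["split"] = SplitConfig(**kwargs["split"])
    if "ga" in kwargs:
        kwargs["ga"] = GAConfig(**kwargs["ga"])
    if "mccv" in kwargs:
        kwargs["mccv"] = MCCVConfig(**kwargs["mccv"])
    if "models" in kwargs:
        kwargs["models"] = tuple(kwargs["models"])
    return PipelineConfig(**kwargs)


def _config_echo(cfg: PipelineConfig) -> dict:
    def conv(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: conv(v) for k, v in obj.items()}
        if isinstance(obj, (tuple, list)):
            return [conv(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return obj
    return conv(cfg)


def _metrics_payload(metrics) -> dict:
    return {
        "AC": metrics.AC, "SENS": metrics.SENS, "SPEC": metrics.SPEC,
        "per_class": metrics.per_class, "averaging": metrics.averaging,
    }


def _fit_factory(name: str, cfg: PipelineConfig, fitted):
    """Per-fold refitting rule for cross-validation.

    Selection-fixed mode (default) freezes the data-driven structure chosen
    on the training partition — GA-selected variables, PCA/PLS component
    counts — and refits only the classifier per fold.  Nested mode reruns
    GA selection inside every fold (slow, unbiased).
    """
    if name == "ga_lda":
        if cfg.nested_cv:
            return lambda X, y: GALDA(cfg.ga).fit(X, y)
        sel = fitted.model.selected_indices
        starts = fitted.model.bin_starts
        return lambda X, y: FixedSelectionLDA(sel, bin_starts=starts).fit(X, y)
    if name == "pca_lda":
        return lambda X, y: build_model(name, n_components=fitted.n_components
                                        ).fit(X, y)
    if name == "pca_qda":
        return lambda X, y: build_model(name, n_components=fitted.n_components
                                        ).fit(X, y)
    if name == "pls_da":
        return lambda X, y: build_model(name, n_latent=fitted.n_latent).fit(X, y)
    return lambda X, y: build_model(name).fit(X, y)


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    cfg = (config if config is not None else PipelineConfig()).resolved()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log.info("defaults in force: baseline=%s, nesting=%s, GA bounds=[%d, %d], "
             "GA profile=%dx%d", cfg.preprocess.baseline_method,
             "nested" if cfg.nested_cv else "selection-fixed",
             cfg.ga.min_vars, cfg.ga.max_vars, cfg.ga.n_generations,
             cfg.ga.population_size)

    # ---- data
    if cfg.input == "simulate":
        raw = simulate_cohort(cfg.cohort, grid=cfg.grid)
    else:
        raw = gio.read_spectra(cfg.input)
    class_order = [g for g in GROUPS if (raw.labels == g).any()] or sorted(
        set(raw.labels.tolist()), key=str)

    # ---- preprocessing (centering is handled per partition below)
    pre_cfg = dataclasses.replace(cfg.preprocess, center=False)
    norm = run_preprocessing(raw, pre_cfg)

    # ---- Kennard-Stone split
    sp = split(norm, cfg.split)
    train_u, test_u = norm.subset(sp.train_indices), norm.subset(sp.test_indices)
    train = mean_center(train_u)
    test = mean_center(test_u, means=train.column_means)
    log.info("split: %d train / %d test (%s)", sp.train_indices.size,
             sp.test_indices.size, sp.per_class_counts)

    summary: dict = {
        "config": _config_echo(cfg),
        "seeds": derive_seeds(cfg.seed),
        "profile": "full-scale" if cfg.full_scale else "reduced",
        "n_samples": int(raw.n_samples),
        "n_points_track": int(norm.n_points),
        "split": {
            "train_ids": train.patient_ids.tolist(),
            "test_ids": test.patient_ids.tolist(),
            "per_class_counts": {str(k): list(v)
                                 for k, v in sp.per_class_counts.items()},
        },
        "models": {},
    }

    galda_fitted = None
    for name in cfg.models:
        log.info("fitting %s", name)
        model = (GALDA(cfg.ga, ppm=train.ppm) if name == "ga_lda"
                 else build_model(name))
        model.fit(train.X, train.labels)
        if name == "ga_lda":
            galda_fitted = model
        entry: dict = {}
        cm_tr = confusion(train.labels, model.predict(train.X), class_order)
        entry["training"] = _metrics_payload(metrics_from_confusion(cm_tr))
        cm_te, m_te = external_test(model, test, class_order)
        entry["test"] = _metrics_payload(m_te)
        entry["test_confusion"] = cm_te.counts.tolist()
        fit_fn = _fit_factory(name, cfg, model)
        cm_cv, m_cv = leave_one_patient_out_cv(fit_fn, train_u, class_order)
        entry["loocv"] = _metrics_payload(m_cv)
        entry["loocv_confusion"] = cm_cv.counts.tolist()
        if name == "ga_lda":
            entry["selected_ppm"] = model.model.selected_ppm.tolist()
            entry["n_selected"] = int(model.model.selected_indices.size)
            pct, avg, cm_mc = monte_carlo_cv(fit_fn, norm, cfg.mccv, class_order)
            entry["mccv"] = {
                "percentage_matrix": pct.tolist(),
                "average_accuracy": avg,
                "counts": cm_mc.counts.tolist(),
                "class_order": list(class_order),
            }
        summary["models"][name] = entry

    # ---- artifacts
    pd.DataFrame({
        "sample_id": raw.patient_ids,
        "partition": ["train" if i in set(sp.train_indices.tolist()) else "test"
                      for i in range(raw.n_samples)],
        "label": raw.labels,
    }).to_csv(out_dir / "split.csv", index=False)

    n_pc = min(5, norm.n_samples - 1, norm.n_points)
    pca = fit_pca(norm.X, n_pc)
    scores = pca_transform(pca, norm.X)
    score_df = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(n_pc)])
    score_df.insert(0, "label", norm.labels)
    score_df.insert(0, "sample_id", norm.patient_ids)
    score_df.to_csv(out_dir / "pca_scores.csv", index=False)
    summary["pca_explained_variance_pct"] = (
        100.0 * pca.explained_variance_fraction).tolist()

    if galda_fitted is not None:
        mc = summary["models"]["ga_lda"]["mccv"]
        mat = pd.DataFrame(
            np.round(np.asarray(mc["percentage_matrix"]), 1),
            index=[f"{c}" for c in class_order],
            columns=list(class_order),
        )
        mat.index.name = "Measured/Predicted"
        mat.to_csv(out_dir / "mccv_matrix.csv")

        reports = report_selected_variables(
            galda_fitted.model, norm, tolerance=cfg.annotation_tolerance)
        rows = []
        for r in reports:
            row = {"ppm": round(r.ppm, 2)}
            for g in class_order:
                row[f"{g}_mean"] = r.per_group[g]["mean"]
                row[f"{g}_sd"] = r.per_group[g]["sd"]
            row["p_value"] = round(r.p_value, 3)
            row["significant"] = r.significant
            row["annotation"] = r.annotation
            rows.append(row)
        pd.DataFrame(rows).to_csv(out_dir / "variable_report.csv", index=False)
        summary["variable_report"] = rows
        (out_dir / "model_ga_lda.json").write_text(
            json.dumps(galda_to_dict(galda_fitted.model), sort_keys=True))

    comparison = [
        {"model": name,
         "test_AC": summary["models"][name]["test"]["AC"],
         "test_SENS": summary["models"][name]["test"]["SENS"],
         "test_SPEC": summary["models"][name]["test"]["SPEC"],
         "loocv_AC": summary["models"][name]["loocv"]["AC"]}
        for name in cfg.models
    ]
    pd.DataFrame(comparison).to_csv(out_dir / "model_comparison.csv",
                                    index=False)
    summary["comparison"] = comparison

    (out_dir / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=2))
    return summary
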