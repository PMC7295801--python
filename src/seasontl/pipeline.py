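"""End-to-end orchestration: plates -> QC -> normalization -> seasonal models.

Mirrors the analysis layout of a two-cohort seasonality study: raw qPCR
wells are reduced to QC'd T/S ratios, converted to per-plate z-scores
(optionally Box-Cox transformed), merged with the phenotype table, and run
through a roster of Fourier seasonal regressions — a crude model and
models adjusted for age/sex, cell composition, maternal BMI, birthweight
and supplementation arm — each summarised by its 2-df seasonal LRT,
amplitude and peak/nadir dates. Per-predictor effect models and a
bootstrap amplitude interval for the crude model complete the report.

Every artifact is written in a deterministic text format, so a rerun with
the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import normalization, qpcr
from .seasonality import (
    bootstrap_amplitude_ci,
    covariate_effect_models,
    seasonal_lrt,
    seasonal_summary,
    select_harmonics,
)
from .synthetic import CELL_TYPES

logger = logging.getLogger(__name__)

__all__ = ["ModelSpec", "RunConfig", "run_pipeline", "default_models", "PipelineStageError"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage. Artifacts
    written before the failure are left in place."""


@dataclass(frozen=True)
class ModelSpec:
    name: str
    covariates: tuple[str, ...]
    fourier_pairs: int = 1


def default_models() -> list[ModelSpec]:
    """The standard roster: crude plus five covariate-adjusted models."""
    cells = tuple(f"frac_{ct}" for ct in CELL_TYPES if ct != "Gran")
    return [
        ModelSpec("crude", ()),
        ModelSpec("age_sex", ("age", "sex")),
        ModelSpec("age_sex_cells", ("age", "sex") + cells),
        ModelSpec("age_sex_bmi", ("age", "sex", "log_maternal_bmi")),
        ModelSpec("age_sex_birthweight", ("age", "sex", "birthweight")),
        ModelSpec("age_sex_supplementation", ("age", "sex", "maternal_arm")),
    ]


@dataclass
class RunConfig:
    """Structured run configuration (YAML-serializable)."""

    wells_csv: str | None = None
    phenotype_csv: str | None = None
    out_dir: str = "seasontl_out"
    cv_threshold: float = 0.15
    ts_method: str = "per_replicate"
    apply_boxcox: bool = False
    boxcox_order: str = "z_then_boxcox"
    log_predictors: tuple[str, ...] = ("maternal_bmi", "maternal_folate")
    models: list[ModelSpec] = field(default_factory=default_models)
    effect_predictors: tuple[str, ...] = (
        "log_maternal_bmi",
        "birthweight",
        "maternal_arm",
        "infant_arm",
        "log_maternal_folate",
    )
    harmonic_k_max: int = 3
    bootstrap_B: int = 1000
    seed: int = 0
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        models = raw.pop("models", None)
        cfg = cls(**raw)
        if models is not None:
            cfg.models = [
                ModelSpec(m["name"], tuple(m["covariates"]), int(m.get("fourier_pairs", 1)))
                for m in models
            ]
        return cfg

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["models"] = [
            {"name": m.name, "covariates": list(m.covariates), "fourier_pairs": m.fourier_pairs}
            for m in self.models
        ]
        raw["log_predictors"] = list(self.log_predictors)
        raw["effect_predictors"] = list(self.effect_predictors)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def _plot_model(summary, name: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(summary.days, summary.curve, color="black", lw=1.5)
    ax.fill_between(summary.days, summary.ci_lower, summary.ci_upper,
                    color="grey", alpha=0.4, lw=0)
    month_starts = [1, 32, 61, 92, 122, 153, 183, 214, 245, 275, 306, 336]
    ax.set_xticks(month_starts)
    ax.set_xticklabels(list("JFMAMJJASOND"))
    ax.set_xlabel("month of conception")
    ax.set_ylabel("LTL (T/S mean z-score)")
    ax.set_title(name)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(
    config: RunConfig,
    wells: pd.DataFrame | None = None,
    phenotype: pd.DataFrame | None = None,
) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``.

    ``wells`` / ``phenotype`` may be passed in memory; otherwise they are
    read from the paths in the config. Returns a dict of in-memory
    artifacts (model table, summaries, QC report, ...).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: dict = {"seed": config.seed}

    # ---- stage: qPCR --------------------------------------------------
    stage = "qpcr"
    try:
        if wells is None:
            if config.wells_csv is None:
                raise ValueError("no wells input (wells_csv unset)")
            well_objs = qpcr.read_wells_csv(config.wells_csv)
        else:
            well_objs = qpcr.wells_from_frame(wells)
        qres = qpcr.process_plates(
            well_objs, cv_threshold=config.cv_threshold, method=config.ts_method
        )
        qpcr.write_ts_records_csv(qres["kept"] + qres["excluded"], out / "ts_records.csv")
        rep = qres["report"]
        qc_report = {
            "intra_assay_cv": rep.intra_assay_cv,
            "inter_assay_cv": rep.inter_assay_cv,
            "n_samples_kept": len(qres["kept"]),
            "n_samples_excluded": len(qres["excluded"]),
            "exclusion_reasons": sorted(
                {r.exclusion_reason for r in qres["excluded"] if r.exclusion_reason}
            ),
            "n_plates": rep.n_plates,
        }
        _write_json(qc_report, out / "qc_report.json")
        run_log["qc"] = qc_report
    except Exception as e:  # noqa: BLE001 - stage-named rethrow
        raise PipelineStageError(f"stage {stage!r} failed: {e}") from e

    # ---- stage: normalization ----------------------------------------
    stage = "normalization"
    try:
        # cohort samples only: reference/control wells are plate furniture
        special = set(qres["reference_ids"]) | set(qres["control_ids"])
        kept = [r for r in qres["kept"] if r.sample_id not in special]
        ts_frame = qpcr.records_to_frame(kept)[["sample_id", "plate_id", "ts_ratio"]]
        anova_f, anova_p = normalization.plate_batch_anova(ts_frame)
        normalized, norm_excluded, transform = normalization.normalize_ltl(
            ts_frame,
            apply_boxcox=config.apply_boxcox,
            boxcox_order=config.boxcox_order,
        )
        normalized.to_csv(out / "normalized_ltl.csv", index=False, float_format="%.10g")
        transform.update(plate_anova_F=anova_f, plate_anova_p=anova_p)
        _write_json(transform, out / "transform_params.json")
        run_log["normalization"] = {
            "plate_anova_F": anova_f,
            "plate_anova_p": anova_p,
            "n_normalized": len(normalized),
            "n_excluded_small_plates": len(norm_excluded),
        }
    except Exception as e:
        raise PipelineStageError(f"stage {stage!r} failed: {e}") from e

    # ---- stage: merge -------------------------------------------------
    stage = "merge"
    try:
        if phenotype is None:
            if config.phenotype_csv is None:
                raise ValueError("no phenotype input (phenotype_csv unset)")
            phenotype = pd.read_csv(
                config.phenotype_csv, parse_dates=["conception_date", "collection_date"]
            )
        pheno = phenotype.drop(columns=["ltl_z"], errors="ignore")
        data = pheno.merge(normalized, on="sample_id", how="inner")
        present = [c for c in config.log_predictors if c in data.columns and data[c].notna().any()]
        data = normalization.log_transform_predictors(data, present)
        run_log["merge"] = {"n_analysis": len(data)}
    except Exception as e:
        raise PipelineStageError(f"stage {stage!r} failed: {e}") from e

    # ---- stage: models ------------------------------------------------
    stage = "models"
    try:
        sel = select_harmonics(data, covariates=(), k_max=config.harmonic_k_max)
        _write_json(
            {
                "selected_k": sel.k,
                "tests": [
                    {"k_reduced": a, "k_full": b,
                     "chi2": t.chi2, "df": t.df, "p_value": t.p_value}
                    for a, b, t in sel.tests
                ],
            },
            out / "harmonic_selection.json",
        )

        model_rows = []
        summaries = {}
        for spec in config.models:
            covs = [c for c in spec.covariates if c in data.columns]
            if len(covs) < len(spec.covariates):
                missing = set(spec.covariates) - set(covs)
                logger.info("model %s: skipping absent covariates %s", spec.name, missing)
            usable = [c for c in covs if data[c].notna().any() and data[c].nunique(dropna=True) > 1]
            full, reduced, lrt = seasonal_lrt(data, spec.fourier_pairs, usable)
            summ = seasonal_summary(full)
            summaries[spec.name] = (full, summ)
            model_rows.append(
                {
                    "model": spec.name,
                    "covariates": "+".join(usable) if usable else "(none)",
                    "n": full.fit.n,
                    "fourier_pairs": spec.fourier_pairs,
                    "lrt_chi2": lrt.chi2,
                    "lrt_df": lrt.df,
                    "lrt_p": lrt.p_value,
                    "amplitude": summ.amplitude,
                    "peak_day": summ.peak_day,
                    "nadir_day": summ.nadir_day,
                }
            )
        model_table = pd.DataFrame(model_rows)
        model_table.to_csv(out / "model_results.csv", index=False, float_format="%.10g")
        run_log["models"] = {r["model"]: r["n"] for r in model_rows}

        if config.make_plots:
            for name, (_full, summ) in summaries.items():
                _plot_model(summ, name, out / f"fig_{name}.png")
    except Exception as e:
        raise PipelineStageError(f"stage {stage!r} failed: {e}") from e

    # ---- stage: bootstrap --------------------------------------------
    stage = "bootstrap"
    try:
        boot = bootstrap_amplitude_ci(
            data, k=1, covariates=(), B=config.bootstrap_B, seed=config.seed
        )
        _write_json(
            {
                "amplitude": boot.amplitude,
                "amplitude_ci": list(boot.amplitude_ci),
                "peak_day": boot.peak_day,
                "peak_day_ci": list(boot.peak_day_ci),
                "B": boot.n_boot,
                "n_redrawn": boot.n_redrawn,
            },
            out / "bootstrap.json",
        )
    except Exception as e:
        raise PipelineStageError(f"stage {stage!r} failed: {e}") from e

    # ---- stage: predictor effects ------------------------------------
    stage = "covariate_effects"
    try:
        preds = [
            p
            for p in config.effect_predictors
            if p in data.columns and data[p].notna().any() and data[p].nunique(dropna=True) > 1
        ]
        effects = covariate_effect_models(data, preds) if preds else pd.DataFrame()
        effects.to_csv(out / "covariate_effects.csv", index=False, float_format="%.10g")
    except Exception as e:
        raise PipelineStageError(f"stage {stage!r} failed: {e}") from e

    _write_json(run_log, out / "run_log.json")
    return {
        "model_table": model_table,
        "summaries": summaries,
        "qc_report": qc_report,
        "bootstrap": boot,
        "covariate_effects": effects,
        "harmonic_selection": sel,
        "data": data,
        "run_log": run_log,
    }
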