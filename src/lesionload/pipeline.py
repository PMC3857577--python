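"""End-to-end orchestration: maps -> loads -> regressions -> stratification.

A run consumes either a directory layout of NIfTI inputs plus a cohort
CSV, or a synthetic study generated on the fly, and writes a fixed
output layout:

    loads.csv            one row per (patient, map), if imaging inputs exist
    regressions.csv      single-load models + dorsal-ventral comparison
    stratification.csv   per-measure cluster split, discriminant accuracy,
                         ROC AUC/threshold for each candidate predictor
    roc_points/*.csv     ROC curve points for plotting
    run.json             config echo, package version, seed

Reruns with the same config are bit-identical; an existing output
directory is refused unless ``force`` is set.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .canonical import read_map
from .cohort import CohortTable, LOAD_COLUMNS, OUTCOME_COLUMNS, load_cohort
from .loads import LesionMask, batch_lesion_loads
from .regression import RegressionSpec, fit_dorsal_ventral_comparison, fit_model
from .severity import discriminant_accuracy, roc_analysis, two_group_cluster
from .synthetic import SyntheticConfig, generate_cohort, write_study
from .volumetric import as_binary, read_volume

__all__ = ["RunConfig", "run_full_analysis"]

log = logging.getLogger(__name__)

#: predictors compared in the stratification stage
STRATIFICATION_PREDICTORS = ["af_ll_cc", "fgm_ll_cc", "af_fgm_ll_cc", "lesion_volume_cc"]


@dataclass(frozen=True)
class RunConfig:
    output_dir: str
    cohort_csv: str | None = None
    maps_dir: str | None = None
    lesions_dir: str | None = None
    synthetic: bool = False
    synthetic_config: SyntheticConfig = field(default_factory=SyntheticConfig)
    outcomes: tuple[str, ...] = tuple(OUTCOME_COLUMNS)
    load_columns: tuple[str, ...] = tuple(LOAD_COLUMNS)
    outlier_sd: float = 2.5
    seed: int = 0
    force: bool = False

    def __post_init__(self) -> None:
        real = self.cohort_csv is not None or self.maps_dir is not None
        if real == self.synthetic:
            raise ValueError("exactly one of real-input paths or synthetic mode must be set")


def _regression_stage(cohort: CohortTable, config: RunConfig) -> pd.DataFrame:
    rows = []
    for outcome in config.outcomes:
        for load in config.load_columns:
            spec = RegressionSpec(outcome=outcome, predictors=(load,), outlier_sd=config.outlier_sd)
            fit = fit_model(cohort, spec)
            rows.append(
                {
                    "model": "single_load",
                    "outcome": outcome,
                    "predictor": load,
                    "r_squared": fit.r_squared,
                    "p_value": fit.p_value_model,
                    "partial_r": fit.partial_r[load],
                    "n_used": fit.n_used,
                    "excluded": ";".join(fit.excluded_ids),
                }
            )
        dv = fit_dorsal_ventral_comparison(cohort, outcome)
        for pred in ("af_ll_cc", "emc_ll_cc", "uf_ll_cc"):
            rows.append(
                {
                    "model": "dorsal_ventral",
                    "outcome": outcome,
                    "predictor": pred,
                    "r_squared": dv.r_squared,
                    "p_value": dv.partial_p[pred],
                    "partial_r": dv.partial_r[pred],
                    "n_used": dv.n_used,
                    "excluded": "",
                }
            )
    return pd.DataFrame(rows)


def _stratification_stage(cohort: CohortTable, config: RunConfig, roc_dir: Path) -> pd.DataFrame:
    rows = []
    roc_dir.mkdir(parents=True, exist_ok=True)
    for outcome in config.outcomes:
        scores = cohort.column(outcome)
        part = two_group_cluster(scores, variable=outcome)
        acc_cluster = discriminant_accuracy(scores, part)
        for pred in STRATIFICATION_PREDICTORS:
            if pred not in cohort.df.columns:
                continue
            roc = roc_analysis(cohort.column(pred), part)
            rows.append(
                {
                    "outcome": outcome,
                    "cutoff_low": part.cutoff_band[0],
                    "cutoff_high": part.cutoff_band[1],
                    "n_severe": part.n_severe,
                    "cluster_accuracy_pct": 100 * acc_cluster,
                    "predictor": pred,
                    "auc_pct": 100 * roc.auc,
                    "threshold_cc": roc.threshold_cc,
                    "sensitivity_pct": 100 * roc.sensitivity,
                    "specificity_pct": 100 * roc.specificity,
                    "accuracy_pct": 100 * roc.accuracy,
                }
            )
            pd.DataFrame(roc.curve, columns=["threshold", "sensitivity", "fpr"]).to_csv(
                roc_dir / f"{outcome}__{pred}.csv", index=False
            )
    return pd.DataFrame(rows)


def _load_imaging(config: RunConfig):
    maps = []
    lesions = []
    if config.maps_dir:
        for p in sorted(Path(config.maps_dir).glob("*.nii*")):
            maps.append(read_map(p))
    if config.lesions_dir:
        for p in sorted(Path(config.lesions_dir).glob("*.nii*")):
            vol = as_binary(read_volume(p))
            pid = p.name.split(".")[0].replace("patient_", "")
            lesions.append(LesionMask(vol.grid, vol.values, patient_id=pid))
    return maps, lesions


def run_full_analysis(config: RunConfig) -> Path:
    """Run every stage the inputs allow and write the report bundle.

    Returns the output directory. Raises on the first stage error after
    logging the stage name.
    """
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()) and not config.force:
        raise FileExistsError(f"output directory {out} is not empty (use force to overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "setup"
    try:
        if config.synthetic:
            stage = "synthesis"
            syn_cfg = dataclasses.replace(config.synthetic_config, seed=config.seed)
            study = generate_cohort(syn_cfg)
            write_study(study, out / "synthetic_study")
            cohort = study.cohort
            loads_df = None  # loads are already the cohort columns, self-consistent
        else:
            stage = "cohort"
            cohort = load_cohort(config.cohort_csv) if config.cohort_csv else None
            stage = "lesion_loads"
            maps, lesions = _load_imaging(config)
            loads_df = batch_lesion_loads(lesions, maps) if (maps and lesions) else None
            if loads_df is None:
                log.info("no imaging inputs: loads.csv skipped")
        if loads_df is not None:
            loads_df.to_csv(out / "loads.csv", index=False, float_format="%.6f")
        if cohort is not None:
            stage = "regressions"
            _regression_stage(cohort, config).to_csv(
                out / "regressions.csv", index=False, float_format="%.6f"
            )
            stage = "stratification"
            _stratification_stage(cohort, config, out / "roc_points").to_csv(
                out / "stratification.csv", index=False, float_format="%.6f"
            )
    except Exception:
        log.exception("stage %r failed", stage)
        raise
    (out / "run.json").write_text(
        json.dumps(
            {
                "package_version": __version__,
                "seed": config.seed,
                "synthetic": config.synthetic,
                "cohort_csv": config.cohort_csv,
                "maps_dir": config.maps_dir,
                "lesions_dir": config.lesions_dir,
                "outcomes": list(config.outcomes),
                "load_columns": list(config.load_columns),
                "outlier_sd": config.outlier_sd,
            },
            indent=2,
        )
    )
    log.info("run complete in %.1f s -> %s", time.time() - t0, out)
    return out
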