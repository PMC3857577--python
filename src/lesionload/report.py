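"""Headline statistics of the reference analysis, computed from a cohort table.

Bundles the desk-scale pipeline — two-group severity clustering,
discriminant accuracy, ROC of lesion loads and lesion volume against
the severity labels, the published cutoff-band AUCs, and the
covariate-controlled regressions — into one dictionary of named
numbers. Percentages are on the 0-100 scale, thresholds in cc,
R-squared on 0-1.
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortTable
from .regression import RegressionSpec, fit_dorsal_ventral_comparison, fit_model
from .severity import (
    REPORTED_CUTOFF_BANDS,
    discriminant_accuracy,
    roc_analysis,
    severity_from_cutoff,
    two_group_cluster,
)

__all__ = ["headline_stats"]


def headline_stats(cohort: CohortTable) -> dict[str, float]:
    """Compute the full set of headline numbers from a cohort table.

    Severity labels come from the exact two-group cluster split of each
    behavioral measure; the published cutoff-band AUCs additionally use
    the fixed band cutoffs (severe = score at or below the band's low
    endpoint). Keys are self-describing; all values are plain floats.
    """
    out: dict[str, float] = {}
    cius = cohort.column("cius_per_min")
    words = cohort.column("words_per_min")
    bnt = cohort.column("bnt")
    af = cohort.column("af_ll_cc")
    lesion_vol = cohort.column("lesion_volume_cc")

    # --- cluster splits + discriminant accuracy
    part_cius = two_group_cluster(cius, "cius_per_min")
    part_words = two_group_cluster(words, "words_per_min")
    part_bnt = two_group_cluster(bnt, "bnt")
    acc_cius = discriminant_accuracy(cius, part_cius)
    acc_words = discriminant_accuracy(words, part_words)
    out["fluency_cluster_discriminant_accuracy_pct"] = 100 * (acc_cius + acc_words) / 2
    out["cius_cluster_discriminant_accuracy_pct"] = 100 * acc_cius
    out["words_cluster_discriminant_accuracy_pct"] = 100 * acc_words
    out["naming_cluster_discriminant_accuracy_pct"] = 100 * discriminant_accuracy(bnt, part_bnt)

    # --- ROC of AF load and lesion volume against the cluster labels
    roc_af_fluency = roc_analysis(af, part_cius)
    out["fluency_af_roc_accuracy_pct"] = 100 * roc_af_fluency.accuracy
    out["fluency_af_roc_threshold_cc"] = roc_af_fluency.threshold_cc
    out["fluency_af_roc_auc_pct"] = 100 * roc_af_fluency.auc
    out["fluency_af_roc_sensitivity_pct"] = 100 * roc_af_fluency.sensitivity
    out["fluency_af_roc_specificity_pct"] = 100 * roc_af_fluency.specificity
    roc_lv_fluency = roc_analysis(lesion_vol, part_cius)
    out["fluency_lesion_volume_roc_accuracy_pct"] = 100 * roc_lv_fluency.accuracy
    out["fluency_lesion_volume_roc_threshold_cc"] = roc_lv_fluency.threshold_cc
    out["fluency_lesion_volume_roc_auc_pct"] = 100 * roc_lv_fluency.auc
    roc_af_naming = roc_analysis(af, part_bnt)
    out["naming_af_roc_accuracy_pct"] = 100 * roc_af_naming.accuracy
    out["naming_af_roc_threshold_cc"] = roc_af_naming.threshold_cc
    out["naming_af_roc_auc_pct"] = 100 * roc_af_naming.auc
    out["naming_af_roc_sensitivity_pct"] = 100 * roc_af_naming.sensitivity

    # --- AUCs for the published cutoff bands (severe = score <= band low)
    for measure, scores in (("cius_per_min", cius), ("words_per_min", words), ("bnt", bnt)):
        low, _ = REPORTED_CUTOFF_BANDS[measure]
        part = severity_from_cutoff(scores, low, measure)
        out[f"{measure}_band_af_auc_pct"] = 100 * roc_analysis(af, part).auc

    # --- single-load regressions with covariates + outlier pass
    for outcome in ("cius_per_min", "words_per_min", "bnt"):
        fit = fit_model(cohort, RegressionSpec(outcome=outcome, predictors=("af_ll_cc",)))
        out[f"{outcome}_af_r_squared"] = fit.r_squared

    # --- dorsal-ventral comparison
    dv = fit_dorsal_ventral_comparison(cohort, "cius_per_min")
    out["cius_dorsal_ventral_af_partial_r"] = dv.partial_r["af_ll_cc"]
    out["cius_dorsal_ventral_af_p"] = dv.partial_p["af_ll_cc"]
    out["cius_dorsal_ventral_emc_p"] = dv.partial_p["emc_ll_cc"]
    out["cius_dorsal_ventral_uf_p"] = dv.partial_p["uf_ll_cc"]
    return out
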