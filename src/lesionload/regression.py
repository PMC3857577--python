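"""Outcome regressions: lesion loads predicting fluency and naming.

Two model families:

* Single-load models (one lesion-load predictor plus age and
  months-post-stroke covariates). Volumetric predictors are cube-root
  transformed for the fluency outcomes (CIUs/min, Words/min) — a lesion
  load scales like a volume, so its linear dimension is the natural
  scale — and left untransformed for naming (BNT), which relates
  linearly to load. After an initial OLS fit, cases with internally
  studentized residual beyond +/-2.5 SD are dropped and the model is
  refit once.

* The dorsal-ventral comparison (AF vs EMC vs UF loads, controlling for
  total lesion volume) reported with per-predictor partial correlations.
  This model matches the published convention: the lesion-size control
  is cube-rooted along with the loads for fluency outcomes, no
  demographic covariates enter, and no outlier pass is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortTable
from .errors import SampleSizeError, SingularDesignError

__all__ = [
    "cube_root",
    "RegressionSpec",
    "RegressionFit",
    "fit_model",
    "fit_dorsal_ventral_comparison",
    "partial_correlation",
]

FLUENCY_OUTCOMES = ("cius_per_min", "words_per_min")


def cube_root(x):
    """Elementwise cube root for nonnegative volumetric quantities."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("cube_root is defined for nonnegative volumes only")
    out = np.cbrt(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


@dataclass(frozen=True)
class RegressionSpec:
    """What to regress on what.

    ``transform_predictors`` defaults to the outcome-appropriate choice:
    cube root for fluency outcomes, identity for naming.
    """

    outcome: str
    predictors: tuple[str, ...]
    covariates: tuple[str, ...] = ("age_years", "months_post_stroke")
    transform_predictors: str = "auto"  # auto | cube_root | identity
    outlier_sd: float | None = 2.5

    def resolved_transform(self) -> str:
        if self.transform_predictors != "auto":
            return self.transform_predictors
        return "cube_root" if self.outcome in FLUENCY_OUTCOMES else "identity"


@dataclass(frozen=True)
class RegressionFit:
    r_squared: float
    adjusted_r_squared: float
    p_value_model: float
    coefficients: pd.DataFrame = field(repr=False)  # term, estimate, p_value
    partial_r: dict[str, float]
    partial_p: dict[str, float]
    n_used: int
    excluded_ids: tuple[str, ...]


def _design(cohort: CohortTable, spec: RegressionSpec):
    df = cohort.df
    cols = [spec.outcome, *spec.predictors, *spec.covariates]
    for c in cols:
        if c not in df.columns:
            raise KeyError(f"column {c!r} not in cohort")
    sub = df[["patient_id", *cols]].dropna(subset=cols)  # listwise on used columns only
    transform = spec.resolved_transform()
    X = pd.DataFrame(index=sub.index)
    for p in spec.predictors:
        X[p] = cube_root(sub[p].to_numpy()) if transform == "cube_root" else sub[p].to_numpy()
    for c in spec.covariates:
        # volumetric covariates share the predictors' scale convention
        vals = sub[c].to_numpy()
        X[c] = cube_root(vals) if (transform == "cube_root" and c.endswith("_cc")) else vals
    X = sm.add_constant(X, has_constant="add")
    y = sub[spec.outcome]
    return y, X, sub["patient_id"]


def _ols(y, X):
    model = sm.OLS(np.asarray(y, float), np.asarray(X, float))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SingularDesignError(
            f"design matrix is rank deficient (columns: {list(X.columns)})"
        )
    return model.fit()


def partial_correlation(y: pd.Series, X: pd.DataFrame, term: str) -> tuple[float, float]:
    """Signed partial correlation of outcome and one design term,
    controlling all other model terms, with its two-sided p-value.

    Computed by residualising both on the remaining terms; the p-value
    is the t-test on n - k - 2 degrees of freedom (k controls).
    """
    from scipy import stats

    others = [c for c in X.columns if c not in ("const", term)]
    Xo = sm.add_constant(X[others], has_constant="add")
    ry = np.asarray(y, float) - _ols(y, Xo).fittedvalues
    rx = X[term].to_numpy() - _ols(X[term], Xo).fittedvalues
    r = float(np.corrcoef(ry, rx)[0, 1])
    n, k = len(ry), len(others)
    dof = n - k - 2
    t = r * np.sqrt(dof / max(1e-12, 1 - r * r))
    p = 2 * stats.t.sf(abs(t), dof)
    return r, float(p)


def fit_model(cohort: CohortTable, spec: RegressionSpec) -> RegressionFit:
    """OLS of the outcome on transformed predictors + covariates with a
    single +/-2.5 SD studentized-residual outlier pass (fit, drop,
    refit once)."""
    y, X, ids = _design(cohort, spec)
    if len(y) < 10:
        raise SampleSizeError(f"only {len(y)} usable records; need >= 10")
    res = _ols(y, X)
    excluded: tuple[str, ...] = ()
    if spec.outlier_sd is not None and res.df_resid > 1:
        z = res.get_influence().resid_studentized_internal
        keep = np.abs(z) <= spec.outlier_sd
        if not keep.all():
            excluded = tuple(ids.to_numpy()[~keep])
            y, X, ids = y[keep], X[keep], ids[keep]
            res = _ols(y, X)
    coeffs = pd.DataFrame(
        {"term": X.columns, "estimate": res.params, "std_error": res.bse, "p_value": res.pvalues}
    ).reset_index(drop=True)
    partial_r, partial_p = {}, {}
    for p in spec.predictors:
        r, pv = partial_correlation(y, X, p)
        partial_r[p], partial_p[p] = r, pv
    return RegressionFit(
        r_squared=float(res.rsquared),
        adjusted_r_squared=float(res.rsquared_adj),
        p_value_model=float(res.f_pvalue),
        coefficients=coeffs,
        partial_r=partial_r,
        partial_p=partial_p,
        n_used=int(res.nobs),
        excluded_ids=excluded,
    )


def fit_dorsal_ventral_comparison(cohort: CohortTable, outcome: str) -> RegressionFit:
    """AF vs EMC vs UF lesion loads predicting one outcome, controlling
    for total lesion volume, with per-predictor partial correlations.

    No demographic covariates and no outlier pass: this mirrors the
    published comparison's convention (see module docstring).
    """
    spec = RegressionSpec(
        outcome=outcome,
        predictors=("af_ll_cc", "emc_ll_cc", "uf_ll_cc"),
        covariates=("lesion_volume_cc",),
        outlier_sd=None,
    )
    return fit_model(cohort, spec)
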