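"""Outcome regressions: transforms, outlier pass, partial correlations."""

import numpy as np
import pandas as pd
import pytest

from lesionload.cohort import CohortTable
from lesionload.errors import SingularDesignError
from lesionload.regression import (
    RegressionSpec,
    cube_root,
    fit_dorsal_ventral_comparison,
    fit_model,
    partial_correlation,
)
from lesionload.synthetic import SyntheticConfig, simulate_cohort_table


def test_cube_root_values():
    assert cube_root(8.0) == pytest.approx(2.0)
    assert cube_root(0.0) == 0.0
    assert cube_root(4.01) == pytest.approx(4.01 ** (1 / 3))
    with pytest.raises(ValueError):
        cube_root(-1.0)


def test_single_load_models_match_published_fits(cohort):
    """R^2 of the covariate-controlled single-load models lands near the
    published 0.66 / 0.53 / 0.49 for CIUs/min, Words/min and BNT on AF load."""
    expected = {"cius_per_min": 0.66, "words_per_min": 0.53, "bnt": 0.49}
    for outcome, r2 in expected.items():
        fit = fit_model(cohort, RegressionSpec(outcome=outcome, predictors=("af_ll_cc",)))
        assert fit.r_squared == pytest.approx(r2, abs=0.05)
        assert fit.p_value_model < 0.001
        assert fit.partial_r["af_ll_cc"] < 0


def test_outlier_pass_removes_at_most_5pct_on_reference(cohort):
    for outcome in ("cius_per_min", "words_per_min", "bnt"):
        fit = fit_model(cohort, RegressionSpec(outcome=outcome, predictors=("af_ll_cc",)))
        assert len(fit.excluded_ids) <= int(np.ceil(0.05 * cohort.n))
        assert fit.n_used + len(fit.excluded_ids) == cohort.n


def test_r_squared_matches_independent_lstsq_oracle(cohort):
    """Same design solved by raw numpy least squares gives the same R^2."""
    spec = RegressionSpec(outcome="bnt", predictors=("af_ll_cc",), outlier_sd=None)
    fit = fit_model(cohort, spec)
    y = cohort.df["bnt"].to_numpy(float)
    X = np.column_stack(
        [
            np.ones(cohort.n),
            cohort.df["af_ll_cc"],
            cohort.df["age_years"],
            cohort.df["months_post_stroke"],
        ]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
    assert fit.r_squared == pytest.approx(r2, abs=1e-10)


def test_perfect_fit_when_outcome_equals_predictor(cohort):
    df = cohort.df.copy()
    df["bnt"] = df["af_ll_cc"]  # identity outcome, no transform for bnt
    fit = fit_model(
        CohortTable(df),
        RegressionSpec(outcome="bnt", predictors=("af_ll_cc",), covariates=()),
    )
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.excluded_ids == ()


def test_r_squared_invariant_to_predictor_rescaling(cohort):
    base = fit_model(cohort, RegressionSpec(outcome="bnt", predictors=("af_ll_cc",)))
    df = cohort.df.copy()
    df["af_ll_cc"] = df["af_ll_cc"] * 7.3
    scaled = fit_model(CohortTable(df), RegressionSpec(outcome="bnt", predictors=("af_ll_cc",)))
    assert scaled.r_squared == pytest.approx(base.r_squared, abs=1e-10)


def test_adding_predictor_never_decreases_r_squared(cohort):
    one = fit_model(
        cohort, RegressionSpec(outcome="cius_per_min", predictors=("af_ll_cc",), outlier_sd=None)
    )
    two = fit_model(
        cohort,
        RegressionSpec(
            outcome="cius_per_min", predictors=("af_ll_cc", "fgm_ll_cc"), outlier_sd=None
        ),
    )
    assert two.r_squared >= one.r_squared - 1e-12


def test_duplicated_predictor_raises_singular_design(cohort):
    df = cohort.df.copy()
    df["af_copy_cc"] = df["af_ll_cc"]
    with pytest.raises(SingularDesignError):
        fit_model(
            CohortTable(df),
            RegressionSpec(outcome="bnt", predictors=("af_ll_cc", "af_copy_cc")),
        )


def test_partial_correlation_matches_pingouin(cohort):
    pingouin = pytest.importorskip("pingouin")
    import statsmodels.api as sm

    df = cohort.df
    y = df["cius_per_min"]
    X = pd.DataFrame(
        {
            "af": np.cbrt(df["af_ll_cc"]),
            "emc": np.cbrt(df["emc_ll_cc"]),
            "uf": np.cbrt(df["uf_ll_cc"]),
            "vol": np.cbrt(df["lesion_volume_cc"]),
        }
    )
    Xc = sm.add_constant(X)
    r, p = partial_correlation(y, Xc, "af")
    data = X.assign(y=y)
    ref = pingouin.partial_corr(data, x="af", y="y", covar=["emc", "uf", "vol"])
    assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
    assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-6)


def test_dorsal_ventral_comparison_singles_out_arcuate(cohort):
    """AF load is the only significant term among AF/EMC/UF when lesion
    size is controlled, with a strong negative partial correlation."""
    for outcome in ("cius_per_min", "words_per_min", "bnt"):
        fit = fit_dorsal_ventral_comparison(cohort, outcome)
        assert fit.partial_p["af_ll_cc"] < 0.05
        assert fit.partial_r["af_ll_cc"] < -0.25
        assert fit.partial_p["emc_ll_cc"] > 0.05
        assert fit.partial_p["uf_ll_cc"] > 0.05
        assert abs(fit.partial_r["af_ll_cc"]) == max(map(abs, fit.partial_r.values()))


def test_parameter_recovery_on_simulated_cohorts():
    """Fitting the generating model on simulated cohorts (n=200, low
    censoring) recovers the lesion-load slope within its 95% CI."""
    model = {"cius_per_min": (40.0, -12.0, 6.0), "words_per_min": (70.0, -15.0, 9.0), "bnt": (15.0, -4.0, 2.0)}
    cfg = SyntheticConfig(outcome_model=model)
    hits = 0
    for seed in range(20):
        table, truth = simulate_cohort_table(cfg, n=200, seed=seed)
        fit = fit_model(
            table,
            RegressionSpec(outcome="cius_per_min", predictors=("af_ll_cc",), outlier_sd=None),
        )
        est = fit.coefficients.set_index("term").loc["af_ll_cc"]
        if est.estimate - 1.96 * est.std_error <= -12.0 <= est.estimate + 1.96 * est.std_error:
            hits += 1
    assert hits >= 18  # ~95% coverage over 20 replicates
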