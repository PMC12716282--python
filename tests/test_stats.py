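"""GLM layer against closed forms and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from wingfa.stats import (
    fit_glm,
    lr_chisq_tests,
    percentage_changes,
    run_full_analysis,
)


def _poisson_newton(y, X, tol=1e-12, max_iter=100):
    """Independent Newton-scoring oracle for the Poisson log-link MLE."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-8))
    for _ in range(max_iter):
        mu = np.exp(X @ beta)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * mu[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def test_exact_linear_fit_has_zero_deviance():
    X = pd.DataFrame({"const": np.ones(10), "x": np.arange(10.0)})
    fit = fit_glm(2 + 3 * np.arange(10.0), X, "gaussian")
    assert fit.params["const"] == pytest.approx(2.0, abs=1e-10)
    assert fit.params["x"] == pytest.approx(3.0, abs=1e-10)
    assert fit.deviance == pytest.approx(0.0, abs=1e-18)


def test_poisson_intercept_only_closed_form():
    X = pd.DataFrame({"const": np.ones(3)})
    fit = fit_glm([1, 2, 3], X, "poisson")
    assert fit.params["const"] == pytest.approx(np.log(2.0), abs=1e-10)


def test_gaussian_glm_equals_least_squares():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = rng.integers(15, 40)
        X = pd.DataFrame({"const": np.ones(n), "a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = rng.normal(size=n)
        fit = fit_glm(y, X, "gaussian")
        beta, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-10)


def test_poisson_irls_matches_newton_oracle():
    rng = np.random.default_rng(1)
    for _ in range(20):
        n = int(rng.integers(25, 60))
        X = pd.DataFrame({"const": np.ones(n), "a": rng.normal(size=n) * 0.5,
                          "b": rng.integers(0, 2, n).astype(float)})
        mu = np.exp(0.5 + 0.3 * X["a"] - 0.2 * X["b"])
        y = rng.poisson(mu)
        if y.sum() == 0:
            continue
        fit = fit_glm(y, X, "poisson")
        oracle = _poisson_newton(y, X)
        assert np.allclose(fit.params.to_numpy(), oracle, atol=1e-8)


def test_rank_deficient_design_names_alias():
    X = pd.DataFrame({"const": np.ones(10), "a": np.arange(10.0)})
    X["twice_a"] = 2 * X["a"]
    with pytest.raises(ValueError, match="alias"):
        fit_glm(np.random.default_rng(0).normal(size=10), X, "gaussian")


def test_poisson_rejects_negative_counts():
    X = pd.DataFrame({"const": np.ones(5)})
    with pytest.raises(ValueError):
        fit_glm([-1, 2, 3, 1, 0], X, "poisson")


# -- likelihood-ratio tests -------------------------------------------------

def _mesocosm_frame(rng, n_per_cell=10, effect=0.0):
    rows = []
    for b in (0, 1):
        for h in (0, 1):
            for k in range(n_per_cell):
                rows.append({"bti": b, "hydrology": h, "sex": "f" if k % 2 else "m"})
    df = pd.DataFrame(rows)
    df["y"] = rng.normal(10 + effect * df["hydrology"], 1.0)
    return df


def test_gaussian_lr_matches_rss_ratio_algebra():
    rng = np.random.default_rng(2)
    df = _mesocosm_frame(rng, 12, effect=0.8)
    lr = lr_chisq_tests(df, "y", "gaussian").set_index("term")

    def rss(cols):
        X = np.column_stack([np.ones(len(df))] + [df[c] if c != "sex" else (df["sex"] == "m").astype(float) for c in cols])
        beta, *_ = np.linalg.lstsq(X, df["y"], rcond=None)
        r = df["y"] - X @ beta
        return float(r @ r)

    n = len(df)
    expected = n * np.log(rss(["bti", "sex"]) / rss(["bti", "hydrology", "sex"]))
    assert lr.loc["hydrology", "chisq"] == pytest.approx(expected, abs=1e-8)


def test_saturated_vs_self_chisq_is_zero():
    rng = np.random.default_rng(3)
    df = _mesocosm_frame(rng, 10)
    from wingfa.stats import _design_mesocosm, _lr_stat

    full = fit_glm(df["y"], _design_mesocosm(df, True), "gaussian")
    assert _lr_stat(full, full) == pytest.approx(0.0, abs=1e-12)
    assert sps.chi2.sf(0.0, 1) == 1.0


def test_poisson_lr_type_one_error_rate():
    """Null Poisson counts: per-term rejection ~5% over 1000 simulations."""
    rng = np.random.default_rng(4)
    reps = 1000
    rej = {t: 0 for t in ("bti", "hydrology", "sex", "bti:hydrology")}
    rows = []
    for b in (0, 1):
        for h in (0, 1):
            for k in range(20):
                rows.append({"bti": b, "hydrology": h, "sex": "f" if k % 2 else "m"})
    base = pd.DataFrame(rows)
    for _ in range(reps):
        df = base.copy()
        # counts at the scale the count responses actually take (cells per wing)
        df["y"] = rng.poisson(250.0, len(df))
        lr = lr_chisq_tests(df, "y", "poisson")
        for _, row in lr.iterrows():
            rej[row["term"]] += row["p"] < 0.05
    lo, hi = sps.binom.interval(0.95, reps, 0.05)
    for term, count in rej.items():
        assert lo <= count <= hi, (term, count / reps)


def test_permuted_response_pvalues_are_uniform():
    rng = np.random.default_rng(5)
    df = _mesocosm_frame(rng, 10, effect=2.0)
    X_cols = ["bti", "hydrology", "sex"]
    pvals = []
    y = df["y"].to_numpy()
    for _ in range(200):
        df2 = df.copy()
        df2["y"] = rng.permutation(y)
        fit = fit_glm(df2["y"], pd.DataFrame({
            "const": np.ones(len(df2)), "hydrology": df2["hydrology"].astype(float)}), "gaussian")
        pvals.append(fit.pvalues["hydrology"])
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


# -- percentage changes -----------------------------------------------------

def test_identical_groups_change_is_zero():
    from wingfa.stats import _design_mesocosm

    rng = np.random.default_rng(6)
    df = _mesocosm_frame(rng, 15)
    df["y"] = 10.0  # constant response
    fit = fit_glm(df["y"], _design_mesocosm(df, True), "gaussian", response="y")
    pc = percentage_changes(fit, df, "mesocosm").set_index("contrast")
    assert pc.loc["bti", "pct_change"] == pytest.approx(0.0, abs=1e-9)
    assert pc.loc["hydrology", "se_pred"] == pytest.approx(0.0, abs=1e-9)


def test_group_means_10_vs_12_is_plus_20_percent():
    df = pd.DataFrame({"bti": [0] * 10 + [1] * 10, "hydrology": 0, "sex": ["f", "m"] * 10})
    df["y"] = np.where(df["bti"] == 1, 12.0, 10.0)
    from wingfa.stats import _design_mesocosm

    fit = fit_glm(df["y"], _design_mesocosm(df, True).drop(columns=["hydrology", "bti:hydrology"]),
                  "gaussian", response="y")
    pc = percentage_changes(fit, df, "mesocosm").set_index("contrast")
    assert pc.loc["bti", "pct_change"] == pytest.approx(20.0, abs=1e-9)


def test_poisson_rate_ratio_recovery_with_wald_coverage():
    """True rate ratio 1.25: estimates within 2 Wald SE of +25% in ~95% of sims."""
    rng = np.random.default_rng(7)
    hits, sigs = 0, 0
    reps = 100
    for _ in range(reps):
        df = pd.DataFrame({"bti": [0] * 100 + [1] * 100, "hydrology": 0,
                           "sex": ["f", "m"] * 100})
        df["y"] = rng.poisson(np.where(df["bti"] == 1, 12.5, 10.0))
        from wingfa.stats import _design_mesocosm

        X = _design_mesocosm(df, True).drop(columns=["hydrology", "bti:hydrology"])
        fit = fit_glm(df["y"], X, "poisson", response="y")
        pc = percentage_changes(fit, df, "mesocosm").set_index("contrast")
        est, se = pc.loc["bti", "pct_change"], pc.loc["bti", "se_wald"]
        hits += abs(est - 25.0) <= 2 * se
        sigs += fit.pvalues["bti"] < 0.05
    assert hits / reps >= 0.90
    assert sigs / reps >= 0.99


# -- full analysis ----------------------------------------------------------

def _records_frame(rng, n=40):
    df = pd.DataFrame({
        "concentration": rng.choice([0.0, 0.0025, 0.01, 0.04], n),
        "sex": rng.choice(["f", "m"], n),
        "wet_weight": rng.normal(24, 2, n),
        "n_cells": rng.poisson(250, n).astype(float),
        "nrmse_width": rng.normal(0.2, 0.02, n),
    })
    return df


def test_run_full_analysis_family_map_and_skips():
    rng = np.random.default_rng(8)
    df = _records_frame(rng)
    with pytest.warns(UserWarning, match="skipped"):
        res = run_full_analysis(df, mode="insecticide")
    coef = res.coefficients
    assert set(coef[coef.response == "n_cells"]["family"]) == {"poisson"}
    assert set(coef[coef.response == "wet_weight"]["family"]) == {"gaussian"}
    assert "fa_score" in res.skipped
    assert set(res.diagnostics.columns) >= {"resid_normality_p", "scale_location_slope"}


def test_mode_mismatch_raises():
    rng = np.random.default_rng(9)
    df = _records_frame(rng)
    with pytest.raises(ValueError, match="mesocosm"):
        run_full_analysis(df, mode="mesocosm")


def test_half_integer_counts_are_rounded_for_poisson():
    rng = np.random.default_rng(10)
    df = _records_frame(rng)
    df["n_cells"] = df["n_cells"] + 0.5  # pair means of counts
    res = run_full_analysis(df, mode="insecticide", responses=["n_cells"])
    assert "n_cells" in res.fits


def test_bh_switch_adds_adjusted_pvalues():
    rng = np.random.default_rng(11)
    df = _records_frame(rng)
    res = run_full_analysis(df, mode="insecticide", bh_correct=True,
                            responses=["wet_weight", "nrmse_width"])
    assert "p_bh" in res.coefficients.columns
    assert ((res.coefficients["p_bh"] + 1e-12) >= res.coefficients["p"]).all()
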