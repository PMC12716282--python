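"""The stressor-effect model layer.

Each response variable is fitted with a generalized linear model: count
responses (days to emergence, cell and junction counts, subtract values)
with a Poisson distribution and log link, everything else gaussian with an
identity link.  Per-coefficient significance uses a t-test for gaussian
models and a Wald z-test for Poisson models.  For the factorial (mesocosm)
mode, per-term Type-II likelihood-ratio chi-square tests compare nested
models; gaussian LR statistics use the fixed-scale profile-deviance
convention ``n * log(RSS_reduced / RSS_full)``.

Effect sizes are expressed as predicted percentage changes relative to the
baseline group: model predictions are generated for every observed
covariate row at each factor level (hence averaged over the levels of the
other factors), group means are compared with the baseline mean, and two
standard errors are reported — the prediction-spread SE
(sd of within-combination predictions / sqrt(n), relative to the baseline
mean) and a delta-method Wald SE propagated from the coefficient
covariance, which is the one to use for coverage statements.

No multiple-testing correction is applied by default; a Benjamini-Hochberg
switch is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "GLMResult",
    "StressAnalysis",
    "fit_glm",
    "lr_chisq_tests",
    "percentage_changes",
    "run_full_analysis",
    "FAMILY_BY_RESPONSE",
    "RESPONSES_INSECTICIDE",
    "RESPONSES_MESOCOSM",
]

POISSON_RESPONSES = (
    "days_to_emergence",
    "n_cells",
    "n_junctions",
    "subtract_cells",
    "subtract_junctions",
)

_COMMON_RESPONSES = [
    "wet_weight",
    "fa_score",
    "subtract_cells",
    "subtract_junctions",
    "wing_area",
    "wing_area_diff",
    "wing_length",
    "wing_perimeter",
    "wing_width",
    "n_cells",
    "n_junctions",
    "nrmse_area",
    "nrmse_length",
    "nrmse_width",
    "nrmse_circularity",
    "mean_dist_centroids",
    "mean_dist_junctions",
    "mean_dist_outlines",
    "wing_load",
]
RESPONSES_INSECTICIDE = ["days_to_emergence", "wet_weight_gain", *_COMMON_RESPONSES]
RESPONSES_MESOCOSM = list(_COMMON_RESPONSES)

FAMILY_BY_RESPONSE = {r: ("poisson" if r in POISSON_RESPONSES else "gaussian")
                      for r in set(RESPONSES_INSECTICIDE) | set(RESPONSES_MESOCOSM)}


@dataclass
class GLMResult:
    """One fitted GLM: estimates, tests and fit diagnostics."""

    response: str
    family: str  # "gaussian" (identity link) | "poisson" (log link)
    params: pd.Series
    bse: pd.Series
    statistic: pd.Series  # t (gaussian) or Wald z (poisson)
    pvalues: pd.Series
    deviance: float
    df_resid: int
    converged: bool
    n: int
    _sm_result: object = field(repr=False, default=None)
    _design: pd.DataFrame = field(repr=False, default=None)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Response-scale predictions for a design matrix."""
        eta = X[self.params.index].to_numpy() @ self.params.to_numpy()
        return np.exp(eta) if self.family == "poisson" else eta

    def cov_params(self) -> np.ndarray:
        return np.asarray(self._sm_result.cov_params())


def _check_design(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # name the aliased columns via QR pivoting
        _, r = np.linalg.qr(arr)
        bad = [X.columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-8] if r.shape[0] >= X.shape[1] else list(X.columns)
        raise ValueError(f"aliased (collinear) design columns: {bad}")


def fit_glm(y, X: pd.DataFrame, family: str, response: str = "y") -> GLMResult:
    """Fit one GLM (gaussian-identity or poisson-log).

    Gaussian models are fitted by least squares with t-tests on the
    coefficients; Poisson models by IRLS with Wald z-tests.  Rank-deficient
    designs raise, naming the collinear columns; non-convergence is flagged
    on the result rather than silently returned.
    """
    y = np.asarray(y, dtype=float)
    if family not in ("gaussian", "poisson"):
        raise ValueError("family must be 'gaussian' or 'poisson'")
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    _check_design(X)
    if family == "poisson":
        if np.any(y < 0):
            raise ValueError("Poisson response must be nonnegative")
        if not np.allclose(y, np.round(y)):
            warnings.warn(f"{response}: Poisson response rounded to integers")
            y = np.round(y)
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=200, tol=1e-10)
        converged = bool(getattr(res, "converged", True))
        stat = res.tvalues  # Wald z for GLM
        pvals = res.pvalues
        deviance = float(res.deviance)
        df_resid = int(res.df_resid)
    else:
        res = sm.OLS(y, X).fit()
        converged = True
        stat = res.tvalues
        pvals = res.pvalues
        deviance = float(res.ssr)
        df_resid = int(res.df_resid)
    return GLMResult(
        response=response,
        family=family,
        params=pd.Series(res.params, index=X.columns),
        bse=pd.Series(res.bse, index=X.columns),
        statistic=pd.Series(stat, index=X.columns),
        pvalues=pd.Series(pvals, index=X.columns),
        deviance=deviance,
        df_resid=df_resid,
        converged=converged,
        n=len(y),
        _sm_result=res,
        _design=X,
    )


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _design_mesocosm(data: pd.DataFrame, interaction: bool = True) -> pd.DataFrame:
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    X["bti"] = data["bti"].astype(float)
    X["hydrology"] = data["hydrology"].astype(float)
    if interaction:
        X["bti:hydrology"] = X["bti"] * X["hydrology"]
    X["sex_m"] = (data["sex"] == "m").astype(float)
    return X


def _design_insecticide(data: pd.DataFrame, coding: str = "continuous") -> pd.DataFrame:
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    if coding == "continuous":
        X["concentration"] = data["concentration"].astype(float)
    elif coding == "factor":
        levels = sorted(data["concentration"].unique())
        for lv in levels[1:]:
            X[f"concentration[{lv:g}]"] = (data["concentration"] == lv).astype(float)
    else:
        raise ValueError("coding must be 'continuous' or 'factor'")
    X["sex_m"] = (data["sex"] == "m").astype(float)
    return X


# ---------------------------------------------------------------------------
# likelihood-ratio tests
# ---------------------------------------------------------------------------

def _lr_stat(fit_full: GLMResult, fit_reduced: GLMResult) -> float:
    if fit_full.family == "poisson":
        return fit_reduced.deviance - fit_full.deviance
    # gaussian, fixed-scale profile-deviance convention
    return fit_full.n * np.log(fit_reduced.deviance / fit_full.deviance)


def lr_chisq_tests(data: pd.DataFrame, response: str, family: str) -> pd.DataFrame:
    """Type-II likelihood-ratio chi-square tests for the factorial mode.

    Terms: ``bti``, ``hydrology``, ``sex`` (each tested against the additive
    model without the term, respecting marginality) and ``bti:hydrology``
    (tested against the full additive-plus-interaction model).
    """
    y = data[response]
    full_int = fit_glm(y, _design_mesocosm(data, interaction=True), family, response)
    additive = fit_glm(y, _design_mesocosm(data, interaction=False), family, response)

    rows = []
    for term in ("bti", "hydrology", "sex"):
        col = "sex_m" if term == "sex" else term
        Xr = _design_mesocosm(data, interaction=False).drop(columns=[col])
        reduced = fit_glm(y, Xr, family, response)
        chi2 = _lr_stat(additive, reduced)
        rows.append({"response": response, "term": term, "chisq": chi2, "df": 1,
                     "p": float(sps.chi2.sf(chi2, 1))})
    chi2 = _lr_stat(full_int, additive)
    rows.append({"response": response, "term": "bti:hydrology", "chisq": chi2, "df": 1,
                 "p": float(sps.chi2.sf(chi2, 1))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# percentage changes
# ---------------------------------------------------------------------------

def _group_mean_prediction(fit: GLMResult, X: pd.DataFrame, setting: dict) -> tuple[np.ndarray, pd.DataFrame]:
    Xc = X.copy()
    for col, val in setting.items():
        Xc[col] = val
    if "bti" in Xc.columns and "bti:hydrology" in Xc.columns:
        Xc["bti:hydrology"] = Xc["bti"] * Xc["hydrology"]
    Xc = Xc[list(fit.params.index)]  # counterfactual columns absent from the fit are ignored
    return fit.predict(Xc), Xc


def _pct_wald_se(fit: GLMResult, X_treat: pd.DataFrame, X_base: pd.DataFrame) -> float:
    """Delta-method SE of 100*(mean_t - mean_b)/mean_b over the coefficient covariance."""
    beta = fit.params.to_numpy()
    cov = fit.cov_params()

    def pct(b):
        if fit.family == "poisson":
            mt = np.exp(X_treat.to_numpy() @ b).mean()
            mb = np.exp(X_base.to_numpy() @ b).mean()
        else:
            mt = (X_treat.to_numpy() @ b).mean()
            mb = (X_base.to_numpy() @ b).mean()
        return 100.0 * (mt - mb) / mb

    eps = 1e-6 * np.maximum(np.abs(beta), 1.0)
    grad = np.empty_like(beta)
    for k in range(len(beta)):
        bp, bm = beta.copy(), beta.copy()
        bp[k] += eps[k]
        bm[k] -= eps[k]
        grad[k] = (pct(bp) - pct(bm)) / (2 * eps[k])
    return float(np.sqrt(grad @ cov @ grad))


def percentage_changes(fit: GLMResult, data: pd.DataFrame, mode: str,
                       coding: str = "continuous") -> pd.DataFrame:
    """Predicted percentage changes relative to the baseline group.

    For every contrast, predictions are made for all observed covariate rows
    with the contrasted factor(s) set counterfactually, so each group mean
    is averaged over the levels of the other factors.  Baseline: the control
    level (0 dose / untreated).  ``se_pred`` is the prediction-spread SE
    (sd within combination / sqrt(n), relative to the baseline mean);
    ``se_wald`` the delta-method sampling SE of the estimate.
    """
    X = fit._design
    rows = []

    def contrast(label, setting_treat, setting_base):
        pt, Xt = _group_mean_prediction(fit, X, setting_treat)
        pb, Xb = _group_mean_prediction(fit, X, setting_base)
        mb, mt = pb.mean(), pt.mean()
        if mb <= 0 and fit.family == "poisson":
            raise ValueError("baseline mean <= 0: percentage change undefined")
        pct = 100.0 * (mt - mb) / mb
        se_pred = 100.0 * (pt.std(ddof=1) / np.sqrt(len(pt))) / abs(mb) if len(pt) > 1 else 0.0
        se_wald = _pct_wald_se(fit, Xt, Xb)
        rows.append({"response": fit.response, "contrast": label, "pct_change": pct,
                     "se_pred": se_pred, "se_wald": se_wald, "n_predictions": len(pt),
                     "baseline_mean": mb, "treatment_mean": mt})

    if mode == "mesocosm":
        contrast("bti", {"bti": 1.0}, {"bti": 0.0})
        contrast("hydrology", {"hydrology": 1.0}, {"hydrology": 0.0})
        # interaction reading: effect of the treatment evaluated under altered hydrology
        contrast("bti|hydrology=1", {"bti": 1.0, "hydrology": 1.0}, {"bti": 0.0, "hydrology": 1.0})
        contrast("sex_m", {"sex_m": 1.0}, {"sex_m": 0.0})
    elif mode == "insecticide":
        if coding == "continuous":
            cmax = float(data["concentration"].max())
            contrast(f"concentration={cmax:g}", {"concentration": cmax}, {"concentration": 0.0})
        else:
            for col in [c for c in X.columns if c.startswith("concentration[")]:
                setting = {c: 0.0 for c in X.columns if c.startswith("concentration[")}
                contrast(col, {**setting, col: 1.0}, setting)
        contrast("sex_m", {"sex_m": 1.0}, {"sex_m": 0.0})
    else:
        raise ValueError("mode must be 'insecticide' or 'mesocosm'")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

@dataclass
class StressAnalysis:
    """Results bundle of one cohort analysis."""

    mode: str
    coefficients: pd.DataFrame
    lr_tests: pd.DataFrame | None
    pct_changes: pd.DataFrame
    diagnostics: pd.DataFrame
    fits: dict
    skipped: list

    def save(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.coefficients.to_csv(outdir / "coefficients.csv", index=False, float_format="%.10g")
        if self.lr_tests is not None:
            self.lr_tests.to_csv(outdir / "lr_tests.csv", index=False, float_format="%.10g")
        self.pct_changes.to_csv(outdir / "pct_changes.csv", index=False, float_format="%.10g")
        self.diagnostics.to_csv(outdir / "diagnostics.csv", index=False, float_format="%.10g")


def _diagnostics_row(fit: GLMResult, y: np.ndarray) -> dict:
    """Numerical stand-ins for the visual residual checks (QQ, scale-location)."""
    mu = fit.predict(fit._design)
    resid = y - mu
    if fit.family == "poisson":
        with np.errstate(divide="ignore", invalid="ignore"):
            dr = np.sign(resid) * np.sqrt(2 * (np.where(y > 0, y * np.log(np.where(y > 0, y, 1) / mu), 0) - (y - mu)))
        resid = np.where(np.isfinite(dr), dr, 0.0)
    try:
        _, qq_p = sps.normaltest(resid)
    except ValueError:
        qq_p = float("nan")
    sd = resid.std(ddof=1) or 1.0
    slope = float(sps.linregress(mu, np.sqrt(np.abs(resid / sd))).slope) if len(np.unique(mu)) > 1 else 0.0
    return {"response": fit.response, "resid_normality_p": float(qq_p),
            "scale_location_slope": slope, "converged": fit.converged}


def run_full_analysis(
    records: pd.DataFrame,
    mode: str,
    coding: str = "continuous",
    bh_correct: bool = False,
    responses: list[str] | None = None,
) -> StressAnalysis:
    """Fit every response of one mode and assemble the results bundle.

    ``records`` is the per-individual (x wing type) table produced by the
    measurement pipeline, with covariate columns for the mode
    (``concentration``+``sex`` or ``bti``+``hydrology``+``sex``).  Unknown
    or absent responses are skipped with a warning.  ``bh_correct`` adds
    Benjamini-Hochberg adjusted p-values (off by default).
    """
    if mode == "insecticide":
        if "concentration" not in records.columns:
            raise ValueError("insecticide mode requires a 'concentration' column")
        wanted = responses or RESPONSES_INSECTICIDE
        design_fn = lambda d: _design_insecticide(d, coding=coding)
    elif mode == "mesocosm":
        if not {"bti", "hydrology"} <= set(records.columns):
            raise ValueError("mesocosm mode requires 'bti' and 'hydrology' columns")
        wanted = responses or RESPONSES_MESOCOSM
        design_fn = lambda d: _design_mesocosm(d, interaction=True)
    else:
        raise ValueError("mode must be 'insecticide' or 'mesocosm'")

    coef_rows, lr_frames, pct_frames, diag_rows, skipped, fits = [], [], [], [], [], {}
    for resp in wanted:
        if resp not in records.columns:
            skipped.append(resp)
            warnings.warn(f"response {resp!r} not in records; skipped")
            continue
        sub = records.dropna(subset=[resp]).reset_index(drop=True)
        if len(sub) < 5:
            skipped.append(resp)
            warnings.warn(f"response {resp!r} has too few observations; skipped")
            continue
        family = FAMILY_BY_RESPONSE.get(resp, "gaussian")
        y = sub[resp].to_numpy(dtype=float)
        if family == "poisson" and not np.allclose(y, np.round(y)):
            y = np.round(y)  # pair means of counts can be half-integers
        if np.ptp(y) == 0:
            skipped.append(resp)
            warnings.warn(f"response {resp!r} is constant; skipped")
            continue
        X = design_fn(sub)
        fit = fit_glm(y, X, family, response=resp)
        fits[resp] = fit
        for term in X.columns:
            coef_rows.append({"response": resp, "family": family, "term": term,
                              "estimate": fit.params[term], "se": fit.bse[term],
                              "statistic": fit.statistic[term], "p": fit.pvalues[term]})
        if mode == "mesocosm":
            lr_frames.append(lr_chisq_tests(sub.assign(**{resp: y}), resp, family))
        pct_frames.append(percentage_changes(fit, sub, mode, coding=coding))
        diag_rows.append(_diagnostics_row(fit, y))

    coefficients = pd.DataFrame(coef_rows)
    lr_tests = pd.concat(lr_frames, ignore_index=True) if lr_frames else None
    pct_changes = pd.concat(pct_frames, ignore_index=True) if pct_frames else pd.DataFrame()
    diagnostics = pd.DataFrame(diag_rows)
    if bh_correct and len(coefficients):
        from statsmodels.stats.multitest import multipletests

        coefficients["p_bh"] = multipletests(coefficients["p"], method="fdr_bh")[1]
        if lr_tests is not None and len(lr_tests):
            lr_tests["p_bh"] = multipletests(lr_tests["p"], method="fdr_bh")[1]
    return StressAnalysis(mode=mode, coefficients=coefficients, lr_tests=lr_tests,
                          pct_changes=pct_changes, diagnostics=diagnostics,
                          fits=fits, skipped=skipped)
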