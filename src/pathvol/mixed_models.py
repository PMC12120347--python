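"""Mixed-effects models comparing habitat-volume estimates and overlap.

Linear mixed models (LMMs) with a random intercept per fish (or fish pair)
are fitted by maximum likelihood through :class:`statsmodels` ``MixedLM``;
ML rather than REML because models are compared across fixed-effect
structures by AIC.  AIC counts fixed-effect coefficients plus both variance
components, matching the convention of lme4.

The binary overlap-presence model is a random-intercept logistic GLMM.  The
installed Python stack has no frequentist fit for this, so the marginal
likelihood is integrated here by Gauss-Hermite quadrature (exact ML up to
quadrature error; 25 nodes) and maximized with BFGS, with a ridge-penalized
refit as the fallback under complete separation.

Variance explained is reported as marginal / conditional R^2 in the sense of
Nakagawa & Schielzeth: fixed-effect variance over total, and fixed plus
random over total, where the logistic residual variance is the latent
logistic variance pi^2/3.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import patsy
from scipy import optimize
from scipy.special import logsumexp
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools import numdiff

logger = logging.getLogger("pathvol")

_LATENT_LOGISTIC_VAR = np.pi ** 2 / 3.0


@dataclass
class MixedModelResult:
    """One fitted mixed model: coefficients, AIC, and variance accounting."""

    label: str
    model_type: str                  # "lmm" or "logistic"
    params: "pd.Series"              # fixed-effect estimates
    bse: "pd.Series"                 # standard errors
    df_resid: float                  # residual df used for t tests
    df_method: str                   # how df was obtained
    aic: float
    loglik: float
    var_fixed: float
    var_random: float
    var_resid: float
    fit_method: str                  # "ML"
    n_obs: int
    n_groups: int
    converged: bool
    penalized: bool = False
    delta_aic: float = np.nan        # filled by rank_models

    @property
    def r2_marginal(self) -> float:
        return r2_nakagawa(self.var_fixed, self.var_random, self.var_resid)[0]

    @property
    def r2_conditional(self) -> float:
        return r2_nakagawa(self.var_fixed, self.var_random, self.var_resid)[1]

    def summary_row(self) -> dict:
        return {
            "model": self.label,
            "AIC": self.aic,
            "dAIC": self.delta_aic,
            "R2_marginal": self.r2_marginal,
            "R2_conditional": self.r2_conditional,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
        }

    def coef_frame(self) -> pd.DataFrame:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.params / self.bse
        return pd.DataFrame({
            "term": self.params.index,
            "estimate": self.params.values,
            "std_error": self.bse.values,
            "df": self.df_resid,
            "t_value": t.values,
        })


def r2_nakagawa(var_fixed: float, var_random: float,
                var_resid: float) -> tuple[float, float]:
    """(marginal, conditional) variance explained from variance components."""
    total = var_fixed + var_random + var_resid
    if total <= 0:
        raise ValueError("total variance must be > 0")
    return var_fixed / total, (var_fixed + var_random) / total


def rank_models(results: list[MixedModelResult]) -> list[MixedModelResult]:
    """Fill delta_aic within one comparison set; best model first."""
    best = min(r.aic for r in results)
    for r in results:
        r.delta_aic = r.aic - best
    return sorted(results, key=lambda r: r.aic)


# ---------------------------------------------------------------------------
# Linear mixed models (statsmodels MixedLM, ML)
# ---------------------------------------------------------------------------

def fit_lmm(df: pd.DataFrame, formula: str, group_col: str,
            label: str | None = None) -> MixedModelResult:
    """Random-intercept LMM fitted by ML; AIC counts k_fixed + 2 variances."""
    groups = df[group_col]
    n_groups = groups.nunique()
    if n_groups < 2:
        raise ValueError(
            f"random intercept per {group_col!r} needs >= 2 groups, "
            f"got {n_groups}")
    model = MixedLM.from_formula(formula, data=df, groups=groups)
    res = None
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                cand = model.fit(reml=False, method=method, disp=False)
            except Exception:
                continue
            if np.isfinite(cand.llf):
                res = cand
                break
    if res is None:
        raise RuntimeError(f"LMM fit failed for {formula!r}")
    k = len(res.fe_params) + 2  # fixed effects + RE variance + residual variance
    aic = 2 * k - 2 * res.llf
    exog = model.exog
    var_fixed = float(np.var(exog @ res.fe_params.values, ddof=1)) \
        if exog.shape[1] else 0.0
    if exog.shape[1] == 1 and np.ptp(exog) == 0:
        var_fixed = 0.0  # intercept-only: no fixed-effect variance
    var_random = float(res.cov_re.iloc[0, 0])
    var_resid = float(res.scale)
    return MixedModelResult(
        label=label or formula,
        model_type="lmm",
        params=res.fe_params,
        bse=res.bse_fe,
        df_resid=float(len(df) - len(res.fe_params)),
        df_method="residual",
        aic=float(aic),
        loglik=float(res.llf),
        var_fixed=var_fixed,
        var_random=var_random,
        var_resid=var_resid,
        fit_method="ML",
        n_obs=len(df),
        n_groups=int(n_groups),
        converged=bool(getattr(res, "converged", True)),
    )


def _with_log_volume(df: pd.DataFrame, col: str = "volume_m3") -> pd.DataFrame:
    out = df.copy()
    if "log_volume" not in out.columns:
        if (out[col] <= 0).any():
            raise ValueError("volumes must be > 0 to log-transform")
        out["log_volume"] = np.log(out[col])
    return out


def fit_volume_npositions(df: pd.DataFrame) -> list[MixedModelResult]:
    """Does the daily position count drive habitat volume?

    Three ML LMMs of log_e volume with a random intercept per fish:
    intercept-only, linear in n_positions, and linear + quadratic.  Returns
    the set ranked by AIC with delta_aic filled.
    """
    d = _with_log_volume(df)
    d["n_positions_sq"] = d["n_positions"].astype(float) ** 2
    specs = [
        ("intercept_only", "log_volume ~ 1"),
        ("n_positions", "log_volume ~ n_positions"),
        ("n_positions + n_positions^2",
         "log_volume ~ n_positions + n_positions_sq"),
    ]
    results = [fit_lmm(d, f, "fish_id", label) for label, f in specs]
    return rank_models(results)


def fit_volume_vswim(df: pd.DataFrame) -> list[MixedModelResult]:
    """Effect of the v_swim quantile and parameterization mode on volume.

    Requires one volume per (fish-day, quantile, mode) cell; fits an ML LMM
    of log_e volume on quantile + mode (both categorical) against the
    intercept-only model, random intercept per fish.
    """
    d = _with_log_volume(df)
    specs = [
        ("intercept_only", "log_volume ~ 1"),
        ("quantile + mode", "log_volume ~ C(vswim_quantile) + C(vswim_mode)"),
    ]
    results = [fit_lmm(d, f, "fish_id", label) for label, f in specs]
    return rank_models(results)


def fit_volume_method_season(df: pd.DataFrame) -> list[MixedModelResult]:
    """Method (ppv / kud2d / kud3d) and season effects on habitat volume.

    Five ML LMMs with a fish random intercept: interaction, additive,
    method-only, season-only, and intercept-only, ranked by AIC.  Missing
    method or season levels degrade the comparison gracefully (with a
    warning) rather than failing.
    """
    d = _with_log_volume(df)
    for col, expected in (("method", {"ppv", "kud2d", "kud3d"}),
                          ("season", {"spring", "summer", "fall", "winter"})):
        present = set(d[col].unique())
        missing = expected - present
        if missing:
            logger.warning("fit_volume_method_season: %s level(s) %s absent",
                           col, sorted(missing))
    specs = [
        ("method * season",
         "log_volume ~ C(method) + C(season) + C(method):C(season)"),
        ("method + season", "log_volume ~ C(method) + C(season)"),
        ("method", "log_volume ~ C(method)"),
        ("season", "log_volume ~ C(season)"),
        ("intercept_only", "log_volume ~ 1"),
    ]
    results = [fit_lmm(d, f, "fish_id", label) for label, f in specs]
    return rank_models(results)


# ---------------------------------------------------------------------------
# Random-intercept logistic GLMM (Gauss-Hermite ML)
# ---------------------------------------------------------------------------

def _gh_negloglik(params, y, X, group_index, n_groups, nodes, log_wts, penalty):
    beta = params[:-1]
    sigma = np.exp(params[-1])
    eta = X @ beta                                   # (n,)
    lin = eta[:, None] + np.sqrt(2.0) * sigma * nodes[None, :]  # (n, K)
    ll_obs = y[:, None] * lin - np.logaddexp(0.0, lin)          # (n, K)
    group_ll = np.zeros((n_groups, lin.shape[1]))
    np.add.at(group_ll, group_index, ll_obs)
    total = logsumexp(group_ll + log_wts[None, :], axis=1).sum()
    return -(total - penalty * float(beta @ beta))


def fit_logistic_mixed(
    df: pd.DataFrame,
    formula: str,
    group_col: str,
    label: str | None = None,
    n_quad: int = 25,
    penalty: float = 0.0,
    _is_refit: bool = False,
) -> MixedModelResult:
    """ML random-intercept logistic regression via Gauss-Hermite quadrature.

    ``formula`` is a patsy formula whose left side is the 0/1 response.
    On apparent complete separation (non-convergence or runaway
    coefficients) the model is refitted with a ridge penalty on the fixed
    effects and the random-intercept SD held at its starting value (the
    variance component is unidentifiable under separation); the result is
    flagged ``penalized``.
    """
    y_mat, X_mat = patsy.dmatrices(formula, df, return_type="dataframe")
    y = np.asarray(y_mat).ravel().astype(float)
    X = np.asarray(X_mat, dtype=float)
    term_names = list(X_mat.columns)
    codes, _ = pd.factorize(df[group_col])
    n_groups = int(codes.max() + 1)
    if n_groups < 2:
        raise ValueError("random intercept needs >= 2 groups")
    nodes, wts = np.polynomial.hermite.hermgauss(n_quad)
    log_wts = np.log(wts) - 0.5 * np.log(np.pi)
    log_sigma0 = np.log(0.5)
    args = (y, X, codes, n_groups, nodes, log_wts, penalty)
    if penalty > 0:
        # separation fallback: sigma held fixed, ridge on the betas
        def objective(b):
            return _gh_negloglik(np.append(b, log_sigma0), *args)

        res_b = optimize.minimize(objective, np.zeros(X.shape[1]),
                                  method="BFGS",
                                  options={"maxiter": 500, "gtol": 1e-6})
        res = res_b
        res.x = np.append(res_b.x, log_sigma0)
    else:
        x0 = np.zeros(X.shape[1] + 1)
        x0[-1] = log_sigma0
        res = optimize.minimize(_gh_negloglik, x0, args=args, method="BFGS",
                                options={"maxiter": 500, "gtol": 1e-6})
    beta = res.x[:-1]
    separated = (not np.all(np.isfinite(res.x))) \
        or np.max(np.abs(beta)) > 15.0 \
        or (not res.success and res.x[-1] > 3.0)
    if separated and not _is_refit:
        logger.warning("logistic mixed model %r: apparent separation; "
                       "refitting with ridge penalty", label or formula)
        out = fit_logistic_mixed(df, formula, group_col, label=label,
                                 n_quad=n_quad, penalty=1.0, _is_refit=True)
        out.penalized = True
        return out
    try:
        hess = numdiff.approx_hess1(res.x, _gh_negloglik, args=args)
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov)[:-1], 0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(beta), np.nan)
    sigma = float(np.exp(res.x[-1]))
    nll = _gh_negloglik(res.x, y, X, codes, n_groups, nodes, log_wts, 0.0)
    k = X.shape[1] + 1
    var_fixed = float(np.var(X @ beta, ddof=1)) if X.shape[1] > 1 else 0.0
    return MixedModelResult(
        label=label or formula,
        model_type="logistic",
        params=pd.Series(beta, index=term_names),
        bse=pd.Series(se, index=term_names),
        df_resid=float(len(y) - X.shape[1]),
        df_method="residual",
        aic=float(2 * k + 2 * nll),
        loglik=float(-nll),
        var_fixed=var_fixed,
        var_random=sigma ** 2,
        var_resid=_LATENT_LOGISTIC_VAR,
        fit_method="ML",
        n_obs=len(y),
        n_groups=n_groups,
        converged=bool(res.success),
        penalized=penalty > 0,
    )


def fit_overlap_models(df: pd.DataFrame) -> dict[str, list[MixedModelResult]]:
    """Presence and magnitude models for daily pairwise habitat overlap.

    ``df`` needs columns present (0/1), overlap_m3, season, method, and
    fish_a/fish_b (or a precomputed ``pair`` column).  Fits

    * a logistic GLMM of overlap presence on season + method + interaction
      with a random intercept per fish pair, against the null model;
    * an LMM of log_e overlap volume on the same effects, restricted to the
      records where overlap is present, against its null.

    Returns {"presence": [...], "magnitude": [...]}, each set AIC-ranked.
    """
    d = df.copy()
    if "pair" not in d.columns:
        d["pair"] = d["fish_a"].astype(str) + "|" + d["fish_b"].astype(str)
    d["present"] = d["present"].astype(int)
    multi_season = d["season"].nunique() > 1
    multi_method = d["method"].nunique() > 1
    terms = []
    if multi_season:
        terms.append("C(season)")
    if multi_method:
        terms.append("C(method)")
    if multi_season and multi_method:
        terms.append("C(season):C(method)")
    fixed = " + ".join(terms) if terms else "1"
    presence = rank_models([
        fit_logistic_mixed(d, "present ~ 1", "pair", label="intercept_only"),
        fit_logistic_mixed(d, f"present ~ {fixed}", "pair",
                           label="season * method"),
    ])
    present_only = d[d["present"] == 1].copy()
    if (present_only["overlap_m3"] <= 0).any():
        raise AssertionError("present records must have positive overlap")
    present_only["log_volume"] = np.log(present_only["overlap_m3"])
    magnitude = rank_models([
        fit_lmm(present_only, "log_volume ~ 1", "pair", label="intercept_only"),
        fit_lmm(present_only, f"log_volume ~ {fixed}", "pair",
                label="season * method"),
    ])
    return {"presence": presence, "magnitude": magnitude}


def model_summary_frame(results: list[MixedModelResult]) -> pd.DataFrame:
    """Comparison table (model, AIC, dAIC, R2m, R2c) for one model set."""
    return pd.DataFrame([r.summary_row() for r in results])
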