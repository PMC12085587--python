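"""Growth–environment statistics: relative growth, GLM fits,
repeated-measures ANOVA with Tukey HSD, and a Gaussian linear mixed model
with colony random intercepts and AR(1) serial residuals.

The mixed model realises the growth equation

    extension ~ K_d490 + SST_summer + DHW + (1 | location) + (1 | core) + AR(1)

as random intercepts plus a first-order autocorrelation of within-core
annual residuals, fitted by maximum likelihood so that AIC is comparable
across fixed-effect structures.  Covariates are standardised internally for
numerical stability and coefficients reported on the original scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "ModelFit",
    "MixedModelFit",
    "RmAnovaResult",
    "relative_extension",
    "composite",
    "fit_glm",
    "rm_anova_tukey",
    "fit_mixed_model",
    "model_selection_aic",
]

log = logging.getLogger(__name__)

BASELINE_PERIOD = (1998, 2012)
FULL_PERIOD = (1998, 2016)


# ---------------------------------------------------------------- relative growth

def relative_extension(table: pd.DataFrame,
                       baseline: tuple = BASELINE_PERIOD,
                       full_period: tuple = FULL_PERIOD) -> tuple:
    """Per-core annual extension as % change from the core's baseline mean.

    Only cores covering every year of ``full_period`` are included (shorter
    records would bias composites); the excluded core ids are returned
    alongside the series.  ``rel = 100·(ext − mean_baseline)/mean_baseline``,
    so each core's baseline-period mean relative extension is exactly zero.
    """
    years_needed = set(range(full_period[0], full_period[1] + 1))
    base_years = set(range(baseline[0], baseline[1] + 1))
    if not base_years:
        raise ValueError("empty baseline period")
    rows, excluded = [], []
    for core_id, sub in table.groupby("core_id"):
        have = set(sub["year"].astype(int))
        if not years_needed.issubset(have):
            excluded.append(core_id)
            continue
        sub = sub[sub["year"].between(*full_period)]
        base_mean = sub.loc[sub["year"].isin(base_years), "extension_cm"].mean()
        if base_mean <= 0:
            raise ValueError(f"core {core_id}: non-positive baseline mean")
        for _, r in sub.iterrows():
            rows.append({"core_id": core_id,
                         "location_id": r.get("location_id", ""),
                         "year": int(r["year"]),
                         "relative_extension":
                             100.0 * (r["extension_cm"] - base_mean) / base_mean})
    if excluded:
        log.info("relative_extension: excluded cores with gaps: %s", excluded)
    return pd.DataFrame(rows), excluded


def composite(rel: pd.DataFrame, by: str = "all") -> pd.DataFrame:
    """Arithmetic-mean composite of per-core relative growth, with SE.

    ``by="all"`` averages across every core per year (the archipelago-wide
    composite); ``by="location"`` gives per-location composites.  SE is the
    standard deviation over cores divided by √n, undefined (NaN) for n = 1.
    """
    keys = ["year"] if by == "all" else ["location_id", "year"]
    grouped = rel.groupby(keys)["relative_extension"]
    out = grouped.agg(relative_extension="mean", sd="std", n="size").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] < 2, "se"] = np.nan
    return out.drop(columns="sd")


# ------------------------------------------------------------------------- GLM

@dataclass
class ModelFit:
    """A fitted regression: coefficients, uncertainty and fit quality."""

    name: str
    response: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r_squared: float
    loglik: float
    aic: float
    nobs: int
    converged: bool = True

    def __post_init__(self):
        expected = 2 * self.n_parameters - 2 * self.loglik
        if abs(self.aic - expected) > 1e-6 * max(1.0, abs(expected)):
            raise ValueError("AIC inconsistent with 2k - 2 logLik")

    @property
    def n_parameters(self) -> int:
        return getattr(self, "_k", len(self.params) + 1)


def fit_glm(data: pd.DataFrame, response: str, covariates,
            name: str | None = None) -> ModelFit:
    """Identity-link Gaussian GLM (ordinary least squares).

    Slope p-values are two-sided t tests; R² is the coefficient of
    determination.  A covariate with zero variance is rejected.
    """
    covariates = [covariates] if isinstance(covariates, str) else list(covariates)
    sub = data[[response] + covariates].dropna()
    y = sub[response].to_numpy(float)
    X = sub[covariates].to_numpy(float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("not enough observations for the number of covariates")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("covariate with zero variance")
    res = sm.OLS(y, sm.add_constant(X)).fit()
    names = ["intercept"] + covariates
    k = len(names) + 1  # + residual variance, so AIC matches 2k - 2 logLik
    fit = ModelFit(
        name=name or f"{response} ~ {' + '.join(covariates)}",
        response=response,
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        r_squared=float(res.rsquared),
        loglik=float(res.llf),
        aic=float(2 * k - 2 * res.llf),
        nobs=int(res.nobs),
    )
    fit._k = k
    return fit


# ---------------------------------------------------------- repeated-measures ANOVA

@dataclass
class RmAnovaResult:
    """Within-subject one-way ANOVA with Tukey HSD on the factor means."""

    anova: pd.DataFrame        # source, ss, df, ms, F, p
    tukey: pd.DataFrame        # pair, diff, q, p, significant
    excluded_subjects: list
    n_subjects: int
    n_levels: int

    @property
    def F(self) -> float:
        return float(self.anova.loc[self.anova["source"] == "bins", "F"].iloc[0])

    @property
    def p(self) -> float:
        return float(self.anova.loc[self.anova["source"] == "bins", "p"].iloc[0])


def rm_anova_tukey(data: pd.DataFrame, subject: str = "core_id",
                   within: str = "bin", value: str = "extension_cm",
                   alpha: float = 0.05) -> RmAnovaResult:
    """Repeated-measures ANOVA (subjects × within-factor) with Tukey post hoc.

    Sums of squares partition as SS_total = SS_bins + SS_subjects + SS_error;
    F has (b−1, (b−1)(n−1)) degrees of freedom.  Tukey HSD uses the
    studentized range with the within-subject error term.  Subjects missing
    any factor level are excluded listwise and reported.
    """
    wide = data.pivot_table(index=subject, columns=within, values=value,
                            aggfunc="mean")
    excluded = wide.index[wide.isna().any(axis=1)].tolist()
    if excluded:
        log.info("rm_anova: excluded incomplete subjects: %s", excluded)
    wide = wide.dropna()
    n, b = wide.shape
    if n < 2 or b < 2:
        raise ValueError("need at least two complete subjects and two levels")
    x = wide.to_numpy(float)
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    ss_bins = float(n * ((x.mean(axis=0) - grand) ** 2).sum())
    ss_subj = float(b * ((x.mean(axis=1) - grand) ** 2).sum())
    ss_err = ss_total - ss_bins - ss_subj
    df_bins, df_err = b - 1, (b - 1) * (n - 1)
    ms_bins, ms_err = ss_bins / df_bins, ss_err / df_err
    if ms_err > 0:
        F = ms_bins / ms_err
        p = float(stats.f.sf(F, df_bins, df_err))
    else:                       # degenerate: no within-subject error at all
        F = np.inf if ms_bins > 0 else 0.0
        p = 0.0 if ms_bins > 0 else 1.0
    anova = pd.DataFrame([
        {"source": "bins", "ss": ss_bins, "df": df_bins, "ms": ms_bins,
         "F": F, "p": p},
        {"source": "subjects", "ss": ss_subj, "df": n - 1,
         "ms": ss_subj / (n - 1), "F": np.nan, "p": np.nan},
        {"source": "error", "ss": ss_err, "df": df_err, "ms": ms_err,
         "F": np.nan, "p": np.nan},
    ])
    means = wide.mean(axis=0)
    pairs = []
    levels = list(wide.columns)
    for i in range(b):
        for j in range(i + 1, b):
            diff = float(means.iloc[j] - means.iloc[i])
            if ms_err > 0:
                q = abs(diff) / np.sqrt(ms_err / n)
                p_pair = float(stats.studentized_range.sf(q, b, df_err))
            elif diff != 0:
                q, p_pair = np.inf, 0.0
            else:
                q, p_pair = 0.0, 1.0
            pairs.append({"level_a": levels[i], "level_b": levels[j],
                          "diff": diff, "q": q, "p": p_pair,
                          "significant": p_pair < alpha})
    return RmAnovaResult(anova=anova, tukey=pd.DataFrame(pairs),
                         excluded_subjects=excluded, n_subjects=n, n_levels=b)


# ------------------------------------------------------------------ mixed model

@dataclass(frozen=True)
class ModelSpec:
    """Structure of a growth mixed model."""

    response: str = "extension_cm"
    fixed: tuple = ("kd490", "sst_summer", "dhw")
    random: tuple = ("location", "core")
    ar1: bool = True
    name: str = ""

    def label(self) -> str:
        return self.name or (" + ".join(self.fixed) if self.fixed else "intercept-only")


@dataclass
class MixedModelFit:
    """ML fit of the random-intercept AR(1) growth model.

    ``r_squared`` is the marginal R²: variance of the fixed-effect
    predictions over the total (fixed + random + residual) variance.
    """

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    variance_components: dict       # name -> variance (original scale)
    sigma2: float
    rho: float
    loglik: float
    aic: float
    r_squared: float
    nobs: int
    n_parameters: int
    converged: bool
    method: str = "ml"
    df_t: int = 0

    @property
    def name(self) -> str:
        return self.spec.label()

    @property
    def response(self) -> str:
        return self.spec.response

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Fixed-effect intervals on a t reference with core-level degrees of
        freedom (n_cores − p) — conservative for covariates that vary mostly
        between colonies, where normal-theory intervals undercover."""
        if self.df_t > 0:
            q = stats.t.ppf(1 - alpha / 2, self.df_t)
        else:
            q = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame({"lower": self.params - q * self.bse,
                             "upper": self.params + q * self.bse})


def _ar1_corr(years: np.ndarray, rho: float) -> np.ndarray:
    lag = np.abs(years[:, None] - years[None, :])
    return rho ** lag


def _block_structure(df: pd.DataFrame, spec: ModelSpec):
    """Rows grouped into independent location blocks (cores nested within)."""
    blocks = []
    group_col = "location_id" if "location" in spec.random else "core_id"
    for _, sub in df.groupby(group_col, sort=True):
        cores = [g.index.to_numpy() for _, g in sub.groupby("core_id", sort=True)]
        blocks.append((sub.index.to_numpy(), cores))
    return blocks


def _nll_profiled(theta, y, X, df, blocks, spec, reml=False):
    """Profiled negative log-(restricted-)likelihood over variance ratios
    and rho.

    theta packs log variance ratios (per random term) and atanh(rho);
    the residual variance is profiled out in closed form.  With ``reml`` the
    restricted likelihood is used (fixed effects integrated out), which
    reduces the downward bias of variance components at small numbers of
    cores; ML remains the default so AIC is comparable across fixed-effect
    structures.
    """
    i = 0
    g = {}
    for term in spec.random:
        g[term] = float(np.exp(np.clip(theta[i], -15, 8)))
        i += 1
    rho = float(np.tanh(theta[i])) if spec.ar1 else 0.0
    n = len(y)
    years = df["year"].to_numpy(float)
    logdet = 0.0
    Xw_parts, yw_parts = [], []
    for rows, cores in blocks:
        m = len(rows)
        W = np.zeros((m, m))
        pos = {r: k for k, r in enumerate(rows)}
        for core_rows in cores:
            idx = np.array([pos[r] for r in core_rows])
            yr = years[core_rows]
            corr = _ar1_corr(yr, rho) if spec.ar1 else np.eye(len(idx))
            W[np.ix_(idx, idx)] += corr
            if "core" in g:
                W[np.ix_(idx, idx)] += g["core"]
        if "location" in g:
            W += g["location"]
        try:
            L = np.linalg.cholesky(W)
        except np.linalg.LinAlgError:
            return 1e12
        logdet += 2.0 * float(np.log(np.diag(L)).sum())
        Xw_parts.append(np.linalg.solve(L, X[rows]))
        yw_parts.append(np.linalg.solve(L, y[rows]))
    Xw = np.vstack(Xw_parts)
    yw = np.concatenate(yw_parts)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    rss = float(np.sum((yw - Xw @ beta) ** 2))
    if rss <= 0:
        return 1e12
    if reml:
        p = X.shape[1]
        sigma2 = rss / (n - p)
        sign, logdet_xx = np.linalg.slogdet(Xw.T @ Xw)
        if sign <= 0:
            return 1e12
        nll = 0.5 * ((n - p) * np.log(2 * np.pi * sigma2) + logdet
                     + logdet_xx - p * np.log(sigma2) + (n - p))
    else:
        sigma2 = rss / n
        nll = 0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return nll


def fit_mixed_model(data: pd.DataFrame, spec: ModelSpec | None = None,
                    maxiter: int = 400, method: str = "ml") -> MixedModelFit:
    """Fit the Gaussian mixed model by maximum (or restricted maximum)
    likelihood.

    Requires at least two cores.  Covariates are standardised internally (the
    reported coefficients are transformed back to the original units).  Use
    ``method="reml"`` for variance components and intervals (less biased at
    few cores); use the default ML when comparing AIC across fixed-effect
    structures.  Non-convergence raises with optimizer diagnostics rather
    than returning a silently bad fit.
    """
    if method not in ("ml", "reml"):
        raise ValueError("method must be 'ml' or 'reml'")
    reml = method == "reml"
    spec = spec or ModelSpec()
    cols = [spec.response, "core_id", "year"] + list(spec.fixed)
    if "location" in spec.random:
        cols.append("location_id")
    df = data[list(dict.fromkeys(cols))].dropna().reset_index(drop=True)
    if df["core_id"].nunique() < 2:
        raise ValueError("mixed model needs at least two cores")
    y = df[spec.response].to_numpy(float)
    names = ["intercept"] + list(spec.fixed)
    X = np.ones((len(df), len(names)))
    scales, centres = {}, {}
    for j, c in enumerate(spec.fixed, start=1):
        v = df[c].to_numpy(float)
        centres[c], scales[c] = float(v.mean()), float(v.std())
        if scales[c] == 0:
            raise ValueError(f"covariate {c} has zero variance")
        X[:, j] = (v - centres[c]) / scales[c]
    blocks = _block_structure(df, spec)

    n_theta = len(spec.random) + (1 if spec.ar1 else 0)
    if n_theta:
        x0 = np.concatenate([np.full(len(spec.random), np.log(0.3)),
                             [np.arctanh(0.2)] if spec.ar1 else []])
        res = optimize.minimize(
            _nll_profiled, x0, args=(y, X, df, blocks, spec, reml),
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-8})
        if not res.success and res.fun >= 1e12:
            raise RuntimeError(f"mixed-model fit failed: {res.message}")
        theta = res.x
        converged = bool(res.success)
        nll = float(res.fun)
    else:
        theta = np.empty(0)
        converged = True
        nll = _nll_profiled(theta, y, X, df, blocks, spec, reml)

    # Recompute quantities at the optimum.
    i = 0
    ratios = {}
    for term in spec.random:
        ratios[term] = float(np.exp(np.clip(theta[i], -15, 8)))
        i += 1
    rho = float(np.tanh(theta[i])) if spec.ar1 else 0.0
    years = df["year"].to_numpy(float)
    XtWX = np.zeros((X.shape[1], X.shape[1]))
    XtWy = np.zeros(X.shape[1])
    rss_parts = []
    for rows, cores in blocks:
        m = len(rows)
        W = np.zeros((m, m))
        pos = {r: k for k, r in enumerate(rows)}
        for core_rows in cores:
            idx = np.array([pos[r] for r in core_rows])
            corr = _ar1_corr(years[core_rows], rho) if spec.ar1 else np.eye(len(idx))
            W[np.ix_(idx, idx)] += corr
            if "core" in ratios:
                W[np.ix_(idx, idx)] += ratios["core"]
        if "location" in ratios:
            W += ratios["location"]
        L = np.linalg.cholesky(W)
        Xw = np.linalg.solve(L, X[rows])
        yw = np.linalg.solve(L, y[rows])
        XtWX += Xw.T @ Xw
        XtWy += Xw.T @ yw
        rss_parts.append((rows, L))
    beta = np.linalg.solve(XtWX, XtWy)
    rss = 0.0
    for rows, L in rss_parts:
        rw = np.linalg.solve(L, y[rows] - X[rows] @ beta)
        rss += float(rw @ rw)
    sigma2 = rss / (len(y) - X.shape[1] if reml else len(y))
    vcov = sigma2 * np.linalg.inv(XtWX)
    loglik = -nll

    # Back-transform to original covariate units.
    beta_orig = beta.copy()
    se_orig = np.sqrt(np.diag(vcov))
    for j, c in enumerate(spec.fixed, start=1):
        beta_orig[j] = beta[j] / scales[c]
        se_orig[j] = se_orig[j] / scales[c]
        beta_orig[0] -= beta[j] * centres[c] / scales[c]
    # Intercept SE on original scale via the linear map a = T b.
    T = np.eye(len(names))
    for j, c in enumerate(spec.fixed, start=1):
        T[0, j] = -centres[c] / scales[c]
        T[j, j] = 1.0 / scales[c]
    se_orig = np.sqrt(np.diag(T @ vcov @ T.T))

    n_cores = df["core_id"].nunique()
    df_t = max(n_cores - len(names), 0)
    tvals = beta_orig / se_orig
    if df_t > 0:
        pvals = 2 * stats.t.sf(np.abs(tvals), df_t)
    else:
        pvals = 2 * stats.norm.sf(np.abs(tvals))
    var_comp = {term: ratios[term] * sigma2 for term in ratios}
    fitted_fixed = X @ beta
    var_fixed = float(np.var(fitted_fixed))
    total = var_fixed + sum(var_comp.values()) + sigma2
    k = len(names) + 1 + len(ratios) + (1 if spec.ar1 else 0)
    return MixedModelFit(
        spec=spec,
        params=pd.Series(beta_orig, index=names),
        bse=pd.Series(se_orig, index=names),
        pvalues=pd.Series(pvals, index=names),
        variance_components=var_comp,
        sigma2=float(sigma2),
        rho=rho,
        loglik=float(loglik),
        aic=float(2 * k - 2 * loglik),
        r_squared=var_fixed / total,
        nobs=len(y),
        n_parameters=k,
        converged=converged,
        method=method,
        df_t=df_t,
    )


def model_selection_aic(fits: list) -> pd.DataFrame:
    """Rank fits by AIC (ascending) with ΔAIC relative to the best.

    All fits must model the same response; comparing AIC across responses is
    meaningless and rejected.
    """
    if not fits:
        raise ValueError("no fits to rank")
    responses = {f.response for f in fits}
    if len(responses) > 1:
        raise ValueError(f"fits model different responses: {sorted(responses)}")
    rows = [{"name": f.name, "aic": f.aic, "loglik": f.loglik,
             "k": f.n_parameters,
             "r_squared": getattr(f, "r_squared", np.nan)} for f in fits]
    out = pd.DataFrame(rows).sort_values("aic", kind="mergesort").reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out["aic"].iloc[0]
    return out
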