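"""Inferential machinery: change tables, classical tests, mixed-model
associations, chained-equation imputation with Rubin pooling, Little's MCAR
test, and the multiple-regression power routine.

Paired comparisons of the pre- vs post-implantation window summaries use the
paired t-test; non-normal outcomes use rank tests and 2x2 contingency tables
Fisher's exact test. The association of an immediate hemodynamic change with
the quality-of-life index is estimated with a Gaussian linear mixed model
(random intercept per patient, fixed effects timepoint + timepoint x change),
whose interaction coefficient - rescaled to a reporting increment such as
"per 10 ms" - is the quantity of interest.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sst

from .exceptions import (
    ConvergenceError,
    InsufficientDataError,
    ValidationError,
)


@dataclasses.dataclass
class ModelResult:
    """Estimate with uncertainty from any statistical procedure."""

    estimate: float
    se: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float
    n: int
    method: str

    def __post_init__(self):
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12):
                raise ValidationError("estimate must lie inside its confidence interval")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# change tables

def summarize_changes(cohort: pd.DataFrame, variable: str, alpha: float = 0.05) -> dict:
    """One change-table row for ``variable``.

    Expects columns ``{variable}_pre`` and ``{variable}_post``. Returns pre
    and post mean/SD, the mean within-patient change with its t-based CI and
    paired-t p-value, and the mean of per-patient percent changes (percent is
    computed per patient before averaging).
    """
    pre = cohort[f"{variable}_pre"].to_numpy(float)
    post = cohort[f"{variable}_post"].to_numpy(float)
    ok = np.isfinite(pre) & np.isfinite(post)
    pre, post = pre[ok], post[ok]
    n = len(pre)
    if n < 3:
        raise InsufficientDataError(f"{variable}: need >= 3 complete pairs, got {n}")
    d = post - pre
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    if sd_d == 0.0:
        p = 1.0
        ci = (mean_d, mean_d)
        se = 0.0
    else:
        se = sd_d / np.sqrt(n)
        tcrit = sst.t.ppf(1 - alpha / 2, n - 1)
        ci = (mean_d - tcrit * se, mean_d + tcrit * se)
        p = float(sst.ttest_rel(post, pre).pvalue)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * d / pre
    return {
        "variable": variable,
        "n": n,
        "pre_mean": float(pre.mean()),
        "pre_sd": float(pre.std(ddof=1)),
        "post_mean": float(post.mean()),
        "post_sd": float(post.std(ddof=1)),
        "mean_change": mean_d,
        "se_change": float(se),
        "ci_low": float(ci[0]),
        "ci_high": float(ci[1]),
        "pct_change": float(np.nanmean(pct)),
        "p_value": p,
    }


# ---------------------------------------------------------------------------
# classical tests

def compare_distributions(x, y, design: str = "paired", kind: str = "rank") -> ModelResult:
    """Rank tests and Fisher's exact test behind one interface.

    ``kind='rank'``: Wilcoxon signed-rank (paired) or rank-sum/Mann-Whitney
    (independent); exact null for n <= 25 without ties, else normal
    approximation with continuity correction. ``kind='exact_2x2'``: Fisher's
    exact test, ``x`` being a 2x2 count table.
    """
    if kind == "exact_2x2":
        table = np.asarray(x, int)
        if table.shape != (2, 2):
            raise ValidationError("exact_2x2 needs a 2x2 count table")
        res = sst.fisher_exact(table)
        return ModelResult(float(res.statistic), None, None, None,
                           float(res.pvalue), int(table.sum()), "fisher_exact")
    if kind != "rank":
        raise ValidationError(f"unknown kind {kind!r}")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if design == "paired":
        if x.shape != y.shape:
            raise ValidationError("paired samples must have equal length")
        d = x - y
        if np.all(d == 0):
            return ModelResult(0.0, None, None, None, 1.0, len(x), "wilcoxon_signed_rank")
        nz = d[d != 0]
        method = "exact" if (len(nz) <= 25 and len(np.unique(np.abs(nz))) == len(nz)) else "approx"
        res = sst.wilcoxon(x, y, zero_method="wilcox", correction=(method == "approx"),
                           method=method)
        return ModelResult(float(res.statistic), None, None, None,
                           float(res.pvalue), len(x), "wilcoxon_signed_rank")
    if design == "independent":
        method = "exact" if (len(x) <= 25 and len(y) <= 25
                             and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)) \
            else "asymptotic"
        res = sst.mannwhitneyu(x, y, method=method, use_continuity=True)
        return ModelResult(float(res.statistic), None, None, None,
                           float(res.pvalue), len(x) + len(y), "rank_sum")
    raise ValidationError(f"unknown design {design!r}")


# ---------------------------------------------------------------------------
# mixed-model association

def mixed_association(
    cohort: pd.DataFrame,
    outcome: tuple[str, str] = ("hrqol_pre", "hrqol_post"),
    predictor: str = "delta_lvet",
    scale: float = -10.0,
    model_form: str = "mixed",
    alpha: float = 0.05,
) -> ModelResult:
    """Association of a per-patient change variable with a repeated outcome.

    Fits a Gaussian linear mixed model on the stacked (pre, post) outcome with
    a random intercept per patient and fixed effects timepoint +
    timepoint x predictor. The reported estimate is the interaction
    coefficient multiplied by ``scale`` (default -10: index points per 10-unit
    *decrease* of the predictor). ``model_form='delta'`` fits the simpler OLS
    of (post - pre) on the predictor instead.
    """
    pre_col, post_col = outcome
    df = cohort[[pre_col, post_col, predictor]].copy()
    df = df[np.isfinite(df[predictor])]
    n_pat = int(((df[pre_col].notna()) | (df[post_col].notna())).sum())
    if n_pat < 20:
        raise InsufficientDataError(f"need >= 20 patients with an outcome, got {n_pat}")

    if model_form == "delta":
        sub = df.dropna()
        slope, intercept, _, p, se = sst.linregress(sub[predictor], sub[post_col] - sub[pre_col])
        est, se_s = slope * scale, abs(scale) * se
        z = sst.t.ppf(1 - alpha / 2, len(sub) - 2)
        return ModelResult(est, se_s, est - z * se_s, est + z * se_s, float(p),
                           len(sub), "ols_delta")
    if model_form != "mixed":
        raise ValidationError(f"unknown model_form {model_form!r}")

    import statsmodels.api as sm

    long = pd.DataFrame(
        {
            "y": np.concatenate([df[pre_col].to_numpy(float), df[post_col].to_numpy(float)]),
            "time": np.concatenate([np.zeros(len(df)), np.ones(len(df))]),
            "x": np.concatenate([df[predictor].to_numpy(float)] * 2),
            "patient": np.concatenate([np.arange(len(df))] * 2),
        }
    ).dropna(subset=["y"])
    exog = sm.add_constant(
        pd.DataFrame({"time": long["time"], "time_x": long["time"] * long["x"]})
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(long["y"], exog, groups=long["patient"])
        fit = None
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                fit = model.fit(method=method, reml=True)
            except Exception:
                continue
            if fit is not None and np.all(np.isfinite(fit.bse.iloc[:3])):
                break
        if fit is None:
            raise ConvergenceError("mixed model failed to converge with all optimizers")
    coef = float(fit.params["time_x"])
    se = float(fit.bse["time_x"])
    z = sst.norm.ppf(1 - alpha / 2)
    est, se_s = coef * scale, abs(scale) * se
    lo, hi = est - z * se_s, est + z * se_s
    return ModelResult(est, se_s, min(lo, hi), max(lo, hi),
                       float(fit.pvalues["time_x"]), n_pat, "mixed_random_intercept")


# ---------------------------------------------------------------------------
# missing data

def _em_mvnorm(y: np.ndarray, max_iter: int = 100, tol: float = 1e-6):
    """ML mean/covariance of a multivariate normal with missing entries (EM).

    The E-step is vectorised over missingness patterns, so cost scales with
    the number of distinct patterns rather than rows.
    """
    n, p = y.shape
    miss = np.isnan(y)
    mu = np.nanmean(y, axis=0)
    filled = np.where(miss, mu, y)
    sigma = np.cov(filled, rowvar=False, bias=True) + 1e-8 * np.eye(p)
    patterns: dict = {}
    for i in range(n):
        patterns.setdefault(tuple(miss[i]), []).append(i)
    pattern_rows = [(np.asarray(k, bool), np.asarray(v)) for k, v in patterns.items()]
    for _ in range(max_iter):
        ey = np.where(miss, 0.0, y)
        cc = np.zeros((p, p))
        for pat, rows in pattern_rows:
            if not pat.any():
                continue
            obs = ~pat
            soo = sigma[np.ix_(obs, obs)]
            smo = sigma[np.ix_(pat, obs)]
            resid = y[np.ix_(rows, obs)] - mu[obs]
            gain = np.linalg.solve(soo, smo.T).T          # (n_miss, n_obs)
            ey[np.ix_(rows, pat)] = mu[pat] + resid @ gain.T
            cond_cov = sigma[np.ix_(pat, pat)] - gain @ smo.T
            cc[np.ix_(pat, pat)] += len(rows) * cond_cov
        mu_new = ey.mean(axis=0)
        centered = ey - mu_new
        sigma_new = (centered.T @ centered + cc) / n + 1e-10 * np.eye(p)
        delta = max(np.abs(mu_new - mu).max(), np.abs(sigma_new - sigma).max())
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            break
    return mu, sigma


def little_mcar(data: pd.DataFrame) -> ModelResult:
    """Little's chi-square test of the missing-completely-at-random hypothesis.

    Groups rows by missingness pattern and sums the Mahalanobis distances of
    each pattern's observed-variable means from the EM (ML) grand means; the
    statistic is chi-square with df = sum of pattern variable counts minus the
    number of variables. Complete data return statistic 0, df 0, p = 1.
    """
    y = data.to_numpy(float)
    n, p = y.shape
    if p < 2:
        raise ValidationError("need at least two variables")
    if np.isnan(y).all(axis=0).any():
        raise ValidationError("a variable is entirely missing")
    miss = np.isnan(y)
    if not miss.any():
        return ModelResult(0.0, None, None, None, 1.0, n, "little_mcar")
    mu, sigma = _em_mvnorm(y)
    patterns = {}
    for i in range(n):
        patterns.setdefault(tuple(miss[i]), []).append(i)
    d2, df = 0.0, 0
    for pat, rows in patterns.items():
        obs = ~np.asarray(pat)
        if not obs.any():
            continue
        sub = y[np.ix_(rows, obs)]
        ybar = sub.mean(axis=0)
        diff = ybar - mu[obs]
        soo = sigma[np.ix_(obs, obs)]
        d2 += len(rows) * float(diff @ np.linalg.solve(soo, diff))
        df += int(obs.sum())
    df -= p
    if df <= 0:
        return ModelResult(float(d2), None, None, None, 1.0, n, "little_mcar")
    pval = float(sst.chi2.sf(d2, df))
    res = ModelResult(float(d2), None, None, None, pval, n, "little_mcar")
    res.df = df
    return res


def mice_impute(
    data: pd.DataFrame,
    m: int = 5,
    iters: int = 10,
    seed: int = 0,
    k_pmm: int = 5,
) -> list[pd.DataFrame]:
    """Multivariate imputation by chained equations with predictive mean
    matching (k = 5 donors), via statsmodels. Returns ``m`` completed copies.

    Deterministic for a fixed seed. With no missing values the input is
    returned unchanged ``m`` times.
    """
    if not data.isna().to_numpy().any():
        return [data.copy() for _ in range(m)]
    frac = data.isna().mean()
    bad = frac[frac >= 0.5]
    if len(bad):
        raise ValidationError(f"missingness >= 50% for {list(bad.index)}")
    out = []
    const_cols = {}
    work = data.copy()
    for c in work.columns:
        vals = work[c].dropna().unique()
        if len(vals) == 1:
            warnings.warn(f"column {c} is constant; imputing by its observed value")
            const_cols[c] = vals[0]
            work = work.drop(columns=[c])
    from statsmodels.imputation.mice import MICEData

    state = np.random.get_state()
    try:
        np.random.seed(seed % (2**31))
        md = MICEData(work.reset_index(drop=True), perturbation_method="gaussian", k_pmm=k_pmm)
        for _ in range(m):
            md.update_all(iters)
            comp = md.data.copy()
            comp.index = data.index
            for c, v in const_cols.items():
                comp[c] = data[c].fillna(v)
            out.append(comp[data.columns])
    finally:
        np.random.set_state(state)
    return out


def rubin_pool(results: list[ModelResult], alpha: float = 0.05) -> ModelResult:
    """Pool repeated-imputation results by Rubin's rules.

    Pooled estimate = mean; total variance = within + (1 + 1/m) * between;
    inference on Barnard-Rubin adjusted t degrees of freedom.
    """
    if not results:
        raise ValidationError("nothing to pool")
    m = len(results)
    ests = np.asarray([r.estimate for r in results], float)
    ses = np.asarray([r.se for r in results], float)
    qbar = float(ests.mean())
    ubar = float(np.mean(ses**2))
    b = float(ests.var(ddof=1)) if m > 1 else 0.0
    if b <= 1e-12 * (abs(qbar) + 1.0) ** 2:   # numerically identical estimates
        b = 0.0
        qbar = float(ests[0])
    t_var = ubar + (1 + 1 / m) * b
    se = float(np.sqrt(t_var))
    if b == 0.0 or se == 0.0:
        r0 = results[0]
        return ModelResult(qbar, se, qbar - 1.96 * se, qbar + 1.96 * se,
                           r0.p_value, r0.n, "rubin_pooled")
    r = (1 + 1 / m) * b / ubar if ubar > 0 else np.inf
    df = (m - 1) * (1 + 1 / r) ** 2 if np.isfinite(r) and r > 0 else m - 1
    tcrit = sst.t.ppf(1 - alpha / 2, df)
    stat = qbar / se
    p = float(2 * sst.t.sf(abs(stat), df))
    return ModelResult(qbar, se, qbar - tcrit * se, qbar + tcrit * se,
                       p, results[0].n, "rubin_pooled")


# ---------------------------------------------------------------------------
# power

def regression_power(f2: float, u: int, alpha: float = 0.05, n: int = 100) -> float:
    """Power of the F test for u predictors in multiple regression at sample
    size n, by exact noncentral-F computation with lambda = f2 * n."""
    if not f2 > 0:
        raise ValidationError("f2 must be positive")
    if u < 1 or n <= u + 1:
        raise ValidationError("need u >= 1 and n > u + 1")
    v = n - u - 1
    crit = sst.f.isf(alpha, u, v)
    return float(sst.ncf.sf(crit, u, v, f2 * n))


def required_n(f2: float, u: int, alpha: float = 0.05, target_power: float = 0.80,
               n_max: int = 1_000_000) -> int:
    """Smallest n whose power reaches ``target_power``."""
    if not (0 < target_power < 1):
        raise ValidationError("target power must be in (0, 1)")
    n = u + 2
    while n <= n_max:
        if regression_power(f2, u, alpha, n) >= target_power:
            return n
        n += 1
    raise ValidationError(f"target power {target_power} infeasible below n = {n_max}")
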