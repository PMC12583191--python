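"""Sensitivity analyses: E-values, random-effects meta-analysis,
stabilized inverse-probability-of-selection weights, chained-equation
covariate imputation with Rubin pooling, and DEHP metabolite-subset
re-derivation.

These quantify how much the headline risk ratios depend on the pooled
common-effect assumption (meta-analysis with REML between-cohort
variance and the I-squared statistic), on complete-case selection
(stabilized IPW), on missing covariates (MICE + Rubin's rules), and on
unmeasured confounding (E-values: the minimum confounder-outcome and
confounder-exposure risk ratio able to explain an estimate away).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .registry import AnalyteRegistry
from .intake import aggregate_parent

Z95 = 1.959963984540054

__all__ = [
    "EvalueResult",
    "MetaResult",
    "evalue",
    "random_effects_meta",
    "stabilized_ipw",
    "mice_pool",
    "dehp_metabolite_restriction",
]


@dataclass(frozen=True)
class EvalueResult:
    rr_input: float
    evalue_point: float
    evalue_ci_bound: float | None = None  # for the CI limit closer to the null


def _evalue_formula(rr: float) -> float:
    # defined for rr >= 1; protective estimates are inverted first
    return rr + np.sqrt(rr * (rr - 1.0))


def evalue(
    rr: float, ci_low: float | None = None, ci_high: float | None = None
) -> EvalueResult:
    """E-value for unmeasured confounding on the risk-ratio scale.

    For an estimate rr >= 1, E = rr + sqrt(rr (rr - 1)); protective
    estimates apply the formula to 1/rr.  The CI-bound E-value uses the
    confidence limit nearer the null and equals 1 when the interval
    crosses 1.
    """
    if rr <= 0:
        raise ValueError("risk ratio must be positive")
    r = rr if rr >= 1 else 1.0 / rr
    point = float(_evalue_formula(r))
    bound = None
    if ci_low is not None and ci_high is not None:
        if ci_low <= 1.0 <= ci_high:
            bound = 1.0
        else:
            lim = ci_low if rr >= 1 else ci_high
            lim = lim if lim >= 1 else 1.0 / lim
            bound = float(_evalue_formula(lim))
    return EvalueResult(rr_input=rr, evalue_point=point, evalue_ci_bound=bound)


@dataclass
class MetaResult:
    pooled_rr: float
    ci_low: float
    ci_high: float
    tau2: float  # between-cohort variance, log scale
    i2: float  # percent, [0, 100]
    q_statistic: float
    per_cohort_rr: list[float]


def _reml_nll(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return 0.5 * (np.sum(np.log(v + tau2)) + np.log(np.sum(w))
                  + np.sum(w * (y - mu) ** 2))


def random_effects_meta(
    log_rr: np.ndarray, se: np.ndarray
) -> MetaResult:
    """Random-effects pooling of cohort-stratified estimates.

    Between-cohort variance tau^2 by restricted maximum likelihood;
    pooled estimate is the inverse-variance weighted mean with weights
    1/(se_i^2 + tau^2); I^2 from Cochran's Q.  A single cohort passes
    through unchanged.
    """
    y = np.asarray(log_rr, dtype=float)
    s = np.asarray(se, dtype=float)
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    v = s**2
    k = len(y)
    if k == 1:
        return MetaResult(
            pooled_rr=float(np.exp(y[0])),
            ci_low=float(np.exp(y[0] - Z95 * s[0])),
            ci_high=float(np.exp(y[0] + Z95 * s[0])),
            tau2=0.0, i2=0.0, q_statistic=0.0,
            per_cohort_rr=[float(np.exp(y[0]))],
        )
    w_fe = 1.0 / v
    mu_fe = np.sum(w_fe * y) / np.sum(w_fe)
    q = float(np.sum(w_fe * (y - mu_fe) ** 2))
    i2 = float(max(0.0, (q - (k - 1)) / q) * 100.0) if q > 0 else 0.0

    res = optimize.minimize_scalar(
        _reml_nll, args=(y, v), bounds=(0.0, 100.0 * max(v.max(), 1e-8)),
        method="bounded", options={"xatol": 1e-12},
    )
    tau2 = float(res.x) if res.x > 1e-10 else 0.0
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se_mu = float(np.sqrt(1.0 / np.sum(w)))
    return MetaResult(
        pooled_rr=float(np.exp(mu)),
        ci_low=float(np.exp(mu - Z95 * se_mu)),
        ci_high=float(np.exp(mu + Z95 * se_mu)),
        tau2=tau2, i2=i2, q_statistic=q,
        per_cohort_rr=[float(np.exp(b)) for b in y],
    )


def stabilized_ipw(
    covariates: pd.DataFrame,
    included: np.ndarray,
    truncate: tuple[float, float] | None = (1.0, 99.0),
) -> np.ndarray:
    """Stabilized inverse-probability-of-selection weights.

    Fits a logistic model of inclusion on the covariates over the
    inception sample; each included subject's weight is the marginal
    inclusion probability divided by the fitted conditional one.
    Weights are truncated at the given percentiles (pass None to skip);
    the mean stabilized weight is close to 1 by construction.  Returns
    weights for the included subjects, NaN for the excluded.
    """
    inc = np.asarray(included, dtype=float)
    from .gee import build_design
    X = build_design(covariates, list(covariates.columns), exposure_col=None)
    res = sm.GLM(inc, np.asarray(X, dtype=float),
                 family=sm.families.Binomial()).fit()
    p_cond = np.asarray(res.predict(np.asarray(X, dtype=float)))
    if np.any(p_cond[inc == 1] < 1e-8) or np.any(p_cond > 1 - 1e-10):
        raise ValueError("near-perfect predictors of inclusion: weights unstable")
    p_marg = inc.mean()
    w = np.where(inc == 1, p_marg / p_cond, np.nan)
    if truncate is not None:
        wi = w[inc == 1]
        lo, hi = np.percentile(wi, truncate)
        w = np.where(inc == 1, np.clip(w, lo, hi), np.nan)
    return w


def _impute_once(
    rows: pd.DataFrame, cols: list[str], rng: np.random.Generator,
    iterations: int,
) -> pd.DataFrame:
    """One chained-equations pass over the covariates in ``cols``."""
    from .gee import build_design
    out = rows.copy()
    miss = {c: out[c].isna().to_numpy() for c in cols if out[c].isna().any()}
    # initial fill: mean / modal category
    for c, m in miss.items():
        if out[c].dtype == object:
            out.loc[m, c] = out[c].mode().iloc[0]
        else:
            out.loc[m, c] = out[c].mean()
    for _ in range(iterations):
        for c, m in miss.items():
            others = [o for o in cols if o != c]
            X = build_design(out, others, exposure_col=None)
            Xn = np.asarray(X, dtype=float)
            if out[c].dtype == object:
                levels = sorted(out.loc[~m, c].unique())
                if len(levels) == 1:
                    out.loc[m, c] = levels[0]
                    continue
                # sequential binary logits give a categorical draw
                probs = np.zeros((m.sum(), len(levels)))
                for j, lev in enumerate(levels):
                    yb = (out.loc[~m, c] == lev).astype(float).to_numpy()
                    try:
                        fit = sm.GLM(yb, Xn[~m],
                                     family=sm.families.Binomial()).fit()
                        probs[:, j] = fit.predict(Xn[m])
                    except Exception:
                        probs[:, j] = yb.mean()
                probs = probs / probs.sum(axis=1, keepdims=True)
                draws = np.array(
                    [rng.choice(levels, p=p) for p in probs], dtype=object
                )
                out.loc[m, c] = draws
            else:
                yc = out.loc[~m, c].to_numpy(dtype=float)
                beta, *_ = np.linalg.lstsq(Xn[~m], yc, rcond=None)
                resid = yc - Xn[~m] @ beta
                sd = resid.std(ddof=Xn.shape[1]) if len(yc) > Xn.shape[1] else resid.std()
                out.loc[m, c] = Xn[m] @ beta + rng.normal(0, sd, int(m.sum()))
    return out


def mice_pool(
    rows: pd.DataFrame,
    covariate_cols: list[str],
    fit_fn: Callable[[pd.DataFrame], tuple[float, float]],
    m: int = 5,
    iterations: int = 20,
    seed: int | None = None,
) -> dict:
    """Chained-equation imputation of missing covariates + Rubin pooling.

    ``fit_fn`` maps a completed table to ``(log_rr, variance)``.  Each
    of the ``m`` imputed datasets is analysed and the estimates pooled
    by Rubin's rules on the log-RR scale.  With no missing data the
    result equals the complete-data fit exactly.
    """
    import warnings
    missing_any = rows[covariate_cols].isna().any().any()
    for c in covariate_cols:
        frac = rows[c].isna().mean()
        if frac >= 1.0:
            raise ValueError(f"{c}: entirely missing; cannot impute")
        if frac > 0.5:
            warnings.warn(f"{c}: {frac:.0%} missing; imputations may be unstable")
    if not missing_any:
        est, var = fit_fn(rows)
        se = float(np.sqrt(var))
        return {
            "log_rr": float(est), "rr": float(np.exp(est)),
            "se": se, "ci_low": float(np.exp(est - Z95 * se)),
            "ci_high": float(np.exp(est + Z95 * se)),
            "within_var": float(var), "between_var": 0.0, "m": 1,
        }
    rng_root = np.random.default_rng(seed)
    ests, vars_ = [], []
    for _ in range(m):
        rng = np.random.default_rng(rng_root.integers(2**31))
        completed = _impute_once(rows, covariate_cols, rng, iterations)
        e, v = fit_fn(completed)
        ests.append(e)
        vars_.append(v)
    ests = np.asarray(ests)
    vars_ = np.asarray(vars_)
    qbar = float(ests.mean())
    ubar = float(vars_.mean())
    b = float(ests.var(ddof=1))
    total = ubar + (1 + 1 / m) * b
    se = float(np.sqrt(total))
    return {
        "log_rr": qbar, "rr": float(np.exp(qbar)), "se": se,
        "ci_low": float(np.exp(qbar - Z95 * se)),
        "ci_high": float(np.exp(qbar + Z95 * se)),
        "within_var": ubar, "between_var": b, "m": m,
    }


def dehp_metabolite_restriction(
    concentrations: pd.DataFrame,
    registry: AnalyteRegistry,
    metabolite_subset: list[str],
    uv: float,
    weight_col: str = "weight",
    parent_code: str = "DEHP",
) -> pd.Series:
    """Re-derive a parent intake from a restricted metabolite set.

    ``concentrations`` is wide (one column per metabolite, one row per
    sample) with a body-weight column; returns the per-row intake using
    only ``metabolite_subset`` — e.g. dropping MEHP, or additionally
    MECPP, to match the metabolites measured in every cohort.
    """
    if not metabolite_subset:
        raise ValueError("restricted metabolite set is empty")
    return concentrations.apply(
        lambda r: aggregate_parent(
            parent_code,
            {mcode: r[mcode] for mcode in metabolite_subset},
            registry, uv=uv, w=r[weight_col],
        ),
        axis=1,
    )
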