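"""Single-compound inference: Poisson GEE risk ratios per exposure doubling.

The estimand is the marginal risk ratio of a binary allergy outcome per
twofold increase in exposure.  With the exposure entered on the log2
scale in a log-link Poisson model, the exposure coefficient's
exponential is exactly that risk ratio; generalized estimating
equations with an exchangeable working correlation account for repeated
outcome assessments within subject, and the robust sandwich covariance
keeps the standard errors valid even when the working correlation is
wrong.  Restricted cubic splines (three knots at the 10th/50th/90th
exposure percentiles) probe non-linearity via Wald tests on the
non-linear spline coefficients, and exposure-by-sex interactions supply
stratum-specific effect estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

Z95 = 1.959963984540054  # standard-normal 97.5th percentile

__all__ = [
    "EffectEstimate",
    "DoseResponseCurve",
    "build_design",
    "fit_gee_poisson",
    "rr_per_doubling",
    "rcs_basis",
    "fit_spline_dose_response",
    "sex_emm",
    "trimester_stratified_fit",
    "SeparationError",
]


class SeparationError(RuntimeError):
    """Raised when coefficients diverge, indicating complete separation."""


@dataclass
class EffectEstimate:
    """Risk ratio per exposure doubling with robust 95% CI."""

    compound: str
    outcome: str
    period: str
    rr: float
    ci_low: float
    ci_high: float
    robust_se: float  # log scale
    n_subjects: int
    n_rows: int
    n_cohorts: int = 1
    pvalue: float = float("nan")
    converged: bool = True

    @property
    def log_rr(self) -> float:
        return float(np.log(self.rr))

    def as_dict(self) -> dict:
        return {
            "compound": self.compound, "outcome": self.outcome,
            "period": self.period, "rr": self.rr, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "robust_se": self.robust_se,
            "n_subjects": self.n_subjects, "n_rows": self.n_rows,
            "n_cohorts": self.n_cohorts, "pvalue": self.pvalue,
        }


@dataclass
class DoseResponseCurve:
    """Predicted relative risk over an exposure grid at reference covariates."""

    exposure_grid: np.ndarray  # log2 scale
    relative_risk: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    reference_exposure: float
    p_nonlinearity: float
    knots: np.ndarray = field(default_factory=lambda: np.array([]))


def build_design(rows: pd.DataFrame, covariate_cols: list[str] | None,
                 exposure_col: str | None = "log2_value") -> pd.DataFrame:
    """Intercept + exposure + dummy-coded covariates, all float.

    Categorical covariates are coded against their first (sorted) level,
    the same reference convention used for dose-response predictions.
    """
    parts = [pd.Series(1.0, index=rows.index, name="const")]
    if exposure_col is not None:
        parts.append(rows[exposure_col].astype(float))
    for c in covariate_cols or []:
        col = rows[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.dropna().unique())
            for lev in levels[1:]:
                parts.append(pd.Series((col == lev).astype(float),
                                       index=rows.index, name=f"{c}[{lev}]"))
        else:
            parts.append(col.astype(float).rename(c))
    return pd.concat(parts, axis=1)


def _check_separation(params: np.ndarray, names) -> None:
    if np.any(np.abs(params) > 50):
        bad = [n for n, p in zip(names, params) if abs(p) > 50]
        raise SeparationError(
            f"diverging coefficients {bad}: likely complete separation"
        )


def _fit_gee(y, X, groups, maxiter: int = 200, ctol: float = 1e-8):
    model = sm.GEE(np.asarray(y, dtype=float), np.asarray(X, dtype=float),
                   groups=np.asarray(groups),
                   family=sm.families.Poisson(),
                   cov_struct=sm.cov_struct.Exchangeable())
    res = model.fit(maxiter=maxiter, ctol=ctol)
    _check_separation(res.params, list(X.columns))
    return res


def fit_gee_poisson(
    rows: pd.DataFrame,
    compound: str = "",
    outcome: str = "",
    period: str = "",
    exposure_col: str = "log2_value",
    outcome_col: str = "status",
    group_col: str = "subject_id",
    covariate_cols: list[str] | None = None,
) -> EffectEstimate:
    """Marginal risk ratio per exposure doubling from a Poisson GEE.

    Exchangeable working correlation clustered on ``group_col``; robust
    sandwich standard errors; Wald 95% CI on the log scale.
    """
    if rows[group_col].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    X = build_design(rows, covariate_cols, exposure_col=exposure_col)
    res = _fit_gee(rows[outcome_col], X, rows[group_col])
    j = list(X.columns).index(exposure_col)
    beta = float(res.params[j])
    se = float(res.bse[j])
    return EffectEstimate(
        compound=compound, outcome=outcome, period=period,
        rr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
        robust_se=se,
        n_subjects=int(rows[group_col].nunique()),
        n_rows=int(len(rows)),
        n_cohorts=int(rows["cohort_id"].nunique()) if "cohort_id" in rows else 1,
        pvalue=float(2 * stats.norm.sf(abs(beta / se))) if se > 0 else float("nan"),
        converged=bool(getattr(res, "converged", True)),
    )


def rr_per_doubling(beta_log2: float) -> float:
    """Risk ratio per twofold exposure increase from the log2 coefficient."""
    if not np.isfinite(beta_log2):
        raise ValueError("coefficient must be finite")
    return float(np.exp(beta_log2))


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (linear beyond the boundary knots).

    Returns ``k - 1`` columns for ``k`` knots: the linear term plus
    ``k - 2`` non-linear terms, normalized by the squared knot span.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = len(t)
    if k < 3:
        raise ValueError("need at least 3 knots")
    if len(np.unique(t)) != k:
        raise ValueError("coincident knots: reduce the number of knots")
    span2 = (t[-1] - t[0]) ** 2

    def pos3(v):
        return np.clip(v, 0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (pos3(x - t[j])
                - pos3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
                + pos3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2]))
        cols.append(term / span2)
    return np.column_stack(cols)


def fit_spline_dose_response(
    rows: pd.DataFrame,
    exposure_col: str = "log2_value",
    outcome_col: str = "status",
    group_col: str = "subject_id",
    covariate_cols: list[str] | None = None,
    knot_quantiles: tuple[float, ...] = (0.10, 0.50, 0.90),
    n_grid: int = 50,
) -> DoseResponseCurve:
    """Spline dose-response inside the GEE, with a non-linearity Wald test.

    Knots sit at the stated exposure quantiles.  The curve is the
    predicted risk over an exposure grid with continuous covariates at
    their means and categoricals at the reference (first) level,
    expressed relative to the median exposure; the non-linearity p-value
    is a robust Wald test of the non-linear spline coefficients.
    """
    x = rows[exposure_col].to_numpy(dtype=float)
    knots = np.quantile(x, knot_quantiles)
    if len(np.unique(knots)) != len(knots):
        raise ValueError("coincident knots at the requested quantiles; "
                         "use fewer knots")
    S = rcs_basis(x, knots)
    spline_names = [f"rcs{j}" for j in range(S.shape[1])]
    Xc = build_design(rows, covariate_cols, exposure_col=None)
    X = pd.concat(
        [Xc, pd.DataFrame(S, columns=spline_names, index=rows.index)], axis=1
    )
    res = _fit_gee(rows[outcome_col], X, rows[group_col])

    names = list(X.columns)
    nl_ix = [names.index(n) for n in spline_names[1:]]
    b = np.asarray(res.params)[nl_ix]
    V = np.asarray(res.cov_params())[np.ix_(nl_ix, nl_ix)]
    wald = float(b @ np.linalg.solve(V, b))
    p_nl = float(stats.chi2.sf(wald, len(nl_ix)))

    grid = np.linspace(x.min(), x.max(), n_grid)
    ref = float(np.median(x))
    Sg = rcs_basis(grid, knots)
    Sr = rcs_basis(np.array([ref]), knots)
    # reference covariates: const 1, dummies 0, continuous at mean
    ref_row = np.zeros(Xc.shape[1])
    for i, nm in enumerate(Xc.columns):
        if nm == "const":
            ref_row[i] = 1.0
        elif "[" not in nm:
            ref_row[i] = float(Xc[nm].mean())
    Xg = np.column_stack([np.tile(ref_row, (n_grid, 1)), Sg])
    Xr = np.concatenate([ref_row, Sr[0]])
    d = Xg - Xr  # log RR contrast vs reference
    beta = np.asarray(res.params)
    log_rr = d @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", d, np.asarray(res.cov_params()), d))
    return DoseResponseCurve(
        exposure_grid=grid,
        relative_risk=np.exp(log_rr),
        ci_low=np.exp(log_rr - Z95 * se),
        ci_high=np.exp(log_rr + Z95 * se),
        reference_exposure=ref,
        p_nonlinearity=p_nl,
        knots=knots,
    )


def sex_emm(
    rows: pd.DataFrame,
    sex_col: str = "sex",
    exposure_col: str = "log2_value",
    outcome_col: str = "status",
    group_col: str = "subject_id",
    covariate_cols: list[str] | None = None,
    **labels,
) -> tuple[dict[str, EffectEstimate], float]:
    """Sex effect-measure modification via an exposure-by-sex interaction.

    Returns stratum-specific risk ratios (marginal contrasts from the
    interaction model) and the robust Wald p-value of the interaction
    coefficient.
    """
    sexes = sorted(rows[sex_col].dropna().unique())
    if len(sexes) < 2:
        raise ValueError("both sexes must be present for effect modification")
    covs = [c for c in (covariate_cols or []) if c != sex_col]
    X = build_design(rows, covs + [sex_col], exposure_col=exposure_col)
    ind = (rows[sex_col] == sexes[1]).astype(float)
    X["exp_x_sex"] = rows[exposure_col].astype(float) * ind
    res = _fit_gee(rows[outcome_col], X, rows[group_col])
    names = list(X.columns)
    V = np.asarray(res.cov_params())
    je, ji = names.index(exposure_col), names.index("exp_x_sex")
    beta = np.asarray(res.params)

    def stratum(contrast: np.ndarray, sex: str) -> EffectEstimate:
        b = float(contrast @ beta)
        se = float(np.sqrt(contrast @ V @ contrast))
        sub = rows[rows[sex_col] == sex]
        return EffectEstimate(
            compound=labels.get("compound", ""), outcome=labels.get("outcome", ""),
            period=labels.get("period", ""),
            rr=float(np.exp(b)), ci_low=float(np.exp(b - Z95 * se)),
            ci_high=float(np.exp(b + Z95 * se)), robust_se=se,
            n_subjects=int(sub[group_col].nunique()), n_rows=int(len(sub)),
            pvalue=float(2 * stats.norm.sf(abs(b / se))),
        )

    c0 = np.zeros(len(names)); c0[je] = 1.0
    c1 = np.zeros(len(names)); c1[je] = 1.0; c1[ji] = 1.0
    strata = {sexes[0]: stratum(c0, sexes[0]), sexes[1]: stratum(c1, sexes[1])}
    bi, sei = beta[ji], float(np.sqrt(V[ji, ji]))
    p_int = float(2 * stats.norm.sf(abs(bi / sei)))
    return strata, p_int


def trimester_stratified_fit(
    trimester_rows: dict[int, pd.DataFrame],
    **fit_kwargs,
) -> dict[int, EffectEstimate]:
    """One GEE fit per trimester table; empty trimesters are skipped."""
    out: dict[int, EffectEstimate] = {}
    for tri, rows in sorted(trimester_rows.items()):
        if rows is None or len(rows) == 0:
            continue
        est = fit_gee_poisson(rows, **fit_kwargs)
        est.period = f"trimester_{tri}"
        out[tri] = est
    return out
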