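"""Urinary concentration pre-processing.

Spot-urine biomarker concentrations are noisy measures of exposure:
they depend on hydration (urine dilution), assay batch, and the time of
day the sample was collected.  This module implements the
standardization chain applied before any intake derivation or
modelling:

1. below-LOD handling on the raw assay scale — either LOD/sqrt(2)
   substitution (phthalates) or multiple imputation from a
   left-censored lognormal fit (bisphenols, whose detection rates are
   lower);
2. dilution correction — Levine-Fahey for specific gravity
   (``E0 * (Sg_median - 1) / (Sg0 - 1)``) or Boeniger for creatinine
   (``E0 * Cr_median / Cr0``);
3. residual-method time-of-day adjustment on the log scale;
4. batch adjustment on the log scale (per-batch mean equalization).

Each stage is separately skippable because cohorts differ in which
corrections their assay protocol requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DilutionContext",
    "standardize_dilution",
    "handle_lod",
    "fit_censored_lognormal",
    "residual_time_adjust",
    "batch_adjust",
    "impute_missing_dilution",
]


@dataclass(frozen=True)
class DilutionContext:
    """Study-sample dilution reference values.

    ``sg_median``/``cr_median`` are the medians of the dilution variable
    over the study sample being standardized; the method picks which one
    the correction uses.
    """

    method: str  # "specific_gravity" | "creatinine"
    sg_median: float | None = None  # unitless, > 1
    cr_median: float | None = None  # mg/dL, > 0

    def __post_init__(self) -> None:
        if self.method not in ("specific_gravity", "creatinine"):
            raise ValueError("method must be 'specific_gravity' or 'creatinine'")
        if self.method == "specific_gravity":
            if self.sg_median is None or self.sg_median <= 1:
                raise ValueError("sg_median must be > 1 for specific gravity")
        else:
            if self.cr_median is None or self.cr_median <= 0:
                raise ValueError("cr_median must be > 0 for creatinine")

    @classmethod
    def from_samples(cls, samples: pd.DataFrame, method: str) -> "DilutionContext":
        if method == "specific_gravity":
            return cls(method=method, sg_median=float(samples["specific_gravity"].median()))
        return cls(method=method, cr_median=float(samples["creatinine"].median()))


def standardize_dilution(
    concentration: float | np.ndarray,
    dilution_value: float | np.ndarray,
    ctx: DilutionContext,
) -> float | np.ndarray:
    """Correct an observed concentration for urine dilution.

    ``dilution_value`` is the sample's own specific gravity (Sg0) or
    creatinine (Cr0), per ``ctx.method``.
    """
    conc = np.asarray(concentration, dtype=float)
    dil = np.asarray(dilution_value, dtype=float)
    if ctx.method == "specific_gravity":
        if np.any(dil <= 1):
            raise ValueError(
                "degenerate dilution: specific gravity must exceed 1 "
                f"(got min {dil.min():.4f})"
            )
        out = conc * (ctx.sg_median - 1.0) / (dil - 1.0)
    else:
        if np.any(dil <= 0):
            raise ValueError(
                f"degenerate dilution: creatinine must be positive (got min {dil.min():.4f})"
            )
        out = conc * ctx.cr_median / dil
    if np.isscalar(concentration) or np.ndim(concentration) == 0:
        return float(out)
    return out


def fit_censored_lognormal(
    detected: np.ndarray, lod: np.ndarray, n_censored_per_lod: np.ndarray
) -> tuple[float, float]:
    """Maximum-likelihood lognormal fit treating non-detects as left-censored.

    ``detected`` are the observed concentrations; censored observations
    contribute ``Phi((log LOD - mu)/sigma)`` to the likelihood, one term
    per censored sample at its own LOD.  Returns ``(mu, sigma)`` on the
    natural-log scale.
    """
    logs = np.log(np.asarray(detected, dtype=float))
    log_lod = np.log(np.asarray(lod, dtype=float))
    n_cens = np.asarray(n_censored_per_lod, dtype=float)
    if logs.size == 0:
        raise ValueError(
            "all observations censored: censored lognormal fit is not "
            "identified; exclude this analyte"
        )

    def nll(theta: np.ndarray) -> float:
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        ll = stats.norm.logpdf(logs, mu, sigma).sum()
        if n_cens.size:
            ll += float(np.sum(n_cens * stats.norm.logcdf((log_lod - mu) / sigma)))
        return -ll

    x0 = np.array([logs.mean(), np.log(max(logs.std(ddof=0), 1e-3))])
    res = optimize.minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    mu, sigma = float(res.x[0]), float(np.exp(res.x[1]))
    return mu, sigma


def _draw_left_truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, upper: np.ndarray
) -> np.ndarray:
    """Draw from lognormal(mu, sigma) truncated to (0, upper), elementwise."""
    p_upper = stats.norm.cdf((np.log(upper) - mu) / sigma)
    u = rng.uniform(0.0, p_upper)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def handle_lod(
    samples: pd.DataFrame,
    method: str = "sqrt2",
    m_imputations: int = 5,
    seed: int | None = None,
) -> list[pd.DataFrame]:
    """Replace below-LOD values; returns one table (sqrt2) or m tables (MI).

    ``samples`` needs columns ``analyte, concentration, censored, lod``.
    Detected values are never altered.  The MI route fits a left-censored
    lognormal per analyte by maximum likelihood, then draws each censored
    value from the fitted distribution truncated to (0, LOD),
    independently per imputation.
    """
    if method not in ("sqrt2", "censored_lognormal_mi"):
        raise ValueError(f"unknown LOD method {method!r}")
    cens = samples["censored"].to_numpy(dtype=bool)
    if method == "sqrt2":
        out = samples.copy()
        out.loc[cens, "concentration"] = out.loc[cens, "lod"] / np.sqrt(2.0)
        out.loc[cens, "censored"] = False
        return [out]

    if not cens.any():
        return [samples.copy() for _ in range(m_imputations)]

    rng_root = np.random.default_rng(seed)
    # per-analyte censored-MLE fit, shared across imputations
    fits: dict[str, tuple[float, float]] = {}
    for analyte, grp in samples.groupby("analyte"):
        gcens = grp["censored"].to_numpy(dtype=bool)
        if not gcens.any():
            continue
        if gcens.all():
            raise ValueError(
                f"{analyte}: every observation is below the LOD; "
                "cannot fit the censored lognormal — exclude this analyte"
            )
        det = grp.loc[~grp["censored"], "concentration"].to_numpy(dtype=float)
        lods = grp.loc[grp["censored"], "lod"].to_numpy(dtype=float)
        fits[analyte] = fit_censored_lognormal(det, lods, np.ones_like(lods))

    tables = []
    for i in range(m_imputations):
        rng = np.random.default_rng(rng_root.integers(2**31))
        out = samples.copy()
        for analyte, (mu, sigma) in fits.items():
            mask = (out["analyte"] == analyte) & cens
            lods = out.loc[mask, "lod"].to_numpy(dtype=float)
            out.loc[mask, "concentration"] = _draw_left_truncated_lognormal(
                rng, mu, sigma, lods
            )
        out.loc[cens, "censored"] = False
        out["imputation"] = i
        tables.append(out)
    return tables


def residual_time_adjust(
    log_values: np.ndarray,
    clock_time: np.ndarray,
    degree: int = 2,
) -> np.ndarray:
    """Residual-method adjustment for time of day at sampling.

    Regresses log concentration on polynomial terms of clock hour
    (default linear + quadratic) and returns residual + grand mean, so
    the adjusted values are uncorrelated with the time terms while the
    overall mean is preserved.
    """
    y = np.asarray(log_values, dtype=float)
    t = np.asarray(clock_time, dtype=float)
    if y.shape != t.shape:
        raise ValueError("log_values and clock_time must align")
    if np.ptp(t) == 0:
        warnings.warn("constant clock time: time-of-day adjustment is a no-op")
        return y.copy()
    X = np.column_stack([t**k for k in range(degree + 1)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return resid + y.mean()


def batch_adjust(
    log_values: np.ndarray, batch: Sequence, min_batch_size: int = 2
) -> np.ndarray:
    """Equalize per-batch means on the log scale.

    Each batch's mean is shifted to the grand mean; singleton batches
    (fewer than ``min_batch_size`` samples) are left unadjusted with a
    warning, since their batch mean is not separable from the sample.
    """
    y = np.asarray(log_values, dtype=float)
    b = pd.Series(batch)
    out = y.copy()
    grand = y.mean()
    for label, idx in b.groupby(b).groups.items():
        pos = np.asarray(idx)
        if pos.size < min_batch_size:
            warnings.warn(f"batch {label!r} has {pos.size} sample(s); left unadjusted")
            continue
        out[pos] = y[pos] - y[pos].mean() + grand
    return out


def impute_missing_dilution(
    dilution: np.ndarray,
    predictors: pd.DataFrame,
    kind: str = "specific_gravity",
    min_complete: int = 30,
    sg_floor: float = 1.001,
) -> np.ndarray:
    """Fill missing dilution measurements by linear regression.

    ``predictors`` holds the regression covariates (e.g. gestational age
    at sampling, maternal age, pre-pregnancy weight), row-aligned with
    ``dilution``.  Observed values are untouched.  Specific-gravity
    predictions are floored just above 1 so the Levine-Fahey denominator
    stays positive.
    """
    y = np.asarray(dilution, dtype=float)
    X = predictors.to_numpy(dtype=float)
    miss = np.isnan(y)
    if not miss.any():
        return y.copy()
    complete = ~miss & ~np.isnan(X).any(axis=1)
    if complete.sum() < min_complete:
        raise ValueError(
            f"only {int(complete.sum())} complete rows; need at least "
            f"{min_complete} to fit the dilution-imputation regression"
        )
    X1 = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X1[complete], y[complete], rcond=None)
    out = y.copy()
    pred = X1[miss] @ beta
    if kind == "specific_gravity":
        pred = np.maximum(pred, sg_floor)
    out[miss] = pred
    return out
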