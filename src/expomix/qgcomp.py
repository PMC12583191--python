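"""Quantile g-computation for the chemical mixture.

Each exposure is replaced by its empirical quantile score (0..q-1); a
log-link Poisson risk model with all quantized exposures plus
covariates is fitted, and the mixture effect psi is the sum of the
exposure coefficients — the log risk ratio of raising every exposure by
one quantile simultaneously.  Signed per-compound weights decompose psi
within the positive and negative coefficient sets.  Confidence
intervals come from a subject-level (cluster) bootstrap, which also
respects the repeated outcome measures; with 20 quantiles and
polynomial or spline terms the same machinery yields mixture
dose-response curves, the specification chosen by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .gee import build_design, rcs_basis

__all__ = [
    "MixtureResult",
    "MixtureCurve",
    "quantize_exposures",
    "fit_qgcomp",
    "fit_qgcomp_nonlinear",
    "qgcomp_sex_emm",
]


@dataclass
class MixtureResult:
    """psi and its decomposition for a one-quantile joint increase."""

    psi: float  # log RR per one-quantile joint increase
    psi_rr: float
    ci_low: float
    ci_high: float
    weights_positive: dict[str, float]
    weights_negative: dict[str, float]
    betas: dict[str, float]
    q: int
    n_boot: int
    n_dropped: int = 0
    n_subjects: int = 0
    n_rows: int = 0


@dataclass
class MixtureCurve:
    """Mixture dose-response over joint quantiles, AIC-selected spec."""

    quantiles: np.ndarray
    relative_risk: np.ndarray
    selected_spec: str
    aic_table: dict[str, float] = field(default_factory=dict)


def quantize_exposures(exposures: pd.DataFrame, q: int) -> pd.DataFrame:
    """Per-compound empirical quantile scores 0..q-1.

    Average-rank ties are mapped through floor(rank * q / (n + 1)), so
    tied values land deterministically in one bin and the scores are
    invariant to strictly monotone transforms of each compound.
    """
    if q < 2:
        raise ValueError("q must be at least 2")
    if exposures.isna().any().any():
        raise ValueError("missing exposures: drop incomplete rows before quantizing")
    n = len(exposures)
    out = {}
    for c in exposures.columns:
        if exposures[c].nunique() < q:
            raise ValueError(f"{c}: fewer distinct values than q={q}")
        r = stats.rankdata(exposures[c], method="average")
        out[c] = np.clip(np.floor(r * q / (n + 1)), 0, q - 1).astype(int)
    return pd.DataFrame(out, index=exposures.index)


def _weights(betas: dict[str, float]) -> tuple[dict[str, float], dict[str, float]]:
    pos = {k: v for k, v in betas.items() if v > 0}
    neg = {k: v for k, v in betas.items() if v < 0}
    spos = sum(pos.values())
    sneg = sum(neg.values())
    wpos = {k: v / spos for k, v in pos.items()} if spos else {}
    wneg = {k: v / sneg for k, v in neg.items()} if sneg else {}
    return wpos, wneg


def _fit_poisson(y: np.ndarray, X: np.ndarray,
                 start: np.ndarray | None = None,
                 tol: float = 1e-10, maxiter: int = 100) -> np.ndarray:
    """Poisson log-link fit by iteratively reweighted least squares.

    A minimal Newton solver kept local so the bootstrap stays cheap;
    matches the statsmodels GLM Poisson solution to solver tolerance.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    beta = np.zeros(p) if start is None else start.copy()
    if start is None:
        beta[0] = np.log(max(y.mean(), 1e-10))
    dev_old = np.inf
    for _ in range(maxiter):
        eta = X @ beta
        if np.any(eta > 30):
            raise RuntimeError("diverging linear predictor in Poisson fit")
        mu = np.exp(eta)
        W = mu  # Poisson working weights
        z = eta + (y - mu) / mu
        XtW = X.T * W
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            raise RuntimeError("singular information matrix in Poisson fit")
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = 2 * np.sum(
                np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
                - (y - mu)
            )
        if np.max(np.abs(beta_new - beta)) < tol or abs(dev_old - dev) < tol:
            beta = beta_new
            break
        beta, dev_old = beta_new, dev
    if not np.all(np.isfinite(beta)) or np.any(np.abs(beta) > 50):
        raise RuntimeError("underlying Poisson fit did not converge")
    return beta


def fit_qgcomp(
    rows: pd.DataFrame,
    compound_cols: list[str],
    outcome_col: str = "status",
    group_col: str = "subject_id",
    covariate_cols: list[str] | None = None,
    q: int = 4,
    n_boot: int = 1000,
    seed: int | None = None,
    prequantized: bool = False,
) -> MixtureResult:
    """Mixture risk ratio per one-quantile joint increase.

    Fits the underlying log-link Poisson risk model on the quantized
    exposures plus covariates; psi is the sum of the compound
    coefficients.  The 95% CI is the percentile interval over
    ``n_boot`` subject-level bootstrap resamples (quantization is redone
    inside each resample).  Replicates that fail to converge are
    dropped; more than 10% dropped is an error.
    """
    rows = rows.dropna(subset=compound_cols).reset_index(drop=True)
    Xc = np.asarray(build_design(rows, covariate_cols, exposure_col=None),
                    dtype=float)
    E = rows[compound_cols].to_numpy(dtype=float)
    y = rows[outcome_col].to_numpy(dtype=float)
    k = len(compound_cols)

    def _quantize_mat(vals: np.ndarray) -> np.ndarray:
        n = vals.shape[0]
        out = np.empty_like(vals)
        for j in range(vals.shape[1]):
            if len(np.unique(vals[:, j])) < q:
                raise ValueError(
                    f"{compound_cols[j]}: fewer distinct values than q={q}"
                )
            r = stats.rankdata(vals[:, j], method="average")
            out[:, j] = np.clip(np.floor(r * q / (n + 1)), 0, q - 1)
        return out

    _start = {"params": None}

    def psi_and_betas(ix: np.ndarray | None) -> np.ndarray:
        if ix is None:
            Ei, Xi, yi = E, Xc, y
        else:
            Ei, Xi, yi = E[ix], Xc[ix], y[ix]
        S = Ei if prequantized else _quantize_mat(Ei)
        params = _fit_poisson(yi, np.column_stack([Xi, S]),
                              start=_start["params"])
        if ix is None:
            _start["params"] = params
        return params[-k:]

    b_full = psi_and_betas(None)
    betas = dict(zip(compound_cols, map(float, b_full)))
    psi = sum(betas.values())
    wpos, wneg = _weights(betas)

    rng = np.random.default_rng(seed)
    subj_codes, _ = pd.factorize(rows[group_col])
    n_subj = subj_codes.max() + 1
    subj_rows = [np.flatnonzero(subj_codes == s) for s in range(n_subj)]
    psis = []
    dropped = 0
    for _ in range(n_boot):
        pick = rng.integers(0, n_subj, size=n_subj)
        ix = np.concatenate([subj_rows[s] for s in pick])
        try:
            psis.append(float(psi_and_betas(ix).sum()))
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            dropped += 1
    if n_boot and dropped > 0.10 * n_boot:
        raise RuntimeError(
            f"{dropped}/{n_boot} bootstrap replicates failed to converge"
        )
    if psis:
        lo, hi = np.percentile(psis, [2.5, 97.5])
    else:
        lo = hi = psi
    return MixtureResult(
        psi=float(psi), psi_rr=float(np.exp(psi)),
        ci_low=float(np.exp(lo)), ci_high=float(np.exp(hi)),
        weights_positive=wpos, weights_negative=wneg, betas=betas,
        q=q, n_boot=n_boot, n_dropped=dropped,
        n_subjects=int(rows[group_col].nunique()), n_rows=int(len(rows)),
    )


def _make_spec_basis(scores: pd.DataFrame, spec: str):
    """Basis transform for the quantile scores, with knots frozen on the
    observed scores so predictions at counterfactual joint quantiles use
    the same basis functions as the fit."""
    knots = {}
    if spec == "rcs":
        for c in scores.columns:
            k = np.quantile(scores[c].to_numpy(dtype=float),
                            [0.10, 0.50, 0.90])
            if len(np.unique(k)) == 3:
                knots[c] = k
        if not knots:
            raise ValueError("rcs basis infeasible: coincident knots")

    def transform(frame: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for c in scores.columns:
            s = frame[c].to_numpy(dtype=float)
            cols[c] = s
            if spec in ("quadratic", "cubic"):
                cols[f"{c}^2"] = s**2
                if spec == "cubic":
                    cols[f"{c}^3"] = s**3
            elif spec == "rcs" and c in knots:
                cols[f"{c}_rcs1"] = rcs_basis(s, knots[c])[:, 1]
        return pd.DataFrame(cols, index=frame.index)

    return transform


def fit_qgcomp_nonlinear(
    rows: pd.DataFrame,
    compound_cols: list[str],
    outcome_col: str = "status",
    covariate_cols: list[str] | None = None,
    q: int = 20,
    candidate_specs: tuple[str, ...] = ("linear", "quadratic", "cubic", "rcs"),
) -> MixtureCurve:
    """Mixture dose-response curve with AIC model selection.

    Each candidate adds polynomial (or restricted-cubic-spline) terms of
    every quantized exposure to the underlying Poisson model; the
    minimum-AIC candidate is selected.  The curve is the g-computation
    prediction: mean predicted risk with all compounds set to joint
    quantile s (covariates at their observed values), relative to s=0.
    """
    rows = rows.dropna(subset=compound_cols).reset_index(drop=True)
    scores = quantize_exposures(rows[compound_cols], q)
    Xc = build_design(rows, covariate_cols, exposure_col=None)
    y = rows[outcome_col].to_numpy(dtype=float)

    aic: dict[str, float] = {}
    fits: dict[str, tuple] = {}
    for spec in candidate_specs:
        try:
            transform = _make_spec_basis(scores, spec)
            X = pd.concat([Xc, transform(scores)], axis=1)
            res = sm.GLM(y, np.asarray(X, dtype=float),
                         family=sm.families.Poisson()).fit()
            aic[spec] = float(res.aic)
            fits[spec] = (res, transform)
        except (ValueError, np.linalg.LinAlgError):
            continue
    if not fits:
        raise RuntimeError("no candidate specification could be fitted")
    selected = min(aic, key=aic.get)
    res, transform = fits[selected]

    grid = np.arange(q)
    preds = np.empty(q)
    for s in grid:
        joint = pd.DataFrame(
            {c: np.full(len(rows), s, dtype=float) for c in compound_cols},
            index=rows.index,
        )
        X = pd.concat([Xc, transform(joint)], axis=1)
        preds[s] = float(np.mean(res.predict(np.asarray(X, dtype=float))))
    return MixtureCurve(
        quantiles=grid,
        relative_risk=preds / preds[0],
        selected_spec=selected,
        aic_table=aic,
    )


def qgcomp_sex_emm(
    rows: pd.DataFrame,
    compound_cols: list[str],
    sex_col: str = "sex",
    outcome_col: str = "status",
    group_col: str = "subject_id",
    covariate_cols: list[str] | None = None,
    q: int = 4,
    n_boot: int = 200,
    seed: int | None = None,
) -> tuple[dict[str, MixtureResult], float]:
    """Per-sex mixture effects and a bootstrap interaction p-value.

    The underlying model interacts every quantized exposure with sex,
    so each sex has its own psi; the interaction p-value comes from the
    bootstrap distribution of the psi difference.
    """
    sexes = sorted(rows[sex_col].dropna().unique())
    if len(sexes) < 2:
        raise ValueError("both sexes must be present")
    rows = rows.dropna(subset=compound_cols + [sex_col]).reset_index(drop=True)
    covs = [c for c in (covariate_cols or []) if c != sex_col]
    Xc = np.asarray(build_design(rows, covs + [sex_col], exposure_col=None),
                    dtype=float)
    E = rows[compound_cols].to_numpy(dtype=float)
    y = rows[outcome_col].to_numpy(dtype=float)
    ind = (rows[sex_col] == sexes[1]).to_numpy(dtype=float)
    k = len(compound_cols)

    def _quantize_mat(vals: np.ndarray) -> np.ndarray:
        n = vals.shape[0]
        out = np.empty_like(vals)
        for j in range(vals.shape[1]):
            r = stats.rankdata(vals[:, j], method="average")
            out[:, j] = np.clip(np.floor(r * q / (n + 1)), 0, q - 1)
        return out

    _start = {"params": None}

    def psis(ix: np.ndarray | None) -> tuple[float, float, np.ndarray, np.ndarray]:
        if ix is None:
            Ei, Xi, yi, di = E, Xc, y, ind
        else:
            Ei, Xi, yi, di = E[ix], Xc[ix], y[ix], ind[ix]
        S = _quantize_mat(Ei)
        X = np.column_stack([Xi, S, S * di[:, None]])
        params = _fit_poisson(yi, X, start=_start["params"])
        if ix is None:
            _start["params"] = params
        b0 = params[-2 * k:-k]
        b1 = b0 + params[-k:]
        return float(b0.sum()), float(b1.sum()), b0, b1

    psi0, psi1, b0v, b1v = psis(None)
    b0 = dict(zip(compound_cols, map(float, b0v)))
    b1 = dict(zip(compound_cols, map(float, b1v)))
    rng = np.random.default_rng(seed)
    subj_codes, _ = pd.factorize(rows[group_col])
    n_subj = subj_codes.max() + 1
    subj_rows = [np.flatnonzero(subj_codes == s) for s in range(n_subj)]
    d0, d1 = [], []
    dropped = 0
    for _ in range(n_boot):
        pick = rng.integers(0, n_subj, size=n_subj)
        ix = np.concatenate([subj_rows[s] for s in pick])
        try:
            p0, p1, *_ = psis(ix)
            d0.append(p0)
            d1.append(p1)
        except (RuntimeError, ValueError, np.linalg.LinAlgError):
            dropped += 1
    diffs = np.array(d1) - np.array(d0)
    if len(diffs):
        frac = float(np.mean(diffs > 0))
        p_int = float(2 * min(frac, 1 - frac))
        ci0 = np.percentile(d0, [2.5, 97.5])
        ci1 = np.percentile(d1, [2.5, 97.5])
    else:
        p_int = float("nan")
        ci0 = ci1 = (psi0, psi1)

    def pack(psi, b, ci) -> MixtureResult:
        wpos, wneg = _weights(b)
        return MixtureResult(
            psi=float(psi), psi_rr=float(np.exp(psi)),
            ci_low=float(np.exp(ci[0])), ci_high=float(np.exp(ci[1])),
            weights_positive=wpos, weights_negative=wneg, betas=b,
            q=q, n_boot=n_boot, n_dropped=dropped,
            n_subjects=int(rows[group_col].nunique()), n_rows=int(len(rows)),
        )

    return {sexes[0]: pack(psi0, b0, ci0), sexes[1]: pack(psi1, b1, ci1)}, p_int
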