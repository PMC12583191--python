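"""End-to-end convenience workflows.

These compose the generator, alignment and model modules into the two
study designs the analysis uses — prenatal (averaged exposure, repeated
outcomes) and postnatal lagged (repeated exposures, windowed outcomes) —
plus the simulation-recovery harness used to validate the estimators
against known truths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import build_postnatal_lagged_table, build_prenatal_table
from .gee import EffectEstimate, fit_gee_poisson
from .intake import period_average
from .qgcomp import MixtureResult, fit_qgcomp
from .simulate import CohortSpec, SimulatedStudy, simulate_study

DEFAULT_COVARIATES = ["sex", "maternal_age"]

__all__ = [
    "exposure_records",
    "analysis_table",
    "fit_single_from_study",
    "RecoveryResult",
    "single_compound_recovery",
    "mixture_table",
    "mixture_recovery",
]


def exposure_records(study: SimulatedStudy, scale: str = "edi") -> pd.DataFrame:
    """Cast simulated urine samples into exposure-record form.

    The synthetic concentrations play the role of the derived exposure
    (EDI or biomarker): the intake conversion is a subject-constant
    positive multiple, so the log2-scale effect estimates are identical
    either way.  Censored samples are excluded.
    """
    s = study.urine_samples
    out = s.loc[~s["censored"], ["subject_id", "cohort_id", "analyte",
                                 "sampling_time", "concentration"]].copy()
    out = out.rename(columns={"analyte": "parent_code",
                              "sampling_time": "timing",
                              "concentration": "value"})
    out["scale"] = scale
    return out


def analysis_table(
    study: SimulatedStudy,
    compound: str,
    outcome: str,
    covariate_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Prenatal or postnatal-lagged analysis rows for one compound-outcome."""
    covs = DEFAULT_COVARIATES if covariate_cols is None else covariate_cols
    period = study.truth.period
    exp = period_average(exposure_records(study), period)
    if period == "prenatal":
        return build_prenatal_table(exp, study.outcomes, study.covariates,
                                    compound, outcome, covariate_cols=covs)
    covs = covs + ["age_at_assessment"] if "age_at_assessment" not in covs else covs
    return build_postnatal_lagged_table(exp, study.outcomes, study.covariates,
                                        compound, outcome, covariate_cols=covs)


def fit_single_from_study(
    study: SimulatedStudy,
    compound: str,
    outcome: str,
    covariate_cols: list[str] | None = None,
) -> EffectEstimate:
    covs = DEFAULT_COVARIATES if covariate_cols is None else covariate_cols
    period = study.truth.period
    rows = analysis_table(study, compound, outcome, covariate_cols=covs)
    model_covs = covs if period == "prenatal" else covs + ["age_at_assessment"]
    model_covs = list(dict.fromkeys(model_covs))
    est = fit_gee_poisson(rows, compound=compound, outcome=outcome,
                          period=period, covariate_cols=model_covs)
    return est


@dataclass
class RecoveryResult:
    """Simulation-recovery summary: does the pipeline find the truth?"""

    true_rr: float
    estimates: list[float]
    coverage: float  # fraction of replicates whose 95% CI covers truth
    mean_rr: float

    @property
    def n_replicates(self) -> int:
        return len(self.estimates)


def single_compound_recovery(
    spec: CohortSpec,
    compound: str,
    outcome: str,
    n_replicates: int,
    seed: int,
    covariate_cols: list[str] | None = None,
) -> RecoveryResult:
    """Repeatedly simulate and refit; report estimates and CI coverage."""
    true_rr = float(np.exp(spec.true_log2_rr[(compound, outcome)]))
    rng = np.random.default_rng(seed)
    ests, hits = [], 0
    for _ in range(n_replicates):
        study = simulate_study(spec, seed=int(rng.integers(2**31)))
        est = fit_single_from_study(study, compound, outcome,
                                    covariate_cols=covariate_cols)
        ests.append(est.rr)
        hits += est.ci_low <= true_rr <= est.ci_high
    return RecoveryResult(
        true_rr=true_rr, estimates=ests,
        coverage=hits / n_replicates,
        mean_rr=float(np.exp(np.mean(np.log(ests)))),
    )


def mixture_table(
    study: SimulatedStudy,
    compounds: list[str],
    outcome: str,
    covariate_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Wide analysis table with one log2-exposure column per compound."""
    covs = DEFAULT_COVARIATES if covariate_cols is None else covariate_cols
    tabs = []
    for c in compounds:
        t = analysis_table(study, c, outcome, covariate_cols=covs)
        key = (["subject_id", "window_id"] if "window_id" in t.columns
               else ["subject_id", "age_at_assessment"])
        tabs.append(t.rename(columns={"log2_value": c}).set_index(key))
    keep = [c for c in tabs[0].columns if c not in compounds]
    wide = pd.concat([tabs[0][keep]] + [t[[c]] for t, c in zip(tabs, compounds)],
                     axis=1)
    return wide.dropna(subset=compounds).reset_index()


def mixture_recovery(
    spec: CohortSpec,
    compounds: list[str],
    outcome: str,
    n_replicates: int,
    seed: int,
    q: int = 4,
    n_boot: int = 200,
    covariate_cols: list[str] | None = None,
) -> RecoveryResult:
    """Simulation-recovery harness for the quantile g-computation psi."""
    true_rr = float(np.exp(spec.mixture_psi[outcome]))
    covs = DEFAULT_COVARIATES if covariate_cols is None else covariate_cols
    model_covs = covs + (["age_at_assessment"]
                         if spec.period == "postnatal" else [])
    rng = np.random.default_rng(seed)
    ests, hits = [], 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(2**31))
        study = simulate_study(spec, seed=rep_seed)
        wide = mixture_table(study, compounds, outcome, covariate_cols=covs)
        res: MixtureResult = fit_qgcomp(
            wide, compounds, covariate_cols=model_covs,
            q=q, n_boot=n_boot, seed=rep_seed,
        )
        ests.append(res.psi_rr)
        hits += res.ci_low <= true_rr <= res.ci_high
    return RecoveryResult(
        true_rr=true_rr, estimates=ests,
        coverage=hits / n_replicates,
        mean_rr=float(np.exp(np.mean(np.log(ests)))),
    )
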