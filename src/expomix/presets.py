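"""Calibrated cohort specifications.

The generator defaults here encode the pooled study's published
marginals: geometric means and geometric standard deviations of the
exposure distributions (estimated daily intakes in ug/kg/day, MCPP as
ug/L), overall outcome prevalences over the first five years, covariate
frequencies, and sample sizes.  Effect sizes for recovery studies are
supplied per call as the truth being tested.

Prenatal sampling uses two pregnancy timepoints (gestational weeks 16
and 26); postnatal sampling uses child ages 1, 2 and 3 years with one
outcome assessment inside each lagged window, so the windowed analysis
row reproduces the per-assessment risk model exactly.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .simulate import CohortSpec

# exposure distributions: GM (GSD); intakes ug/kg/day, MCPP ug/L
PRENATAL_EXPOSURES: dict[str, tuple[float, float]] = {
    "DMP": (0.05, 4.40), "DEP": (1.52, 5.82), "DBP": (0.90, 3.62),
    "BBzP": (0.20, 4.53), "DEHP": (3.85, 3.78), "MCPP": (1.40, 3.92),
    "BPA": (0.02, 5.07), "BPS": (0.005, 6.65), "BPF": (0.003, 15.97),
}
POSTNATAL_EXPOSURES: dict[str, tuple[float, float]] = {
    "DEP": (1.23, 2.77), "DBP": (2.28, 1.96), "BBzP": (0.41, 3.00),
    "DEHP": (6.62, 2.55), "MCPP": (1.31, 2.72), "BPA": (0.17, 2.13),
}

# overall outcome prevalences, birth to five years
PRENATAL_PREVALENCE = {"asthma": 0.146, "wheeze": 0.380,
                       "eczema": 0.387, "rhinitis": 0.350}
POSTNATAL_PREVALENCE = {"asthma": 0.130, "wheeze": 0.598,
                        "eczema": 0.651, "rhinitis": 0.210}

# compounds entering the mixture analyses (insufficient measurement
# coverage excludes DMP/BPS/BPF prenatally and BPA postnatally)
PRENATAL_MIXTURE = ["DEP", "DBP", "BBzP", "DEHP", "MCPP", "BPA"]
POSTNATAL_MIXTURE = ["DEP", "DBP", "BBzP", "DEHP", "MCPP"]

DEFAULT_COVARIATE_DISTRIBUTIONS = {
    "sex": {"type": "categorical", "levels": ["male", "female"],
            "probs": [0.509, 0.491]},
    "maternal_age": {"type": "normal", "mean": 30.4, "sd": 5.6},
}

__all__ = [
    "PRENATAL_EXPOSURES", "POSTNATAL_EXPOSURES",
    "PRENATAL_PREVALENCE", "POSTNATAL_PREVALENCE",
    "PRENATAL_MIXTURE", "POSTNATAL_MIXTURE",
    "prenatal_spec", "postnatal_spec",
]


def prenatal_spec(
    n_subjects: int = 2900,
    analytes: list[str] | None = None,
    outcomes: list[str] | None = None,
    true_rr: Mapping[tuple[str, str], float] | None = None,
    mixture_rr: Mapping[str, float] | None = None,
    seed: int = 0,
) -> CohortSpec:
    """Pregnancy-exposure cohort at the pooled study's marginals.

    ``true_rr`` maps (compound, outcome) to the risk ratio per exposure
    doubling used as simulation truth; ``mixture_rr`` maps an outcome to
    the risk ratio of a joint one-quartile mixture increase.
    """
    analytes = analytes or list(PRENATAL_EXPOSURES)
    outcomes = outcomes or list(PRENATAL_PREVALENCE)
    return CohortSpec(
        cohort_id="SYN-PRE",
        n_subjects=n_subjects,
        period="prenatal",
        analytes=analytes,
        exposure_gm={a: PRENATAL_EXPOSURES[a][0] for a in analytes},
        exposure_gsd={a: PRENATAL_EXPOSURES[a][1] for a in analytes},
        sampling_times=[16.0, 26.0],
        outcome_baseline_risk={o: PRENATAL_PREVALENCE[o] for o in outcomes},
        outcome_assessment_ages={o: [2.0, 4.0] for o in outcomes},
        true_log2_rr={k: float(np.log(v)) for k, v in (true_rr or {}).items()},
        mixture_psi={k: float(np.log(v)) for k, v in (mixture_rr or {}).items()},
        covariate_distributions=DEFAULT_COVARIATE_DISTRIBUTIONS,
        seed=seed,
    )


def postnatal_spec(
    n_subjects: int = 1700,
    analytes: list[str] | None = None,
    outcomes: list[str] | None = None,
    true_rr: Mapping[tuple[str, str], float] | None = None,
    mixture_rr: Mapping[str, float] | None = None,
    seed: int = 0,
) -> CohortSpec:
    """Childhood-exposure cohort with the lagged repeated-measures design."""
    analytes = analytes or list(POSTNATAL_EXPOSURES)
    outcomes = outcomes or list(POSTNATAL_PREVALENCE)
    return CohortSpec(
        cohort_id="SYN-POST",
        n_subjects=n_subjects,
        period="postnatal",
        analytes=analytes,
        exposure_gm={a: POSTNATAL_EXPOSURES[a][0] for a in analytes},
        exposure_gsd={a: POSTNATAL_EXPOSURES[a][1] for a in analytes},
        sampling_times=[1.0, 2.0, 3.0],
        outcome_baseline_risk={o: POSTNATAL_PREVALENCE[o] for o in outcomes},
        outcome_assessment_ages={o: [1.5, 2.5, 3.5] for o in outcomes},
        true_log2_rr={k: float(np.log(v)) for k, v in (true_rr or {}).items()},
        mixture_psi={k: float(np.log(v)) for k, v in (mixture_rr or {}).items()},
        covariate_distributions=DEFAULT_COVARIATE_DISTRIBUTIONS,
        seed=seed,
    )
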