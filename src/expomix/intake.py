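"""Estimated daily intake (EDI) derivation and exposure aggregation.

A standardized urinary metabolite concentration C_adj (ug/L) is
back-calculated to a parent-compound daily intake (ug/kg/day) under a
steady-state excretion model::

    EDI = (C_adj * UV * MW_parent) / (FUE * W * MW_metabolite)

where UV is the average daily urine volume (1.6 L during pregnancy),
W the body weight at sampling (kg), FUE the molar fractional urinary
excretion, and the molecular-weight ratio converts the metabolite mass
to parent-compound mass.  DEHP intake uses the molar sum of its
oxidative metabolites; DBP is the sum of the DiBP and DnBP intakes;
MCPP stays on the concentration scale.  The module also carries the
helpers needed to evaluate the formula: gestational weight-at-sampling
from the Institute of Medicine weight-gain guideline, and the
age-indexed child urine-volume-per-weight table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .registry import AnalyteDefinition, AnalyteRegistry

PREGNANCY_UV_L_PER_DAY = 1.6

__all__ = [
    "EDIInputs",
    "compute_edi",
    "aggregate_parent",
    "estimate_weight_at_sampling",
    "child_uv_per_weight",
    "period_average",
    "trimester_average",
    "TRIMESTER_BOUNDARIES",
    "IOM_TOTAL_GAIN_KG",
    "CHILD_UV_PER_WEIGHT",
]


@dataclass(frozen=True)
class EDIInputs:
    """Inputs to the intake formula for a single sample."""

    c_adj: float  # ug/L, standardized metabolite concentration
    w: float  # kg
    analyte: AnalyteDefinition
    uv: float = PREGNANCY_UV_L_PER_DAY  # L/day; pregnancy default

    def __post_init__(self) -> None:
        if self.c_adj <= 0 or self.uv <= 0 or self.w <= 0:
            raise ValueError("c_adj, uv and w must all be strictly positive")


def compute_edi(inputs: EDIInputs) -> float:
    """Parent-compound estimated daily intake, ug/kg body weight/day."""
    a = inputs.analyte
    if not a.is_edi_eligible:
        raise ValueError(
            f"{a.metabolite_code} is analysed as a urinary concentration; "
            "it is not eligible for intake derivation"
        )
    return (inputs.c_adj * inputs.uv * a.mw_parent) / (
        a.fue * inputs.w * a.mw_metabolite
    )


def aggregate_parent(
    parent_code: str,
    concentrations: Mapping[str, float],
    registry: AnalyteRegistry,
    uv: float,
    w: float,
) -> float:
    """Parent-level daily intake from one or more metabolite concentrations.

    Multi-metabolite parents (DEHP) use the molar sum of the available
    metabolites converted through the parent molecular weight and the
    combined FUE of exactly that subset::

        EDI = (sum_i C_i / MW_i) * MW_parent * UV / (FUE_subset * W)

    A single metabolite reduces to :func:`compute_edi`.  DBP is handled
    at a higher level as the arithmetic sum of the DiBP and DnBP
    intakes (see :func:`dbp_intake`).
    """
    if not concentrations:
        raise ValueError(f"no metabolite concentrations supplied for {parent_code}")
    defs = {code: registry.lookup(code) for code in concentrations}
    for code, d in defs.items():
        if d.parent_code != parent_code:
            raise ValueError(f"{code} is not a metabolite of {parent_code}")
        if not d.is_edi_eligible:
            raise ValueError(f"{code} is not eligible for intake derivation")
    mw_parent = next(iter(defs.values())).mw_parent
    molar_sum = sum(
        conc / defs[code].mw_metabolite for code, conc in concentrations.items()
    )
    fue = registry.combined_fue(parent_code, concentrations.keys())
    return molar_sum * mw_parent * uv / (fue * w)


def dbp_intake(dibp_edi: float, dnbp_edi: float) -> float:
    """Di-butyl phthalates intake: sum of the DiBP and DnBP intakes."""
    return dibp_edi + dnbp_edi


# Institute of Medicine gestational weight-gain guideline, encoded as the
# recommended total-gain range (kg) at term per pre-pregnancy BMI category
# plus a common first-trimester gain.  Weekly rates after week 13 are
# derived so that the cumulative gain at week 40 equals the range midpoint.
IOM_TOTAL_GAIN_KG: dict[str, tuple[float, float]] = {
    "underweight": (12.5, 18.0),  # BMI < 18.5
    "normal": (11.5, 16.0),  # 18.5 <= BMI < 25
    "overweight": (7.0, 11.5),  # 25 <= BMI < 30
    "obese": (5.0, 9.0),  # BMI >= 30
}
FIRST_TRIMESTER_GAIN_KG = 1.25  # midpoint of the 0.5-2.0 kg guideline range
_T1_END_WEEK = 13.0
_TERM_WEEK = 40.0


def bmi_category(bmi: float) -> str:
    if bmi <= 0:
        raise ValueError("BMI must be positive")
    if bmi < 18.5:
        return "underweight"
    if bmi < 25:
        return "normal"
    if bmi < 30:
        return "overweight"
    return "obese"


def estimate_weight_at_sampling(
    pre_pregnancy_weight: float, pre_pregnancy_bmi: float, gestational_week: float
) -> float:
    """Maternal weight at a gestational week under the IOM gain schedule.

    First-trimester gain accrues linearly to 1.25 kg by week 13; gain
    thereafter accrues at the BMI-category weekly rate that reaches the
    category's total-gain midpoint at week 40.  Monotone non-decreasing
    in gestational week.
    """
    if not (0 <= gestational_week <= 42):
        raise ValueError("gestational week must lie in [0, 42]")
    cat = bmi_category(pre_pregnancy_bmi)
    lo, hi = IOM_TOTAL_GAIN_KG[cat]
    total_mid = (lo + hi) / 2.0
    rate = (total_mid - FIRST_TRIMESTER_GAIN_KG) / (_TERM_WEEK - _T1_END_WEEK)
    if gestational_week <= _T1_END_WEEK:
        gain = FIRST_TRIMESTER_GAIN_KG * gestational_week / _T1_END_WEEK
    else:
        gain = FIRST_TRIMESTER_GAIN_KG + rate * (gestational_week - _T1_END_WEEK)
    return pre_pregnancy_weight + gain


# Normative daily urine output per kg body weight by child age band,
# L/day/kg; piecewise constant over [lower, upper) age in years.
CHILD_UV_PER_WEIGHT: list[tuple[float, float, float]] = [
    (0.0, 1.0, 0.047),
    (1.0, 2.0, 0.040),
    (2.0, 3.0, 0.035),
    (3.0, 4.0, 0.032),
    (4.0, 6.0, 0.030),
]


def child_uv_per_weight(
    age_years: float,
    table: list[tuple[float, float, float]] | None = None,
) -> float:
    """Age-indexed urine volume per body weight, L/day/kg."""
    tab = table if table is not None else CHILD_UV_PER_WEIGHT
    if age_years <= 0:
        raise ValueError("age must be positive")
    for lo, hi, value in tab:
        if lo <= age_years < hi:
            return value
    raise ValueError(f"age {age_years} outside the supported range")


def period_average(records: pd.DataFrame, period: str) -> pd.DataFrame:
    """Reduce repeated exposure records to the analysis exposure.

    Prenatal: average on the natural scale across a subject's samples,
    one row per (subject, compound), then log2.  Postnatal: repeated
    records are kept per timepoint (the lagged analysis consumes them).
    Expects columns ``subject_id, parent_code, timing, value, scale``.
    """
    if period == "postnatal":
        out = records.copy()
        out["log2_value"] = np.log2(out["value"])
        return out
    agg = (
        records.groupby(["subject_id", "parent_code", "scale"], as_index=False)
        .agg(value=("value", "mean"))
    )
    agg["period"] = "prenatal"
    agg["log2_value"] = np.log2(agg["value"])
    return agg


TRIMESTER_BOUNDARIES = (14.0, 28.0)  # T1 < 14, T2 14-27, T3 >= 28 weeks


def trimester_average(
    records: pd.DataFrame,
    boundaries: tuple[float, float] = TRIMESTER_BOUNDARIES,
) -> pd.DataFrame:
    """Average prenatal samples within trimester bins.

    ``records`` needs columns ``subject_id, parent_code, timing`` (in
    gestational weeks) and ``value``.  Subjects without samples in a
    trimester are simply absent from that trimester's rows.
    """
    t1_end, t2_end = boundaries
    weeks = records["timing"].to_numpy(dtype=float)
    trimester = np.where(weeks < t1_end, 1, np.where(weeks < t2_end, 2, 3))
    tmp = records.assign(trimester=trimester)
    agg = (
        tmp.groupby(["subject_id", "parent_code", "trimester"], as_index=False)
        .agg(value=("value", "mean"))
    )
    agg["log2_value"] = np.log2(agg["value"])
    return agg
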