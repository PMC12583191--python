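"""Outcome harmonization and analysis-table construction.

Cohorts report the four allergy outcomes (asthma, wheeze, eczema,
rhinitis) with different question codings; :func:`harmonize_outcomes`
maps them onto unified binary records.  Two analysis layouts follow:

* prenatal — one (averaged) exposure per subject-compound, repeated
  outcome assessments as rows, clustered by subject;
* postnatal lagged — each exposure timepoint t is paired with the
  outcome assessments in the half-open window (t, t'] up to the next
  exposure timepoint (the last window extends to age five), aggregated
  as any-positive, so exposure always precedes outcome.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

OUTCOMES = ("asthma", "wheeze", "eczema", "rhinitis")
MAX_FOLLOWUP_YEARS = 5.0

__all__ = ["OUTCOMES", "harmonize_outcomes", "build_prenatal_table",
           "build_postnatal_lagged_table"]


def harmonize_outcomes(
    cohort_tables: Mapping[str, pd.DataFrame],
    coding: Mapping[str, Mapping[str, int]],
) -> pd.DataFrame:
    """Map cohort-specific outcome codings onto unified binary records.

    ``cohort_tables`` maps cohort id to a table with columns
    ``subject_id, outcome, age_at_assessment, code``; ``coding`` maps
    cohort id to a {code: 0/1} dictionary (e.g. the clinical-assessment
    coding "definite" -> 1, "possible" -> 0, "no" -> 0).  Rows whose
    code is absent from the mapping raise, listing the offending codes.
    """
    out = []
    for cohort, tab in cohort_tables.items():
        cmap = coding[cohort]
        codes = tab["code"].astype(str)
        unknown = sorted(set(codes) - set(cmap))
        if unknown:
            raise ValueError(f"{cohort}: unmapped outcome codes {unknown}")
        t = tab.copy()
        t["status"] = codes.map(cmap).astype(int)
        t["cohort_id"] = cohort
        out.append(t.drop(columns=["code"]))
    res = pd.concat(out, ignore_index=True)
    bad_age = ~res["age_at_assessment"].between(0, MAX_FOLLOWUP_YEARS)
    if bad_age.any():
        raise ValueError("age_at_assessment outside [0, 5] years")
    return res


def build_prenatal_table(
    exposures: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
    compound: str,
    outcome: str,
    covariate_cols: list[str] | None = None,
    complete_case: bool = True,
) -> pd.DataFrame:
    """One row per (subject, outcome assessment) sharing the subject's exposure.

    ``exposures`` holds one averaged record per subject-compound
    (columns ``subject_id, parent_code, log2_value``).  Subjects missing
    the exposure or all outcome assessments contribute no rows; the main
    analysis is complete-case on covariates.
    """
    exp = exposures.loc[exposures["parent_code"] == compound,
                        ["subject_id", "log2_value"]]
    out = outcomes.loc[outcomes["outcome"] == outcome,
                       ["subject_id", "age_at_assessment", "status"]]
    rows = out.merge(exp, on="subject_id", how="inner")
    rows = rows.merge(covariates, on="subject_id", how="left")
    if complete_case and covariate_cols:
        rows = rows.dropna(subset=covariate_cols)
    return rows.reset_index(drop=True)


def build_postnatal_lagged_table(
    exposures: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
    compound: str,
    outcome: str,
    covariate_cols: list[str] | None = None,
    complete_case: bool = True,
    max_age: float = MAX_FOLLOWUP_YEARS,
) -> pd.DataFrame:
    """Lagged exposure-outcome pairing with any-positive window aggregation.

    ``exposures`` holds repeated records (columns ``subject_id,
    parent_code, timing, log2_value`` with ``timing`` in years).  For
    each subject and exposure timepoint t, outcome assessments with age
    in (t, t'] — t' the subject's next exposure timepoint, or ``max_age``
    after the last — collapse to a single binary row (case iff any
    assessment positive), whose age covariate is the midpoint of the
    aggregated assessment ages.  Windows without any assessment yield no
    row, so every row satisfies exposure time < outcome age.
    """
    exp = exposures.loc[exposures["parent_code"] == compound,
                        ["subject_id", "timing", "log2_value"]].copy()
    out = outcomes.loc[outcomes["outcome"] == outcome,
                       ["subject_id", "age_at_assessment", "status"]].copy()
    if exp.empty or out.empty:
        return pd.DataFrame()
    exp = exp.sort_values(["subject_id", "timing"], kind="stable")
    exp["window_end"] = (
        exp.groupby("subject_id")["timing"].shift(-1).fillna(max_age)
    )
    # assign each assessment to the most recent strictly-earlier exposure
    out = out[out["age_at_assessment"] <= max_age]
    merged = pd.merge_asof(
        out.sort_values("age_at_assessment", kind="stable"),
        exp.sort_values("timing", kind="stable"),
        by="subject_id",
        left_on="age_at_assessment",
        right_on="timing",
        direction="backward",
        allow_exact_matches=False,
    ).dropna(subset=["timing"])
    # the backward match already respects the (t, t'] upper bound because
    # a later exposure would have captured any older assessment
    tab = (
        merged.groupby(["subject_id", "timing"], as_index=False)
        .agg(
            log2_value=("log2_value", "first"),
            window_end=("window_end", "first"),
            status=("status", "max"),
            age_at_assessment=("age_at_assessment", "mean"),
        )
        .rename(columns={"timing": "exposure_timing"})
    )
    tab["window_id"] = [
        f"{t:g}-{e:g}" for t, e in zip(tab["exposure_timing"], tab["window_end"])
    ]
    tab = tab.drop(columns=["window_end"])
    if tab.empty:
        return tab
    tab = tab.merge(covariates, on="subject_id", how="left")
    if complete_case and covariate_cols:
        tab = tab.dropna(subset=covariate_cols)
    return tab.reset_index(drop=True)
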