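"""Chemical constants and cohort assay metadata.

Every downstream computation — dilution correction, estimated daily
intake (EDI), parent-compound aggregation — consumes the analyte
registry defined here.  The registry maps each urinary metabolite
(e.g. MnBP) to its parent diester (di-n-butyl phthalate, DnBP) and
carries the molecular weights and fractional urinary excretion (FUE)
needed for the intake back-calculation.

Molecular weights are computed from the molecular formulas; FUE values
are molar-basis defaults from the biomonitoring literature.  Both can
be overridden by supplying a custom constants table (TSV with columns
``metabolite_code, parent_code, mw_metabolite, mw_parent, fue,
is_edi_eligible, analyte_class``), so the constants in force are always
pinned and reportable.  MCPP is a non-specific metabolite of several
high-molecular-weight phthalates and is analysed as a urinary
concentration, never converted to an intake (``is_edi_eligible=False``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

CONSTANTS_VERSION = "2025.1"

__all__ = [
    "AnalyteDefinition",
    "CohortAssayProfile",
    "AnalyteRegistry",
    "UnknownAnalyteError",
    "load_default_registry",
    "apply_detection_filter",
    "apply_cohort_filter",
]


class UnknownAnalyteError(KeyError):
    """Raised when a metabolite code is not in the registry."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"unknown analyte code: {self.code!r}"


@dataclass(frozen=True)
class AnalyteDefinition:
    """One urinary metabolite and the constants tying it to its parent.

    ``fue`` is the molar fractional urinary excretion: the fraction of
    an absorbed parent-compound dose excreted in urine as this
    metabolite.  ``is_edi_eligible`` is False for analytes kept on the
    concentration scale (MCPP).
    """

    metabolite_code: str
    parent_code: str
    mw_metabolite: float  # g/mol
    mw_parent: float  # g/mol
    fue: float  # molar fraction in (0, 1]
    is_edi_eligible: bool = True
    analyte_class: str = "phthalate"  # phthalate | bisphenol

    def __post_init__(self) -> None:
        if self.mw_metabolite <= 0 or self.mw_parent <= 0:
            raise ValueError(
                f"{self.metabolite_code}: molecular weights must be positive"
            )
        if not (0 < self.fue <= 1):
            raise ValueError(f"{self.metabolite_code}: fue must lie in (0, 1]")
        if self.analyte_class not in ("phthalate", "bisphenol"):
            raise ValueError(f"{self.metabolite_code}: bad analyte_class")


@dataclass
class CohortAssayProfile:
    """Assay metadata for one cohort: LODs, dilution variable, adjustments."""

    cohort_id: str
    analytes_measured: set[str]
    lod_per_analyte: dict[str, float] = field(default_factory=dict)
    dilution_variable: str = "specific_gravity"  # or "creatinine"
    time_of_day_adjusted: bool = False
    batch_adjusted: bool = False

    def __post_init__(self) -> None:
        if self.dilution_variable not in ("specific_gravity", "creatinine"):
            raise ValueError(
                f"{self.cohort_id}: dilution_variable must be "
                "'specific_gravity' or 'creatinine'"
            )
        extra = set(self.lod_per_analyte) - set(self.analytes_measured)
        if extra:
            raise ValueError(
                f"{self.cohort_id}: LODs given for unmeasured analytes {sorted(extra)}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortAssayProfile":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            cohort_id=raw["cohort_id"],
            analytes_measured=set(raw["analytes_measured"]),
            lod_per_analyte=dict(raw.get("lod_per_analyte", {})),
            dilution_variable=raw.get("dilution_variable", "specific_gravity"),
            time_of_day_adjusted=bool(raw.get("time_of_day_adjusted", False)),
            batch_adjusted=bool(raw.get("batch_adjusted", False)),
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "cohort_id": self.cohort_id,
            "analytes_measured": sorted(self.analytes_measured),
            "lod_per_analyte": dict(self.lod_per_analyte),
            "dilution_variable": self.dilution_variable,
            "time_of_day_adjusted": self.time_of_day_adjusted,
            "batch_adjusted": self.batch_adjusted,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


class AnalyteRegistry:
    """Lookup table of :class:`AnalyteDefinition` keyed by metabolite code."""

    def __init__(
        self,
        definitions: Iterable[AnalyteDefinition],
        version: str = CONSTANTS_VERSION,
    ):
        self.version = version
        self._defs: dict[str, AnalyteDefinition] = {}
        for d in definitions:
            if d.metabolite_code in self._defs:
                raise ValueError(f"duplicate metabolite {d.metabolite_code}")
            self._defs[d.metabolite_code] = d
        # per-(parent, frozenset-of-metabolites) FUE overrides for subset
        # aggregation; empty unless the user supplies values
        self._subset_fue: dict[tuple[str, frozenset[str]], float] = {}

    def lookup(self, metabolite_code: str) -> AnalyteDefinition:
        try:
            return self._defs[metabolite_code]
        except KeyError:
            raise UnknownAnalyteError(metabolite_code) from None

    def metabolites(self) -> list[str]:
        return list(self._defs)

    def metabolites_of(self, parent_code: str) -> list[str]:
        """All registered metabolites whose parent is ``parent_code``."""
        return [
            c for c, d in self._defs.items() if d.parent_code == parent_code
        ]

    def set_subset_fue(
        self, parent_code: str, metabolites: Iterable[str], fue: float
    ) -> None:
        """Override the combined FUE used when only a metabolite subset of
        ``parent_code`` is available (e.g. DEHP without MEHP)."""
        if not (0 < fue <= 1):
            raise ValueError("fue must lie in (0, 1]")
        self._subset_fue[(parent_code, frozenset(metabolites))] = fue

    def combined_fue(self, parent_code: str, metabolites: Iterable[str]) -> float:
        """Combined molar FUE for a metabolite subset of one parent.

        Defaults to the sum of the per-metabolite FUEs (molar excretion
        fractions are additive across distinct metabolites); an explicit
        subset override takes precedence.
        """
        mets = frozenset(metabolites)
        if (parent_code, mets) in self._subset_fue:
            return self._subset_fue[(parent_code, mets)]
        total = 0.0
        for code in mets:
            d = self.lookup(code)
            if d.parent_code != parent_code:
                raise ValueError(f"{code} is not a metabolite of {parent_code}")
            total += d.fue
        if not (0 < total <= 1):
            raise ValueError(
                f"combined FUE {total:.3f} for {parent_code} outside (0, 1]"
            )
        return total

    @classmethod
    def from_tsv(cls, path: str | Path, version: str | None = None) -> "AnalyteRegistry":
        tab = pd.read_csv(path, sep="\t")
        defs = [
            AnalyteDefinition(
                metabolite_code=row.metabolite_code,
                parent_code=row.parent_code,
                mw_metabolite=float(row.mw_metabolite),
                mw_parent=float(row.mw_parent),
                fue=float(row.fue),
                is_edi_eligible=bool(int(row.is_edi_eligible)),
                analyte_class=row.analyte_class,
            )
            for row in tab.itertuples()
        ]
        return cls(defs, version=version or CONSTANTS_VERSION)


def load_default_registry() -> AnalyteRegistry:
    """The packaged constants table (version :data:`CONSTANTS_VERSION`)."""
    with resources.as_file(
        resources.files("expomix.data").joinpath("analytes.tsv")
    ) as p:
        return AnalyteRegistry.from_tsv(p)


def apply_detection_filter(
    detection_rates: Mapping[str, float],
    analyte_class: Mapping[str, str],
) -> set[str]:
    """Analyte inclusion by detection rate.

    Phthalates are retained when detected in strictly more than 50% of
    samples; bisphenols, with their lower assay sensitivity, when
    detected in strictly more than 10%.
    """
    retained: set[str] = set()
    for analyte, rate in detection_rates.items():
        if not (0 <= rate <= 1):
            raise ValueError(f"{analyte}: detection rate {rate} outside [0, 1]")
        cls = analyte_class[analyte]
        threshold = 0.50 if cls == "phthalate" else 0.10
        if rate > threshold:
            retained.add(analyte)
    return retained


def apply_cohort_filter(
    cohort_summaries: Mapping[str, tuple[int, float]],
) -> set[str]:
    """Cohort inclusion: n of at least 30 and at most 50% missing covariates."""
    retained: set[str] = set()
    for cohort, (n, missing_frac) in cohort_summaries.items():
        if n < 0 or not (0 <= missing_frac <= 1):
            raise ValueError(f"{cohort}: invalid summary ({n}, {missing_frac})")
        if n >= 30 and missing_frac <= 0.50:
            retained.add(cohort)
    return retained
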