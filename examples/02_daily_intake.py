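"""Estimated daily intakes from standardized metabolite concentrations.

Back-calculates parent-compound intakes (ug/kg/day) from urinary
metabolite levels: a single-metabolite parent (DnBP from MnBP), the
DEHP molar sum over its oxidative metabolites, and a pregnancy body
weight from the IOM weight-gain schedule.
"""

from expomix.intake import (
    EDIInputs, aggregate_parent, child_uv_per_weight, compute_edi,
    estimate_weight_at_sampling,
)
from expomix.registry import load_default_registry

registry = load_default_registry()

# maternal weight at 26 gestational weeks, normal pre-pregnancy BMI
w = estimate_weight_at_sampling(pre_pregnancy_weight=62.0,
                                pre_pregnancy_bmi=22.0,
                                gestational_week=26.0)
print(f"estimated weight at week 26: {w:.1f} kg (62 kg pre-pregnancy)")

mnbp = EDIInputs(c_adj=50.0, uv=1.6, w=w, analyte=registry.lookup("MnBP"))
print(f"DnBP intake from MnBP at 50 ug/L: {compute_edi(mnbp):.2f} ug/kg/day")

dehp = aggregate_parent(
    "DEHP",
    {"MEHP": 2.1, "MEHHP": 9.8, "MEOHP": 6.4, "MECPP": 14.9},  # ug/L
    registry, uv=1.6, w=w,
)
print(f"DEHP intake (molar sum of 4 metabolites): {dehp:.2f} ug/kg/day")

uvw = child_uv_per_weight(2.5)
print(f"child urine volume per weight at age 2.5: {uvw:.3f} L/day/kg — "
      "used in place of UV/W for postnatal intakes")
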