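"""Glucose unit conversions.

Conventions used throughout the package: glucose concentrations in mmol/L,
infusion rates in g/h (dextrose/carbohydrate) or IU/h (insulin), times in
minutes, first-order rate constants in 1/h.
"""

#: molar mass of D-glucose, g/mol
GLUCOSE_MOLAR_MASS = 180.16

#: mg/dL per mmol/L
MG_DL_PER_MMOL_L = 18.016


def mmol_l_to_mg_dl(value: float) -> float:
    """Convert a glucose concentration from mmol/L to mg/dL."""
    return value * MG_DL_PER_MMOL_L


def mg_dl_to_mmol_l(value: float) -> float:
    """Convert a glucose concentration from mg/dL to mmol/L."""
    return value / MG_DL_PER_MMOL_L


def glucose_g_to_mmol(grams: float) -> float:
    """Convert a glucose mass in grams to millimoles."""
    return grams * 1000.0 / GLUCOSE_MOLAR_MASS
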