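"""Unit conversions at the package boundary.

Internally everything is cm–g–min: lengths in cm, masses in g, volumes in
cm^3, times in min, concentrations in g cm^-3, permeabilities in cm min^-1.
User-facing configuration and the CLI speak the bench units (µL, µm, µg,
mg mL^-1, mL min^-1); these helpers convert exactly once, at the boundary.
"""

UL_TO_CM3 = 1e-3          # 1 µL = 1e-3 cm^3
UM_TO_CM = 1e-4           # 1 µm = 1e-4 cm
UG_TO_G = 1e-6            # 1 µg = 1e-6 g
MG_PER_ML_TO_G_PER_CM3 = 1e-3   # 1 mg/mL = 1e-3 g/cm^3
ML_PER_MIN_TO_CM3_PER_MIN = 1.0  # 1 mL = 1 cm^3


def uL_to_cm3(v: float) -> float:
    return v * UL_TO_CM3


def cm3_to_uL(v: float) -> float:
    return v / UL_TO_CM3


def um_to_cm(x: float) -> float:
    return x * UM_TO_CM


def cm_to_um(x: float) -> float:
    return x / UM_TO_CM


def ug_to_g(m: float) -> float:
    return m * UG_TO_G


def g_to_ug(m: float) -> float:
    return m / UG_TO_G


def mg_per_mL_to_g_per_cm3(c: float) -> float:
    return c * MG_PER_ML_TO_G_PER_CM3


def g_per_cm3_to_mg_per_mL(c: float) -> float:
    return c / MG_PER_ML_TO_G_PER_CM3
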