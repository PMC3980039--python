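"""Insulin sensitivity from the meal test: the OGIS index and its
urinary-glucose-excretion (UGE) correction.

OGIS estimates glucose clearance during a euglycaemic clamp from oral-test
glucose and insulin values via a closed-form physiological model. Under an
SGLT2 inhibitor part of glucose disposal is renal and insulin-independent,
so raw OGIS overestimates insulin-sensitivity improvements; subtracting the
renal glucose clearance (UGE / plasma glucose AUC, per body surface area)
yields the corrected index OGIS_c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import ogis_constants as oc
from .profiles import MealSpec, MmttProfile, trapezoid_auc

__all__ = [
    "SensitivityResult",
    "ogis_2h",
    "ogis_from_values",
    "renal_glucose_clearance",
    "ogis_corrected",
    "sensitivity_indices",
]

GLUCOSE_G_PER_MMOL = 0.18016  # molar mass 180.16 g/mol


@dataclass(frozen=True)
class SensitivityResult:
    ogis: float  # ml min^-1 m^-2
    renal_clearance: float  # ml min^-1 m^-2
    ogis_c: float  # ml min^-1 m^-2

    def __post_init__(self) -> None:
        if self.renal_clearance < 0:
            raise ValueError("renal clearance must be non-negative")
        if abs(self.ogis_c - (self.ogis - self.renal_clearance)) > 1e-9:
            raise ValueError("ogis_c must equal ogis - renal_clearance")


def ogis_from_values(
    g0: float, g90: float, g120: float, i0: float, i90: float,
    dose_g: float, bsa: float,
) -> float:
    """2-h OGIS from glucose (mmol/l) at 0/90/120 min, insulin (pmol/l) at
    0/90 min, the oral glucose dose (g) and body surface area (m^2).

    Evaluates the published closed form in its original units and returns
    ml min^-1 m^-2. Deterministic.
    """
    for name, val in (("g0", g0), ("g90", g90), ("g120", g120)):
        if not val > 0:
            raise ValueError(f"non-physiological glucose {name}={val!r}")
    if i0 < 0 or i90 < 0:
        raise ValueError("negative insulin")
    if not (dose_g > 0 and bsa > 0):
        raise ValueError("dose and BSA must be positive")

    G0, G90, G120 = (g * oc.MGDL_PER_MMOLL for g in (g0, g90, g120))
    I0, I90 = i0 / oc.PMOLL_PER_MUL, i90 / oc.PMOLL_PER_MUL
    D = dose_g / bsa  # g/m^2

    B = (
        oc.P4
        * ((oc.P1 * D - oc.V_GLUCOSE * (G120 - G90) / 30.0) / G90 + oc.P3 / G0)
        / (I90 - I0 + oc.P2)
    )
    disc = B * B + 4.0 * oc.P5 * oc.P6 * (G90 - oc.G_CLAMP) * B
    return 0.5 * (B + float(np.sqrt(max(disc, 0.0))))


def ogis_2h(profile: MmttProfile, meal: MealSpec = MealSpec(), bsa: float | None = None) -> float:
    """OGIS for one MMTT profile. Requires glucose at 0/90/120 min and
    insulin at 0/90 min; the t=0 values use the fasting convention (mean of
    the -15 and 0 min samples where both exist). The glucose dose is the
    meal's carbohydrate content."""
    if bsa is None:
        bsa = profile.bsa()
    try:
        g0 = profile.fasting_value("glucose")
        i0 = profile.fasting_value("insulin")
        g90 = profile.value_at("glucose", 90)
        g120 = profile.value_at("glucose", 120)
        i90 = profile.value_at("insulin", 90)
    except ValueError as err:
        raise ValueError(f"OGIS requires samples at 0/90/120 min: {err}") from err
    if any(np.isnan(v) for v in (g0, i0, g90, g120, i90)):
        raise ValueError("OGIS requires non-missing glucose/insulin at 0/90/120 min")
    return ogis_from_values(g0, g90, g120, i0, i90, meal.carbohydrate_g, bsa)


def renal_glucose_clearance(uge_g: float, glucose_auc: float, bsa: float) -> float:
    """Renal glucose clearance in ml min^-1 m^-2.

    UGE (grams over the test) is converted to mmol (molar mass 180.16 g/mol)
    and divided by the plasma glucose AUC (mmol.min/l) and body surface area.
    """
    if uge_g < 0:
        raise ValueError("UGE must be non-negative")
    if not glucose_auc > 0:
        raise ValueError("glucose AUC must be positive")
    if not bsa > 0:
        raise ValueError("BSA must be positive")
    uge_mmol = uge_g / GLUCOSE_G_PER_MMOL
    clearance_l_min = uge_mmol / glucose_auc
    return clearance_l_min * 1000.0 / bsa


def ogis_corrected(ogis: float, renal: float) -> float:
    """UGE-corrected OGIS: subtract renal glucose clearance."""
    if not (np.isfinite(ogis) and np.isfinite(renal)):
        raise ValueError("ogis and renal clearance must be finite")
    return ogis - renal


def sensitivity_indices(
    profile: MmttProfile, meal: MealSpec = MealSpec()
) -> SensitivityResult:
    """OGIS, renal glucose clearance and OGIS_c for one profile. A missing
    UGE measurement is treated as zero renal clearance."""
    bsa = profile.bsa()
    ogis = ogis_2h(profile, meal, bsa)
    uge = profile.uge_0_3h
    if uge is None or np.isnan(uge):
        renal = 0.0
    else:
        auc = trapezoid_auc(profile.times, profile.glucose)
        renal = renal_glucose_clearance(uge, auc, bsa)
    return SensitivityResult(ogis=ogis, renal_clearance=renal, ogis_c=ogis_corrected(ogis, renal))
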