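"""Hemodynamic derivations: cardiac output, BSA, PBV and PBVi.

Pulmonary blood volume follows from the indicator-dilution relation
``PBV = PTT * cardiac output`` and is indexed to body surface area,
``PBVi = PBV / BSA``.  Canonical internal units are seconds, ml, ml/s and
m^2; the :mod:`pulmotransit.units` layer rejects mismatched units (for
example a cardiac output in l/min passed where ml/s is required).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .units import Quantity, UnitError, expect


@dataclass(frozen=True)
class CardiacOutput:
    """Cardiac output stored canonically in ml/s with an l/min accessor."""

    ml_per_s: float

    @property
    def l_per_min(self) -> float:
        return self.ml_per_s * 60.0 / 1000.0

    def as_quantity(self, unit: str = "ml/s") -> Quantity:
        return Quantity(self.ml_per_s, "ml/s").to(unit)


def cardiac_output(stroke_volume: float, heart_rate: float) -> CardiacOutput:
    """CO = stroke volume (ml) x heart rate (beats/min).

    Returns a :class:`CardiacOutput` exposing both ml/s and l/min.
    """
    if stroke_volume <= 0:
        raise ValueError("stroke_volume must be positive (ml)")
    if heart_rate <= 0:
        raise ValueError("heart_rate must be positive (beats/min)")
    return CardiacOutput(ml_per_s=stroke_volume * heart_rate / 60.0)


def body_surface_area(height: float, weight: float, formula: str = "mosteller") -> float:
    """Body surface area in m^2 from height (cm) and weight (kg).

    ``mosteller``: sqrt(height*weight/3600).
    ``dubois``: 0.007184 * height^0.725 * weight^0.425.
    """
    if height <= 0 or weight <= 0:
        raise ValueError("height and weight must be positive")
    if formula == "mosteller":
        return math.sqrt(height * weight / 3600.0)
    if formula == "dubois":
        return 0.007184 * height**0.725 * weight**0.425
    raise ValueError(f"unknown BSA formula {formula!r}; use 'mosteller' or 'dubois'")


def pulmonary_blood_volume(ptt, co) -> float:
    """PBV (ml) = PTT (s) x cardiac output (ml/s).

    ``co`` may be a float (interpreted as ml/s), a :class:`CardiacOutput`,
    or a :class:`~pulmotransit.units.Quantity` in ml/s.  A Quantity in any
    other unit (e.g. l/min) raises :class:`~pulmotransit.units.UnitError`.
    """
    ptt_s = expect(ptt, "s", "ptt")
    if isinstance(co, CardiacOutput):
        co_ml_s = co.ml_per_s
    else:
        co_ml_s = expect(co, "ml/s", "cardiac output")
    if ptt_s <= 0 or co_ml_s <= 0:
        raise ValueError("ptt and cardiac output must be positive")
    return ptt_s * co_ml_s


def pbvi(pbv, bsa) -> float:
    """PBVi (ml/m^2) = PBV (ml) / BSA (m^2)."""
    pbv_ml = expect(pbv, "ml", "pbv")
    bsa_m2 = expect(bsa, "m^2", "bsa")
    if pbv_ml <= 0 or bsa_m2 <= 0:
        raise ValueError("pbv and bsa must be positive")
    return pbv_ml / bsa_m2


@dataclass
class HemodynamicRecord:
    """Per-subject hemodynamics: inputs and all derived quantities."""

    stroke_volume: float  # ml
    heart_rate: float     # beats/min
    height: float         # cm
    weight: float         # kg
    ptt: float            # s
    bsa_formula: str = "mosteller"
    cardiac_output_ml_s: float = field(init=False)
    cardiac_output_l_min: float = field(init=False)
    bsa: float = field(init=False)
    pbv: float = field(init=False)
    pbvi: float = field(init=False)

    def __post_init__(self) -> None:
        co = cardiac_output(self.stroke_volume, self.heart_rate)
        self.cardiac_output_ml_s = co.ml_per_s
        self.cardiac_output_l_min = co.l_per_min
        self.bsa = body_surface_area(self.height, self.weight, self.bsa_formula)
        self.pbv = pulmonary_blood_volume(self.ptt, co)
        self.pbvi = pbvi(self.pbv, self.bsa)

    def as_dict(self) -> dict:
        return {
            "stroke_volume_ml": self.stroke_volume,
            "heart_rate_bpm": self.heart_rate,
            "height_cm": self.height,
            "weight_kg": self.weight,
            "ptt_s": self.ptt,
            "bsa_formula": self.bsa_formula,
            "cardiac_output_ml_s": self.cardiac_output_ml_s,
            "cardiac_output_l_min": self.cardiac_output_l_min,
            "bsa_m2": self.bsa,
            "pbv_ml": self.pbv,
            "pbvi_ml_m2": self.pbvi,
        }


def derive_record(stroke_volume, heart_rate, height, weight, ptt,
                  bsa_formula: str = "mosteller") -> HemodynamicRecord:
    """Convenience constructor for :class:`HemodynamicRecord`."""
    return HemodynamicRecord(stroke_volume, heart_rate, height, weight, ptt,
                             bsa_formula=bsa_formula)


__all__ = [
    "CardiacOutput", "cardiac_output", "body_surface_area",
    "pulmonary_blood_volume", "pbvi", "HemodynamicRecord", "derive_record",
    "UnitError",
]
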