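"""Canonical unit system and conversions.

Internally the model works in picograms (mass), millimetres (length) and
minutes (time); concentrations are therefore pg/mm^3 and areal fluxes
pg/mm^2/min.  Interfaces accept and report the units customary for the
quantities involved (mg/dl for lipoprotein cholesterol, ug/ml for ApoA-I,
cm/s for permeability coefficients, um/year for deposit growth).
"""

from __future__ import annotations

SECONDS_PER_MIN = 60.0
MIN_PER_HOUR = 60.0
MIN_PER_DAY = 1440.0
DAYS_PER_YEAR = 365.0
MIN_PER_YEAR = 525_600.0  # 365 days
MIN_PER_MONTH = MIN_PER_YEAR / 12.0  # 43,800 min

MM_PER_CM = 10.0
UM_PER_MM = 1000.0
NM_PER_CM = 1.0e7

#: conversion factors from each supported concentration unit to pg/mm^3
_CONC_TO_PG_PER_MM3 = {
    "mg/dl": 1.0e4,
    "ug/ml": 1.0e3,
    "pg/cm^3": 1.0e-3,
    "pg/mm^3": 1.0,
    "g/cm^3": 1.0e9,
}

_UNIT_ALIASES = {
    "μg/ml": "ug/ml",  # μg/ml
    "µg/ml": "ug/ml",
    "pg/cm3": "pg/cm^3",
    "pg/mm3": "pg/mm^3",
    "g/cm3": "g/cm^3",
    "pg/cm³": "pg/cm^3",
    "pg/mm³": "pg/mm^3",
    "g/cm³": "g/cm^3",
}

#: pg/mm^2/min produced by 1 cm/s of permeability acting on 1 mg/dl:
#: 1 cm/s = 600 mm/min, 1 mg/dl = 1e4 pg/mm^3 -> 6e6.
PERMEABILITY_FLUX_COEFF = 6.0e6


class UnitError(ValueError):
    """Raised for unsupported or inconsistent unit strings."""


def _normalize(unit: str) -> str:
    unit = unit.strip()
    unit = _UNIT_ALIASES.get(unit, unit)
    if unit not in _CONC_TO_PG_PER_MM3:
        supported = ", ".join(sorted(_CONC_TO_PG_PER_MM3))
        raise UnitError(f"unsupported concentration unit {unit!r}; supported: {supported}")
    return unit


def convert_concentration(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a concentration between supported units.

    The conversion is an exact dimensional identity; round-trips return the
    input to machine precision.
    """
    f = _CONC_TO_PG_PER_MM3[_normalize(from_unit)]
    t = _CONC_TO_PG_PER_MM3[_normalize(to_unit)]
    return value * (f / t)


def cm_per_s_to_mm_per_min(p: float) -> float:
    """Convert a permeability coefficient from cm/s to mm/min."""
    return p * MM_PER_CM * SECONDS_PER_MIN


def permeability_flux(p_cm_per_s: float, c_mg_per_dl: float) -> float:
    """Areal flux (pg/mm^2/min) driven by a permeability P across a
    concentration difference C.

    Computes P*C with P in cm/s and C in mg/dl, i.e. the product of the
    permeability converted to mm/min and the concentration converted to
    pg/mm^3.  Bilinear in both arguments.
    """
    if p_cm_per_s < 0:
        raise ValueError(f"permeability must be >= 0, got {p_cm_per_s}")
    if c_mg_per_dl < 0:
        raise ValueError(f"concentration must be >= 0, got {c_mg_per_dl}")
    return PERMEABILITY_FLUX_COEFF * p_cm_per_s * c_mg_per_dl


def flux_coefficient(p_cm_per_s: float) -> float:
    """Flux per unit mg/dl concentration (pg/mm^2/min per mg/dl) for a
    permeability given in cm/s."""
    return PERMEABILITY_FLUX_COEFF * p_cm_per_s


def um_per_year_to_mm_per_min(rate: float) -> float:
    return rate / UM_PER_MM / MIN_PER_YEAR


def mm_per_min_to_um_per_year(rate: float) -> float:
    return rate * UM_PER_MM * MIN_PER_YEAR
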