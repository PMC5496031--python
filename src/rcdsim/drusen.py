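"""Basal cholesterol efflux from the RPE, drusen growth and macrophage
clearance in Bruch's membrane.

Two efflux routes leave the basal RPE: ABCA1-mediated transfer to lipid-poor
ApoA-I (small ~6.3 nm particles that escape through the choriocapillaris
fenestrae) and secretion of large ~70 nm ApoB-cholesterol particles that are
trapped in Bruch's membrane and accumulate as basal linear deposits and
drusen.  Trapped flux converts to deposit thickness through a calibrated
volumetric cholesterol density rho, so drusen height grows linearly in time.
Infiltrating macrophages clear deposit cholesterol by ABCA1 efflux with
Michaelis-Menten dependence on the local lipid-poor ApoA-I concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .units import (
    MIN_PER_YEAR,
    UM_PER_MM,
    flux_coefficient,
    mm_per_min_to_um_per_year,
)

#: deposit cholesterol density (pg/mm^3) from the growth calibration
#: 1 pg/mm^2/min of trapped flux <-> 0.7 um/year of thickness growth
DEFAULT_DEPOSIT_CH_DENSITY = 525_600.0 / 0.7e-3  # ~7.51e8 pg/mm^3


@dataclass
class EffluxParams:
    """Basal-efflux scalings and deposit properties."""

    kin_abca1: float = 6.73  # pg/mm^2/min, apical ABCA1 flux
    apical_basal_ratio: float = 6.37  # apical:basal ABCA1 expression
    hepatic_apob_flux: float = 967.0  # pg/mm^2/min, liver-equivalent secretion
    apob_expr_frac: float = 0.075  # RPE ApoB mRNA relative to liver
    mtp_expr_frac: float = 0.04  # RPE MTP-A mRNA relative to liver
    p_apoai_cc: float = 1.2e-4  # cm/s, ApoA-I-Ch permeability across the CC
    ch_to_apoai_mass_ratio: float = 0.14  # Ch mass per ApoA-I mass, calibrated
    deposit_ch_density: float = DEFAULT_DEPOSIT_CH_DENSITY  # pg/mm^3

    def __post_init__(self) -> None:
        for name in (
            "kin_abca1",
            "apical_basal_ratio",
            "hepatic_apob_flux",
            "apob_expr_frac",
            "mtp_expr_frac",
            "p_apoai_cc",
            "ch_to_apoai_mass_ratio",
            "deposit_ch_density",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.apical_basal_ratio <= 1:
            raise ValueError("apical_basal_ratio must exceed 1")


@dataclass
class MacrophageParams:
    """Macrophage clearance kinetics and scenario density."""

    vmax_per_cell: float = 5.79e-2  # pg/cell/min at saturating ApoA-I
    km_apoai: float = 5.0  # ug/ml
    density: float = 1000.0  # cells/mm^2, scenario range 0-5000
    c_apoai_brm: float = 25.0  # ug/ml lipid-poor ApoA-I near the deposit
    saturating_apoai: bool = False

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.vmax_per_cell <= 0 or self.km_apoai <= 0 or self.c_apoai_brm < 0:
            raise ValueError("vmax_per_cell and km_apoai must be > 0, c_apoai_brm >= 0")

    @property
    def saturation_factor(self) -> float:
        if self.saturating_apoai:
            return 1.0
        return self.c_apoai_brm / (self.km_apoai + self.c_apoai_brm)

    def with_density(self, density: float) -> "MacrophageParams":
        return replace(self, density=density)


@dataclass
class DrusenTrajectory:
    """Piecewise-linear drusen thickness time course."""

    times: np.ndarray  # min
    heights: np.ndarray  # um, floored at 0
    time_to_clear: float | None  # min, None if the deposit never clears
    net_rate: float  # um/year, negative = shrinking


def basal_abca1_flux(kin_abca1: float, apical_basal_ratio: float) -> float:
    """Basal ABCA1 efflux flux obtained by scaling the apical flux by the
    apical:basal expression ratio (pg/mm^2/min)."""
    if kin_abca1 <= 0 or apical_basal_ratio <= 0:
        raise ValueError("inputs must be > 0")
    return kin_abca1 / apical_basal_ratio


def apob_ch_flux(
    hepatic_flux: float, apob_expr_frac: float, mtp_expr_frac: float
) -> float:
    """ApoB-cholesterol secretion flux of the RPE (pg/mm^2/min): the
    liver-equivalent rate scaled by the relative ApoB and MTP expression."""
    for frac in (apob_expr_frac, mtp_expr_frac):
        if not (0.0 < frac <= 1.0):
            raise ValueError("expression fractions must lie in (0, 1]")
    if hepatic_flux < 0:
        raise ValueError("hepatic_flux must be >= 0")
    return hepatic_flux * apob_expr_frac * mtp_expr_frac


def apoai_ch_concentration(
    flux: float, p_apoai_cc: float, ch_to_apoai_mass_ratio: float
) -> tuple[float, float]:
    """Steady-state ApoA-I-Ch concentrations in Bruch's membrane sustained by
    an efflux ``flux`` cleared through the CC fenestrae.

    Returns (cholesterol concentration, ApoA-I protein concentration), both
    mg/dl.  C = flux / (flux coefficient of P); protein = Ch / mass ratio.
    """
    if flux <= 0 or p_apoai_cc <= 0 or ch_to_apoai_mass_ratio <= 0:
        raise ValueError("inputs must be > 0")
    ch_conc = flux / flux_coefficient(p_apoai_cc)
    return ch_conc, ch_conc / ch_to_apoai_mass_ratio


def deposit_density_from_growth_calibration(
    reference_flux: float = 1.0, reference_growth: float = 0.7
) -> float:
    """Volumetric cholesterol density of the deposit (pg/mm^3) implied by a
    reference (flux pg/mm^2/min, growth um/year) pair."""
    if reference_flux <= 0 or reference_growth <= 0:
        raise ValueError("inputs must be > 0")
    return reference_flux * MIN_PER_YEAR / (reference_growth / UM_PER_MM)


def drusen_growth_rate(apob_flux: float, deposit_ch_density: float) -> float:
    """Linear drusen thickness growth rate (um/year) produced by a trapped
    ApoB-Ch flux; proportional to the flux."""
    if apob_flux < 0 or deposit_ch_density <= 0:
        raise ValueError("apob_flux must be >= 0 and deposit_ch_density > 0")
    return mm_per_min_to_um_per_year(apob_flux / deposit_ch_density)


def drusen_height(rate: float, years: float) -> float:
    """Deposit thickness (um) after ``years`` of linear growth at ``rate``
    um/year (includes the basal linear deposit)."""
    if rate < 0 or years < 0:
        raise ValueError("inputs must be >= 0")
    return rate * years


def macrophage_clearance_flux(mac: MacrophageParams) -> float:
    """Areal cholesterol clearance flux of the macrophage population
    (pg/mm^2/min): density x per-cell vmax x ApoA-I saturation factor."""
    return mac.density * mac.vmax_per_cell * mac.saturation_factor


def drusen_clearance_timecourse(
    h0: float,
    mac: MacrophageParams,
    efflux: EffluxParams,
    include_deposition: bool = False,
    t_grid: np.ndarray | None = None,
) -> DrusenTrajectory:
    """Drusen thickness under macrophage clearance (optionally with
    concurrent ApoB-Ch deposition).

    dh/dt = (deposition - clearance) / rho; the height is linear until it
    hits zero and stays there.  ``time_to_clear`` is the zero-crossing time
    when the net flux is negative, else None.
    """
    if h0 < 0:
        raise ValueError("h0 must be >= 0")
    deposition = (
        apob_ch_flux(efflux.hepatic_apob_flux, efflux.apob_expr_frac, efflux.mtp_expr_frac)
        if include_deposition
        else 0.0
    )
    net_flux = deposition - macrophage_clearance_flux(mac)  # pg/mm^2/min
    rho = efflux.deposit_ch_density
    rate_um_per_min = net_flux / rho * UM_PER_MM  # um/min
    if net_flux < 0:
        time_to_clear = h0 / (-rate_um_per_min) if h0 > 0 else 0.0
    else:
        time_to_clear = None
    if t_grid is None:
        horizon = 1.25 * time_to_clear if time_to_clear else 10.0 * MIN_PER_YEAR
        t_grid = np.linspace(0.0, max(horizon, 1.0), 201)
    t_grid = np.asarray(t_grid, dtype=float)
    heights = np.clip(h0 + rate_um_per_min * t_grid, 0.0, None)
    return DrusenTrajectory(
        times=t_grid,
        heights=heights,
        time_to_clear=time_to_clear,
        net_rate=mm_per_min_to_um_per_year(net_flux / rho),
    )


def required_macrophage_density(
    h0: float, t_clear: float, mac: MacrophageParams, efflux: EffluxParams
) -> float:
    """Macrophage density (cells/mm^2) needed to clear a deposit of height
    ``h0`` (um) in ``t_clear`` minutes, clearance-only linear model.

    Inverse of :func:`drusen_clearance_timecourse`:
    density = h0 * rho / (t_clear * vmax_per_cell * saturation_factor).
    """
    if h0 <= 0 or t_clear <= 0:
        raise ValueError("h0 and t_clear must be > 0")
    mass_per_area = (h0 / UM_PER_MM) * efflux.deposit_ch_density  # pg/mm^2
    return mass_per_area / (t_clear * mac.vmax_per_cell * mac.saturation_factor)
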