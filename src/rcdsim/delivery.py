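"""Cholesterol delivery from the choriocapillaris (CC) to the RPE.

LDL particles cross the fenestrated CC endothelium by transcytosis, modelled
as effective permeabilities P_in (lumen -> Bruch's membrane) and P_out
(back-flux).  In Bruch's membrane (BrM) the free LDL pool is cleared by
LDL-receptor endocytosis at the basal RPE surface, with Michaelis-Menten
kinetics V(C) = Vmax*C/(Km + C).  At steady state

    P_in*C_CC = P_out*C_BrM + Vmax*C_BrM/(Km + C_BrM)

which is a quadratic in C_BrM with a single positive root.  Concentrations
are LDL cholesterol in mg/dl; fluxes pg/mm^2/min.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import sqrt

import numpy as np
import pandas as pd

from .units import flux_coefficient


@dataclass
class DeliveryParams:
    """Transcytosis permeabilities and LDLR uptake constants."""

    p_in_ldl: float = 1.2e-7  # cm/s
    pout_ratio: float = 1.0  # P_out/P_in, scenario values 0.1, 0.5, 1
    vmax_ldlr: float = 13.1  # pg/mm^2/min
    km_ldlr: float = 5.4  # mg/dl LDL-Ch
    kin_abca1: float = 6.73  # pg/mm^2/min, apical ABCA1 delivery to the rods

    def __post_init__(self) -> None:
        if self.p_in_ldl <= 0 or self.vmax_ldlr <= 0 or self.km_ldlr <= 0:
            raise ValueError("p_in_ldl, vmax_ldlr and km_ldlr must be > 0")
        if not (0.0 <= self.pout_ratio <= 1.0):
            raise ValueError(f"pout_ratio must lie in [0, 1], got {self.pout_ratio}")
        if self.kin_abca1 <= 0:
            raise ValueError("kin_abca1 must be > 0")

    @property
    def p_out_ldl(self) -> float:
        return self.pout_ratio * self.p_in_ldl

    def with_pout_ratio(self, ratio: float) -> "DeliveryParams":
        return replace(self, pout_ratio=ratio)


class NoSteadyStateError(RuntimeError):
    """Influx exceeds the uptake capacity with no back-flux: the BrM pool
    grows without bound."""


def ldlr_uptake_flux(c_brm: float, params: DeliveryParams) -> float:
    """Michaelis-Menten LDLR uptake flux at BrM LDL-Ch concentration
    ``c_brm`` (mg/dl); saturates at Vmax."""
    if c_brm < 0:
        raise ValueError("concentration must be >= 0")
    return params.vmax_ldlr * c_brm / (params.km_ldlr + c_brm)


def brm_ldl_steady_state(c_cc: float, params: DeliveryParams) -> tuple[float, float]:
    """Steady-state BrM LDL-Ch concentration and RPE uptake flux for a given
    choriocapillaris LDL-Ch concentration ``c_cc`` (mg/dl).

    Solves the flux balance in closed form.  With P_out > 0 the balance is
    a quadratic with exactly one positive root; with P_out = 0 a solution
    exists only while the influx stays below Vmax.
    """
    if c_cc < 0:
        raise ValueError("concentration must be >= 0")
    if c_cc == 0.0:
        return 0.0, 0.0
    a = flux_coefficient(params.p_in_ldl)  # pg/mm^2/min per mg/dl
    b = flux_coefficient(params.p_out_ldl)
    v, km = params.vmax_ldlr, params.km_ldlr
    phi_in = a * c_cc
    if b == 0.0:
        if phi_in >= v:
            raise NoSteadyStateError(
                "no steady state (unbounded BrM accumulation): influx "
                f"{phi_in:.4g} pg/mm^2/min >= Vmax {v:.4g} with P_out = 0"
            )
        c_brm = km * phi_in / (v - phi_in)
    else:
        # b*C^2 + (b*Km + V - phi_in)*C - phi_in*Km = 0; the positive root
        # in the cancellation-free form (matters when b*C << V)
        beta = b * km + v - phi_in
        disc = sqrt(beta * beta + 4.0 * b * phi_in * km)
        if beta > 0:
            c_brm = 2.0 * phi_in * km / (beta + disc)
        else:
            c_brm = (disc - beta) / (2.0 * b)
    return c_brm, ldlr_uptake_flux(c_brm, params)


def c90_threshold(params: DeliveryParams) -> float:
    """Choriocapillaris LDL-Ch concentration (mg/dl) at which RPE uptake
    reaches 90% of Vmax.

    Uptake = 0.9 Vmax requires C_BrM = 9 Km; inverting the balance gives
    ``C_CC = (P_out_flux(9 Km) + 0.9 Vmax) / a`` with ``a`` the influx flux
    coefficient.  Increasing in pout_ratio and in Km.
    """
    a = flux_coefficient(params.p_in_ldl)
    b = flux_coefficient(params.p_out_ldl)
    c_brm_90 = 9.0 * params.km_ldlr
    return (b * c_brm_90 + 0.9 * params.vmax_ldlr) / a


def uptake_curve(
    params: DeliveryParams,
    c_cc_grid: np.ndarray,
    pout_ratios: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """Steady-state uptake as a function of choriocapillaris LDL-Ch.

    Returns a table with columns (pout_ratio, c_cc, c_brm, uptake_flux),
    one block per permeability-ratio scenario.
    """
    c_cc_grid = np.asarray(c_cc_grid, dtype=float)
    if np.any(c_cc_grid < 0) or np.any(np.diff(c_cc_grid) < 0):
        raise ValueError("c_cc_grid must be non-negative and non-decreasing")
    if pout_ratios is None:
        pout_ratios = (params.pout_ratio,)
    rows = []
    for ratio in pout_ratios:
        p = params.with_pout_ratio(ratio)
        for c_cc in c_cc_grid:
            c_brm, flux = brm_ldl_steady_state(c_cc, p)
            rows.append((ratio, c_cc, c_brm, flux))
    return pd.DataFrame(rows, columns=["pout_ratio", "c_cc", "c_brm", "uptake_flux"])


def abca1_apical_delivery(params: DeliveryParams) -> float:
    """ABCA1-mediated cholesterol flux from the apical RPE surface into the
    rod layer (pg/mm^2/min); a constant in this model."""
    return params.kin_abca1
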