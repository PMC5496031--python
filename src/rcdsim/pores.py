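"""Hindered diffusion of lipoprotein particles through the diaphragmed
fenestrae of the choriocapillaris endothelium.

Each fenestra is bridged by a diaphragm perforated by cylindrical pores of
~6-12 nm.  A particle of diameter d diffusing through a pore of diameter
d_p is slowed by the Renkin centerline hindrance factor H(lambda), with
lambda = d/d_p; particles with lambda >= 1 are sterically excluded.  The
effective endothelial permeability is

    P = D * H(lambda) * epsilon / L

with D the Stokes-Einstein free diffusivity, epsilon the open pore area
fraction (fenestra density x pores per fenestra x pore cross-section) and L
the pore (diaphragm) path length.  Small ~6.3 nm ApoA-I-Ch particles pass;
21 nm LDL and ~70 nm ApoB-Ch particles do not.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi

BOLTZMANN_J_PER_K = 1.380649e-23

#: particle diameters (nm) of the lipoproteins considered by the model
PARTICLE_DIAMETERS_NM = {"apoai-ch": 6.3, "ldl": 21.0, "apob-ch": 70.0}


@dataclass
class PoreModelParams:
    """Geometry and physical conditions of the fenestral pore pathway.

    The geometry defaults (pore diameter at the upper end of the observed
    6-12 nm range, pore length, pores per fenestra, fenestra density) are a
    calibration set chosen to land the ApoA-I-Ch permeability on the value
    the downstream model uses; see docs/methods.md.
    """

    particle_diameter: float = 6.3  # nm
    pore_diameter: float = 12.0  # nm
    pore_length: float = 40.0  # nm
    pores_per_fenestra: int = 12
    fenestra_density: float = 1.0e7  # per mm^2 (= 10 per um^2)
    temperature: float = 310.0  # K
    solvent_viscosity: float = 6.9e-4  # Pa s, water at 37 C

    def __post_init__(self) -> None:
        for name in (
            "particle_diameter",
            "pore_diameter",
            "pore_length",
            "pores_per_fenestra",
            "fenestra_density",
            "temperature",
            "solvent_viscosity",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class PermeabilityResult:
    diffusivity: float  # cm^2/s
    lam: float  # particle/pore diameter ratio
    hindrance: float
    open_area_fraction: float
    permeability: float  # cm/s
    size_excluded: bool


def stokes_einstein_diffusivity(d_nm: float, temperature: float, viscosity: float) -> float:
    """Free diffusivity (cm^2/s) of a sphere of diameter ``d_nm`` nm:
    D = k_B T / (3 pi eta d)."""
    if d_nm <= 0 or temperature <= 0 or viscosity <= 0:
        raise ValueError("inputs must be > 0")
    d_m = d_nm * 1e-9
    d_si = BOLTZMANN_J_PER_K * temperature / (3.0 * pi * viscosity * d_m)  # m^2/s
    return d_si * 1e4


def renkin_hindrance(lam: float) -> float:
    """Centerline hindrance factor for a sphere in a cylindrical pore,
    H(lambda) = (1-lambda)^2 (1 - 2.104 lambda + 2.09 lambda^3
    - 0.95 lambda^5); zero at and beyond lambda = 1 (steric exclusion)."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if lam >= 1.0:
        return 0.0
    partition = (1.0 - lam) ** 2
    drag = 1.0 - 2.104 * lam + 2.09 * lam**3 - 0.95 * lam**5
    return partition * max(drag, 0.0)


def open_area_fraction(params: PoreModelParams) -> float:
    """Fraction of the endothelial surface open as pore cross-section."""
    pore_radius_cm = params.pore_diameter / 2.0 * 1e-7
    pore_area_cm2 = pi * pore_radius_cm**2
    fenestrae_per_cm2 = params.fenestra_density * 100.0  # mm^-2 -> cm^-2
    return fenestrae_per_cm2 * params.pores_per_fenestra * pore_area_cm2


def fenestra_permeability(params: PoreModelParams) -> PermeabilityResult:
    """Effective permeability (cm/s) of the fenestral pore pathway for the
    configured particle; zero with ``size_excluded=True`` when the particle
    does not fit the pore."""
    d = stokes_einstein_diffusivity(
        params.particle_diameter, params.temperature, params.solvent_viscosity
    )
    lam = params.particle_diameter / params.pore_diameter
    h = renkin_hindrance(lam)
    eps = open_area_fraction(params)
    pore_length_cm = params.pore_length * 1e-7
    p = d * h * eps / pore_length_cm
    return PermeabilityResult(
        diffusivity=d,
        lam=lam,
        hindrance=h,
        open_area_fraction=eps,
        permeability=p,
        size_excluded=lam >= 1.0,
    )
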