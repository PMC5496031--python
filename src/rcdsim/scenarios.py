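"""Scenario runner: machine-readable tables for the model's standard
steady-state curves and simulations, a flux summary, and Monte-Carlo
uncertainty propagation of the registry CVs.

Scenario ids
------------
``fig5a``   disc cholesterol / Ch-PL ratio profile down the transit chain
``fig5b``   turnover flux Kin_Ch versus the recycling fraction
``fig6``    RPE uptake flux versus choriocapillaris LDL-Ch, three P_out/P_in
``fig7``    linear drusen growth over 50 years at bounding fluxes 1 and 6
``fig8a``   drusen clearance versus macrophage density (0-5000 cells/mm^2)
``fig8b``   clearance versus per-macrophage vmax fold change (0.25-10)
``fig8c``   clearance versus ApoA-I fold change (0.25-10) plus saturating limit
``flux_table``  the named steady-state fluxes side by side
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd

from . import __version__
from .delivery import abca1_apical_delivery, c90_threshold, uptake_curve
from .drusen import (
    apob_ch_flux,
    basal_abca1_flux,
    drusen_clearance_timecourse,
    drusen_growth_rate,
)
from .params import ModelParameters, load_parameters, sample_parameters
from .ros import steady_state_profile, turnover_rate
from .units import MIN_PER_YEAR

FIG8_DENSITIES = (0.0, 500.0, 1000.0, 2500.0, 5000.0)
FIG8_FOLDS = (0.25, 0.5, 1.0, 2.0, 5.0, 10.0)


@dataclass
class ScenarioResult:
    scenario_id: str
    tables: dict[str, pd.DataFrame]
    metadata: dict


def _meta(params: ModelParameters, **extra) -> dict:
    meta = {
        "version": __version__,
        "k_out_mode": params.k_out_mode,
        "parameters": {name: p.value for name, p in params.registry.items()},
        "ros_k_out_per_day": params.ros.k_out,
    }
    meta.update(extra)
    return meta


def _fig5a(params: ModelParameters) -> dict[str, pd.DataFrame]:
    ss = steady_state_profile(params.ros)
    table = pd.DataFrame(
        {
            "compartment": np.arange(1, params.ros.n_compartments + 1),
            "relative_ch": ss.ch_per_compartment,
            "ch_pl_ratio": ss.ch_pl_ratio_profile,
        }
    )
    return {"profile": table}


def _fig5b(params: ModelParameters) -> dict[str, pd.DataFrame]:
    f_grid = np.linspace(0.0, 1.0, 21)
    kin = [turnover_rate(params.ros.with_recycling(f)) for f in f_grid]
    return {"turnover": pd.DataFrame({"f_recycling": f_grid, "kin_ch": kin})}


def _fig6(params: ModelParameters) -> dict[str, pd.DataFrame]:
    grid = np.linspace(0.0, 200.0, 201)
    ratios = (0.1, 0.5, 1.0)
    curve = uptake_curve(params.delivery, grid, pout_ratios=ratios)
    c90 = pd.DataFrame(
        {
            "pout_ratio": ratios,
            "c90_mg_dl": [c90_threshold(params.delivery.with_pout_ratio(r)) for r in ratios],
        }
    )
    return {"curve": curve, "c90": c90}


def _fig7(params: ModelParameters) -> dict[str, pd.DataFrame]:
    years = np.linspace(0.0, 50.0, 51)
    rho = params.efflux.deposit_ch_density
    lo = drusen_growth_rate(1.0, rho)
    hi = drusen_growth_rate(6.0, rho)
    return {
        "growth": pd.DataFrame(
            {"years": years, "height_low_um": lo * years, "height_high_um": hi * years}
        )
    }


def _clearance_family(
    params: ModelParameters, label: str, values, make_mac: Callable
) -> dict[str, pd.DataFrame]:
    t_grid = np.linspace(0.0, 10.0 * MIN_PER_YEAR, 241)
    curves, summary = [], []
    for v in values:
        mac = make_mac(v)
        traj = drusen_clearance_timecourse(120.0, mac, params.efflux, t_grid=t_grid)
        curves.append(
            pd.DataFrame({label: v, "time_years": t_grid / MIN_PER_YEAR, "height_um": traj.heights})
        )
        ttc = traj.time_to_clear
        summary.append((v, ttc / MIN_PER_YEAR if ttc is not None else np.nan, traj.net_rate))
    return {
        "curves": pd.concat(curves, ignore_index=True),
        "summary": pd.DataFrame(summary, columns=[label, "time_to_clear_years", "net_rate_um_year"]),
    }


def _fig8a(params: ModelParameters) -> dict[str, pd.DataFrame]:
    base = params.macrophage
    return _clearance_family(
        params, "density", FIG8_DENSITIES, lambda d: base.with_density(d)
    )


def _fig8b(params: ModelParameters) -> dict[str, pd.DataFrame]:
    base = params.macrophage
    return _clearance_family(
        params,
        "vmax_fold",
        FIG8_FOLDS,
        lambda f: replace(base, vmax_per_cell=f * base.vmax_per_cell),
    )


def _fig8c(params: ModelParameters) -> dict[str, pd.DataFrame]:
    base = params.macrophage
    out = _clearance_family(
        params,
        "apoai_fold",
        FIG8_FOLDS,
        lambda f: replace(base, c_apoai_brm=f * base.c_apoai_brm),
    )
    sat = drusen_clearance_timecourse(
        120.0, replace(base, saturating_apoai=True), params.efflux
    )
    out["saturating_limit"] = pd.DataFrame(
        {
            "time_to_clear_years": [sat.time_to_clear / MIN_PER_YEAR],
            "net_rate_um_year": [sat.net_rate],
        }
    )
    return out


def flux_summary(params: ModelParameters) -> pd.DataFrame:
    """The model's named steady-state cholesterol fluxes (pg/mm^2/min)."""
    e = params.efflux
    rows = [
        ("KinCh_f0", turnover_rate(params.ros.with_recycling(0.0)),
         "ROS turnover flux, no recycling"),
        ("KinCh_f1", turnover_rate(params.ros.with_recycling(1.0)),
         "ROS turnover flux, complete recycling"),
        ("VmaxLDLR", params.delivery.vmax_ldlr, "maximum LDLR uptake flux"),
        ("KinABCA1", abca1_apical_delivery(params.delivery),
         "apical ABCA1 delivery to the outer retina"),
        ("KoutABCA1", basal_abca1_flux(e.kin_abca1, e.apical_basal_ratio),
         "basal ABCA1 efflux to Bruch's membrane"),
        ("KoutApoBCh", apob_ch_flux(e.hepatic_apob_flux, e.apob_expr_frac, e.mtp_expr_frac),
         "ApoB-Ch particle secretion into Bruch's membrane"),
    ]
    return pd.DataFrame(rows, columns=["flux", "value_pg_mm2_min", "description"])


def _flux_table(params: ModelParameters) -> dict[str, pd.DataFrame]:
    return {"fluxes": flux_summary(params)}


_SCENARIOS: dict[str, Callable[[ModelParameters], dict[str, pd.DataFrame]]] = {
    "fig5a": _fig5a,
    "fig5b": _fig5b,
    "fig6": _fig6,
    "fig7": _fig7,
    "fig8a": _fig8a,
    "fig8b": _fig8b,
    "fig8c": _fig8c,
    "flux_table": _flux_table,
}


def scenario_ids() -> tuple[str, ...]:
    return tuple(_SCENARIOS)


def run_scenario(
    scenario_id: str,
    params: ModelParameters | None = None,
    overrides: dict | None = None,
) -> ScenarioResult:
    """Run a named scenario at its baseline values and return its tables.

    ``overrides`` maps registry keys to replacement point values (applied
    through the same validation as a config file).
    """
    if scenario_id not in _SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario_id!r}; valid ids: {', '.join(_SCENARIOS)}"
        )
    if params is None:
        params = load_parameters()
    if overrides:
        from .params import ParameterValue

        registry = dict(params.registry)
        for key, value in overrides.items():
            if key not in registry:
                raise ValueError(f"unknown parameter key {key!r} in overrides")
            base = registry[key]
            registry[key] = ParameterValue(
                base.name, float(value), base.percent_uncertainty, base.units, base.source
            )
        from .params import _build

        params = _build(registry, params.k_out_mode)
    tables = _SCENARIOS[scenario_id](params)
    return ScenarioResult(scenario_id=scenario_id, tables=tables, metadata=_meta(params))


def monte_carlo(
    params: ModelParameters | None = None,
    n: int = 2000,
    seed: int = 0,
    outputs: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Propagate the registry CVs through the flux summary and the drusen
    growth rate.

    Returns median and 2.5/97.5 percentiles per output.  Medians recover the
    point estimates because the sampling distributions are lognormal with
    median at the point value.
    """
    if params is None:
        params = load_parameters()
    if n < 100:
        raise ValueError("n must be >= 100 for stable percentiles")
    draws = sample_parameters(params, n, seed)
    records: dict[str, list[float]] = {}
    for d in draws:
        fs = flux_summary(d).set_index("flux")["value_pg_mm2_min"]
        for name, value in fs.items():
            records.setdefault(name, []).append(float(value))
        apob = apob_ch_flux(
            d.efflux.hepatic_apob_flux, d.efflux.apob_expr_frac, d.efflux.mtp_expr_frac
        )
        records.setdefault("drusen_growth_um_year", []).append(
            drusen_growth_rate(apob, d.efflux.deposit_ch_density)
        )
    if outputs is not None:
        records = {k: v for k, v in records.items() if k in outputs}
    rows = []
    for name, values in records.items():
        arr = np.asarray(values)
        rows.append(
            (name, float(np.median(arr)), float(np.percentile(arr, 2.5)),
             float(np.percentile(arr, 97.5)))
        )
    return pd.DataFrame(rows, columns=["output", "median", "p2.5", "p97.5"])
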