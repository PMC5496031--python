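"""Parameter registry: every model constant with units, percent uncertainty
(interpreted as a coefficient of variation) and provenance, plus the
structured parameter objects the simulation modules consume.

The registry keys follow the flux/parameter names used in the field
(ASCII-transliterated): ``KinCh_f0``, ``k_t``, ``PinLDL``, ``VmaxLDLR_ARPE``,
``KmMac`` and so on.  A YAML config file with the same keys can override any
point value or uncertainty; unknown keys are rejected so typos cannot pass
silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml

from .delivery import DeliveryParams
from .drusen import EffluxParams, MacrophageParams, deposit_density_from_growth_calibration
from .ros import RosChainParams, calibrate_k_out


@dataclass(frozen=True)
class ParameterValue:
    """A named physical quantity with units, uncertainty and provenance."""

    name: str
    value: float
    percent_uncertainty: float
    units: str
    source: str

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"parameter {self.name!r}: value must be >= 0, got {self.value}")
        if self.percent_uncertainty < 0:
            raise ValueError(
                f"parameter {self.name!r}: percent_uncertainty must be >= 0, "
                f"got {self.percent_uncertainty}"
            )


def _default_entries() -> list[ParameterValue]:
    pv = ParameterValue
    return [
        # --- ROS turnover ---
        pv("KinCh_f0", 5.84, 49.0, "pg/mm^2/min",
           "steady-state Ch turnover flux at zero recycling"),
        pv("KinCh_f1", 0.97, 49.0, "pg/mm^2/min",
           "steady-state Ch turnover flux at complete recycling"),
        pv("Kindiscs", 85.0, 6.0, "discs/day", "rate of new disc formation entering the ROS"),
        pv("k_t", 0.85, 6.0, "1/day", "first-order disc transfer rate within the transit chain"),
        pv("k_out", 0.19, 34.0, "1/day",
           "first-order Ch removal from transit compartments 2-10"),
        pv("ch_pl_ratio_initial", 0.3, 0.0, "molar ratio",
           "Ch/PL molar ratio of newly formed discs"),
        pv("fold_decrease", 6.0, 0.0, "dimensionless",
           "disc Ch decrease from the newest to the oldest compartment"),
        pv("n_compartments", 10.0, 0.0, "count", "transit-chain length"),
        pv("discs_per_compartment", 100.0, 0.0, "count", "discs per transit compartment"),
        # --- choroidal delivery ---
        pv("PinLDL", 1.2e-7, 7.0, "cm/s",
           "effective LDL transcytosis permeability, lumen to Bruch's membrane"),
        pv("PoutLDL_ratio", 1.0, 0.0, "dimensionless",
           "P_out/P_in back-flux ratio; scenario values 0.1, 0.5, 1"),
        pv("VmaxLDLR_ARPE", 13.1, 50.0, "pg/mm^2/min",
           "maximum LDLR-mediated LDL-Ch uptake flux of the RPE (downregulated state)"),
        pv("KmLDLR", 5.4, 9.0, "mg/dl",
           "Michaelis constant of LDLR uptake, as LDL-Ch concentration"),
        pv("KinABCA1", 6.73, 50.0, "pg/mm^2/min",
           "apical ABCA1-mediated Ch delivery from RPE to outer retina"),
        # --- basal efflux / drusen ---
        pv("KoutABCA1", 1.06, 50.0, "pg/mm^2/min",
           "basal ABCA1-mediated Ch efflux from RPE to Bruch's membrane"),
        pv("apical_basal_ABCA1_ratio", 6.37, 0.0, "dimensionless",
           "apical:basal ABCA1 expression ratio of the RPE"),
        pv("PApoA1ChCC", 1.2e-4, 41.0, "cm/s",
           "permeability of ApoA-I-Ch particles across the choriocapillaris"),
        pv("KoutApoBCh", 3.0, 50.0, "pg/mm^2/min",
           "Ch efflux in ApoB particles across the basal RPE membrane"),
        pv("hepatic_ApoB_Ch_flux", 967.0, 50.0, "pg/mm^2/min",
           "liver-equivalent ApoB-Ch secretion flux before expression scaling; "
           "carries the CV of the scaled efflux estimate"),
        pv("ApoB_expr_frac", 0.075, 0.0, "dimensionless",
           "RPE ApoB mRNA expression relative to liver"),
        pv("MTP_expr_frac", 0.04, 0.0, "dimensionless",
           "RPE MTP-A mRNA expression relative to liver"),
        pv("ch_to_apoai_mass_ratio", 0.14, 0.0, "dimensionless",
           "Ch mass per ApoA-I mass in nascent particles (calibrated)"),
        pv("drusen_growth_rate_ref", 0.7, 49.0, "um/year",
           "deposit growth rate at a trapped flux of 1 pg/mm^2/min"),
        pv("KmMac", 5.0, 35.0, "ug/ml",
           "Michaelis constant of macrophage ABCA1 efflux, as ApoA-I concentration"),
        pv("vmaxMac", 5.79e-2, 27.0, "pg/cell/min",
           "maximum ABCA1-mediated Ch efflux per macrophage at saturating ApoA-I"),
        pv("CBrMApoAI", 25.0, 0.0, "ug/ml",
           "baseline lipid-poor ApoA-I concentration in Bruch's membrane"),
    ]


_OVERRIDABLE_FIELDS = {"value", "percent_uncertainty"}


@dataclass
class ModelParameters:
    """Resolved model configuration: the registry plus the structured
    per-module parameter objects built from it."""

    ros: RosChainParams
    delivery: DeliveryParams
    efflux: EffluxParams
    macrophage: MacrophageParams
    registry: dict[str, ParameterValue]
    k_out_mode: str = "calibrated"

    def __getitem__(self, name: str) -> ParameterValue:
        return self.registry[name]

    def __iter__(self) -> Iterator[ParameterValue]:
        return iter(self.registry.values())


class ConfigError(ValueError):
    """Malformed or inconsistent parameter configuration."""


def _build(registry: dict[str, ParameterValue], k_out_mode: str) -> ModelParameters:
    g = lambda k: registry[k].value  # noqa: E731
    if k_out_mode == "calibrated":
        k_out = calibrate_k_out(g("fold_decrease"), g("k_t"), int(g("n_compartments")))
    elif k_out_mode == "table":
        k_out = g("k_out")
    else:
        raise ConfigError(f"unknown k_out mode {k_out_mode!r}; use 'calibrated' or 'table'")
    ros = RosChainParams(
        n_compartments=int(g("n_compartments")),
        discs_per_compartment=int(g("discs_per_compartment")),
        disc_influx_rate=g("Kindiscs"),
        k_t=g("k_t"),
        k_out=k_out,
        ch_pl_ratio_initial=g("ch_pl_ratio_initial"),
        j0_flux=g("KinCh_f0"),
        f_recycling=0.0,
    )
    delivery = DeliveryParams(
        p_in_ldl=g("PinLDL"),
        pout_ratio=g("PoutLDL_ratio"),
        vmax_ldlr=g("VmaxLDLR_ARPE"),
        km_ldlr=g("KmLDLR"),
        kin_abca1=g("KinABCA1"),
    )
    efflux = EffluxParams(
        kin_abca1=g("KinABCA1"),
        apical_basal_ratio=g("apical_basal_ABCA1_ratio"),
        hepatic_apob_flux=g("hepatic_ApoB_Ch_flux"),
        apob_expr_frac=g("ApoB_expr_frac"),
        mtp_expr_frac=g("MTP_expr_frac"),
        p_apoai_cc=g("PApoA1ChCC"),
        ch_to_apoai_mass_ratio=g("ch_to_apoai_mass_ratio"),
        deposit_ch_density=deposit_density_from_growth_calibration(
            1.0, g("drusen_growth_rate_ref")
        ),
    )
    macrophage = MacrophageParams(
        vmax_per_cell=g("vmaxMac"),
        km_apoai=g("KmMac"),
        density=1000.0,
        c_apoai_brm=g("CBrMApoAI"),
        saturating_apoai=False,
    )
    return ModelParameters(
        ros=ros,
        delivery=delivery,
        efflux=efflux,
        macrophage=macrophage,
        registry=registry,
        k_out_mode=k_out_mode,
    )


def default_registry() -> dict[str, ParameterValue]:
    return {p.name: p for p in _default_entries()}


def load_parameters(
    config_path: str | Path | None = None, k_out_mode: str = "calibrated"
) -> ModelParameters:
    """Default parameters, optionally overridden by a YAML config.

    The config maps registry keys either to a bare number (point-value
    override) or to a mapping with ``value`` and/or ``percent_uncertainty``.
    Unknown keys and negative values are rejected.
    """
    registry = default_registry()
    if config_path is not None:
        try:
            raw = yaml.safe_load(Path(config_path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {config_path}: {exc}") from exc
        if raw is None:
            raw = {}
        if not isinstance(raw, Mapping):
            raise ConfigError(f"config {config_path} must be a mapping of parameter names")
        for key, spec in raw.items():
            if key == "k_out_mode":
                k_out_mode = str(spec)
                continue
            if key not in registry:
                raise ConfigError(f"unknown parameter key {key!r} in {config_path}")
            base = registry[key]
            if isinstance(spec, Mapping):
                bad = set(spec) - _OVERRIDABLE_FIELDS
                if bad:
                    raise ConfigError(
                        f"parameter {key!r}: unknown field(s) {sorted(bad)}; "
                        f"allowed: {sorted(_OVERRIDABLE_FIELDS)}"
                    )
                value = float(spec.get("value", base.value))
                pct = float(spec.get("percent_uncertainty", base.percent_uncertainty))
            else:
                value = float(spec)
                pct = base.percent_uncertainty
            try:
                registry[key] = ParameterValue(base.name, value, pct, base.units, base.source)
            except ValueError as exc:
                raise ConfigError(str(exc)) from exc
    return _build(registry, k_out_mode)


def registry_to_json(params: ModelParameters, path: str | Path | None = None) -> str:
    """JSON export of the resolved registry including provenance strings."""
    payload = {
        name: {
            "value": p.value,
            "percent_uncertainty": p.percent_uncertainty,
            "units": p.units,
            "source": p.source,
        }
        for name, p in params.registry.items()
    }
    payload["_k_out_mode"] = params.k_out_mode
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def save_config(params: ModelParameters, path: str | Path) -> None:
    """Write the resolved registry back out as a config file.

    Loading the result reproduces the same ``ModelParameters`` (lossless
    round-trip)."""
    doc = {
        name: {"value": p.value, "percent_uncertainty": p.percent_uncertainty}
        for name, p in params.registry.items()
    }
    doc["k_out_mode"] = params.k_out_mode
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def sample_parameters(params: ModelParameters, n: int, seed: int) -> list[ModelParameters]:
    """``n`` Monte-Carlo draws of the parameter set.

    Each registry entry with a nonzero percent uncertainty is drawn from a
    lognormal distribution with median equal to the point value and
    coefficient of variation equal to percent_uncertainty/100; entries with
    zero uncertainty stay fixed.  Reproducible for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    draws: list[ModelParameters] = []
    names = list(params.registry)
    for _ in range(n):
        registry = {}
        deviates: dict[str, float] = {}
        for name in names:
            base = params.registry[name]
            cv = base.percent_uncertainty / 100.0
            if cv > 0 and base.value > 0:
                # k_t is Kindiscs/discs_per_compartment: same measurement,
                # same deviate, so every draw stays internally consistent
                key = "Kindiscs" if name in ("k_t", "Kindiscs") else name
                if key not in deviates:
                    deviates[key] = float(rng.normal())
                sigma = float(np.sqrt(np.log1p(cv * cv)))
                value = base.value * float(np.exp(sigma * deviates[key]))
            else:
                value = base.value
            registry[name] = ParameterValue(
                base.name, value, base.percent_uncertainty, base.units, base.source
            )
        draws.append(_build(registry, params.k_out_mode))
    return draws
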