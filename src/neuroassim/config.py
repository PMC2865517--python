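"""Flat parameter configuration keyed by the model's symbol names.

A config file is a YAML mapping from symbol to either a bare number or a
``{value, unit}`` pair; unknown keys and wrong units are rejected, missing
keys are filled with the shipped defaults (the standard parameter set of
this model family).  The same flat namespace feeds the cell, microenvironment
and synapse parameter builders, so a config round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .biophysics import CellParams, MicroenvParams, SynapseParams
from .errors import ConfigError

__all__ = ["ParamSpec", "Config", "load_config", "save_config", "SCHEMA"]


@dataclass(frozen=True)
class ParamSpec:
    default: float
    unit: str
    description: str
    nonnegative: bool = True


SCHEMA: dict[str, ParamSpec] = {
    # membrane (conductances in mS/cm^2)
    "C_m": ParamSpec(1.0, "uF/cm^2", "membrane capacitance"),
    "g_Na": ParamSpec(100.0, "mS/cm^2", "transient sodium conductance"),
    "g_K": ParamSpec(40.0, "mS/cm^2", "delayed-rectifier potassium conductance"),
    "g_AHP": ParamSpec(0.01, "mS/cm^2", "afterhyperpolarization conductance (PC only)"),
    "g_KL": ParamSpec(0.05, "mS/cm^2", "potassium leak conductance"),
    "g_NaL": ParamSpec(0.0175, "mS/cm^2", "sodium leak conductance"),
    "g_ClL": ParamSpec(0.05, "mS/cm^2", "chloride leak conductance"),
    "phi": ParamSpec(3.0, "1/ms", "gating time-constant factor"),
    "g_Ca": ParamSpec(0.1, "mS/cm^2", "calcium conductance"),
    "E_Ca": ParamSpec(120.0, "mV", "fixed calcium reversal potential", nonnegative=False),
    "Cl_o": ParamSpec(130.0, "mM", "extracellular chloride concentration"),
    "Cl_i": ParamSpec(6.0, "mM", "intracellular chloride concentration"),
    "I_stim": ParamSpec(0.0, "uA/cm^2", "constant bias current", nonnegative=False),
    # microenvironment
    "beta": ParamSpec(7.0, "1", "intra/extracellular volume ratio"),
    "rho": ParamSpec(1.25, "mM/s", "maximum Na/K pump rate"),
    "G_glia": ParamSpec(66.0, "mM/s", "maximum glial buffering rate"),
    "epsilon": ParamSpec(1.25, "1/s", "bath diffusion coefficient"),
    "K_bath": ParamSpec(3.0, "mM", "reservoir potassium concentration"),
    "gamma": ParamSpec(0.0445, "mM*cm^2/uC", "current-to-concentration conversion"),
    "delta": ParamSpec(0.0, "1/s", "lateral potassium diffusion coefficient"),
    "time_scale": ParamSpec(1.0, "1", "slow-subsystem time compression factor"),
    # Nernst / geometry
    "therm": ParamSpec(26.64, "mV", "thermal factor RT/F in the Nernst equation"),
    "radius": ParamSpec(7.0, "um", "micro-domain radius setting gamma"),
    "stim_radius": ParamSpec(20.0, "um", "effective membrane radius for pA conversion"),
    # synapse
    "g_inh": ParamSpec(0.84, "mS/cm^2", "GABA_A strength, IN onto PC"),
    "g_exc": ParamSpec(0.17, "mS/cm^2", "AMPA strength, PC onto IN"),
    "tau_e": ParamSpec(4.0, "ms", "excitatory synaptic time constant"),
    "tau_i": ParamSpec(8.0, "ms", "inhibitory synaptic time constant"),
    "E_exc": ParamSpec(0.0, "mV", "excitatory reversal potential", nonnegative=False),
    "E_inh": ParamSpec(-80.0, "mV", "inhibitory reversal potential", nonnegative=False),
    "s_theta": ParamSpec(-20.0, "mV", "synaptic activation threshold", nonnegative=False),
    "s_slope": ParamSpec(3.0, "mV", "synaptic activation slope"),
    "eta_theta": ParamSpec(-40.0, "mV", "depolarization-block threshold", nonnegative=False),
    "eta_slope": ParamSpec(2.0, "mV", "depolarization-block indicator slope"),
    "tau_eta": ParamSpec(800.0, "ms", "depolarization-block integration time"),
    "chi_half": ParamSpec(0.6, "1", "chi gate half point"),
    "chi_slope": ParamSpec(0.06, "1", "chi gate slope"),
}

_NEG_OK = {name for name, s in SCHEMA.items() if not s.nonnegative}


class Config:
    """Validated flat parameter bundle with attribute access."""

    def __init__(self, values: dict[str, float]):
        self._values = dict(values)

    def __getattr__(self, name: str) -> float:
        try:
            return self._values[name]
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def to_dict(self) -> dict[str, float]:
        return dict(self._values)

    # -- builders ------------------------------------------------------------
    def cell_params(self, cell_type: str = "PC", **overrides) -> CellParams:
        v = self._values
        kw = dict(C_m=v["C_m"], g_Na=v["g_Na"], g_K=v["g_K"],
                  g_AHP=v["g_AHP"] if cell_type == "PC" else 0.0,
                  g_KL=v["g_KL"], g_NaL=v["g_NaL"], g_ClL=v["g_ClL"],
                  g_Ca=v["g_Ca"], phi=v["phi"], E_Ca=v["E_Ca"],
                  Cl_i=v["Cl_i"], Cl_o=v["Cl_o"], cell_type=cell_type,
                  I_stim=v["I_stim"])
        kw.update(overrides)
        return CellParams(**kw)

    def microenv_params(self, **overrides) -> MicroenvParams:
        v = self._values
        kw = dict(rho=v["rho"], G_glia=v["G_glia"], epsilon=v["epsilon"],
                  K_bath=v["K_bath"], beta_vol=v["beta"], gamma=v["gamma"],
                  delta=v["delta"], time_scale=v["time_scale"])
        kw.update(overrides)
        return MicroenvParams(**kw)

    def synapse_params(self, **overrides) -> SynapseParams:
        v = self._values
        kw = dict(g_exc=v["g_exc"], g_inh=v["g_inh"], tau_e=v["tau_e"],
                  tau_i=v["tau_i"], E_exc=v["E_exc"], E_inh=v["E_inh"],
                  s_theta=v["s_theta"], s_slope=v["s_slope"],
                  eta_theta=v["eta_theta"], eta_slope=v["eta_slope"],
                  tau_eta=v["tau_eta"], chi_half=v["chi_half"],
                  chi_slope=v["chi_slope"])
        kw.update(overrides)
        return SynapseParams(**kw)


def _coerce(name: str, raw) -> float:
    if isinstance(raw, dict):
        extra = set(raw) - {"value", "unit"}
        if extra:
            raise ConfigError(f"{name}: unexpected fields {sorted(extra)}")
        if "unit" in raw and str(raw["unit"]) != SCHEMA[name].unit:
            raise ConfigError(
                f"{name}: unit {raw['unit']!r} does not match schema unit "
                f"{SCHEMA[name].unit!r}")
        raw = raw.get("value")
    try:
        val = float(raw)
    except (TypeError, ValueError):
        raise ConfigError(f"{name}: value {raw!r} is not a number") from None
    if val < 0 and name not in _NEG_OK:
        raise ConfigError(f"{name}: negative value {val} not allowed")
    return val


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> Config:
    """Load a YAML config; missing keys take defaults, unknown keys error."""
    values = {name: spec.default for name, spec in SCHEMA.items()}
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
    raw.update(overrides or {})
    for name, value in raw.items():
        if name not in SCHEMA:
            raise ConfigError(f"unknown config key {name!r}")
        values[name] = _coerce(name, value)
    return Config(values)


def save_config(config: Config, path: str | Path) -> None:
    """Write the full parameter set with units; round-trips exactly."""
    out = {name: {"value": config[name], "unit": SCHEMA[name].unit}
           for name in SCHEMA}
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))
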