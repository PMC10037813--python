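"""Parameter and state containers for the services-capacity stock-flow model.

The model tracks two stocks: people with mild/moderate disorders (``M``) and
people with severe disorders (``S``) who have engaged with specialised mental
health services, inside a total population ``P`` served by a capacity of ``C``
services per year.  All rates are per year; stocks are persons; capacity and
demand are services per year.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Optional

import yaml

__all__ = ["ModelParameters", "SystemState", "FlowRates", "Preset", "load_preset"]


class DomainError(ValueError):
    """An input violates the model's domain (negative stock, rate, ...)."""


@dataclass(frozen=True)
class ModelParameters:
    """Rate and ratio constants of the stock-flow model.

    Attributes
    ----------
    i : float
        Per-capita rate at which people with a perceived need engage with
        specialised services (1/year).
    gamma : float
        Proportion of people who already have a severe disorder when they
        first engage with services (dimensionless, in [0, 1]).
    v : float
        Per-capita disease progression rate, mild/moderate -> severe (1/year).
    u : float
        Per-capita spontaneous-recovery (or ageing-out) rate (1/year).
    r : float
        Proportion of treated patients who recover (dimensionless, in [0, 1]).
    k : float
        Mean number of services needed to treat one mild/moderate patient.
    theta : float
        Ratio of services needed per severe patient versus per mild/moderate
        patient (>= 1).
    mu : float
        Per-capita mortality rate for mild/moderate patients (1/year).
    eta : float
        Mortality hazard ratio for severe patients (>= 1).
    g : float
        Population growth, persons/year (0 for the generic analysis).
    h : float
        Capacity growth, services/year per year (0 for the generic analysis).
    """

    i: float
    gamma: float
    v: float
    u: float
    r: float
    k: float
    theta: float
    mu: float
    eta: float
    g: float = 0.0
    h: float = 0.0

    def __post_init__(self) -> None:
        for name in ("i", "v", "u", "mu", "k"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("gamma", "r"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise DomainError(f"{name} must be in [0, 1], got {val}")
        if self.theta < 1.0:
            raise DomainError(f"theta must be >= 1, got {self.theta}")
        if self.eta < 1.0:
            raise DomainError(f"eta must be >= 1, got {self.eta}")

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class SystemState:
    """The stocks and auxiliaries of the model at one instant.

    ``M`` and ``S`` are the engaged mild/moderate and severe stocks (persons),
    ``P`` the total population (persons), ``C`` the services capacity
    (services/year) and ``t`` the time in years.
    """

    t: float
    M: float
    S: float
    P: float
    C: float

    def __post_init__(self) -> None:
        if self.M < 0 or self.S < 0:
            raise DomainError(f"stocks must be >= 0, got M={self.M}, S={self.S}")
        if self.P <= 0:
            raise DomainError(f"population must be > 0, got P={self.P}")
        if self.C < 0:
            raise DomainError(f"capacity must be >= 0, got C={self.C}")
        if self.M + self.S > self.P * (1 + 1e-12):
            raise DomainError(
                f"engaged stocks exceed population: M+S={self.M + self.S} > P={self.P}"
            )


@dataclass(frozen=True)
class FlowRates:
    """The instantaneous flows of the model, all in persons/year except
    ``demand`` (services/year)."""

    inflow_M: float
    inflow_S: float
    progression: float
    spont_recovery_M: float
    spont_recovery_S: float
    treat_recovery_M: float
    treat_recovery_S: float
    mortality_M: float
    mortality_S: float
    demand: float
    patients_treated: float


@dataclass(frozen=True)
class Preset:
    """A bundled parameter configuration plus (possibly partial) initial state."""

    name: str
    params: ModelParameters
    M0: Optional[float] = None
    S0: Optional[float] = None
    P0: Optional[float] = None
    C0: Optional[float] = None
    raw: dict = field(default_factory=dict, repr=False)

    def initial_state(self, t0: float = 0.0, **overrides: float) -> SystemState:
        """Build a SystemState from the preset's initial values.

        Values the preset leaves unset must be supplied via ``overrides``
        (keys M0, S0, P0, C0).
        """
        vals = {"M0": self.M0, "S0": self.S0, "P0": self.P0, "C0": self.C0}
        vals.update(overrides)
        missing = [key for key, val in vals.items() if val is None]
        if missing:
            raise DomainError(
                f"preset '{self.name}' leaves {missing} unset; pass them explicitly"
            )
        return SystemState(t=t0, M=vals["M0"], S=vals["S0"], P=vals["P0"], C=vals["C0"])


_PARAM_KEYS = ("i", "gamma", "v", "u", "r", "k", "theta", "mu", "eta", "g", "h")
_INIT_KEYS = ("M0", "S0", "P0", "C0")


def load_preset(name: str, **overrides: float) -> Preset:
    """Load a bundled preset ('table1' or 'table2'), optionally overriding values.

    ``overrides`` may set any parameter symbol or initial value; parameters
    the preset leaves unset (e.g. ``i`` and ``v`` in the case-study preset,
    which are estimated from data) must be supplied here before the returned
    preset's ``params`` can be built.
    """
    path = resources.files("caredyn.presets").joinpath(f"{name}.yaml")
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise KeyError(f"unknown preset '{name}' (expected 'table1' or 'table2')")
    unknown = set(overrides) - set(_PARAM_KEYS) - set(_INIT_KEYS)
    if unknown:
        raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
    merged = dict(raw)
    merged.update(overrides)
    missing = [key for key in _PARAM_KEYS if merged.get(key) is None]
    if missing:
        raise DomainError(
            f"preset '{name}' leaves parameter(s) {missing} unset; "
            "supply them as keyword overrides"
        )
    params = ModelParameters(**{key: float(merged[key]) for key in _PARAM_KEYS})
    inits = {
        key: (None if merged.get(key) is None else float(merged[key]))
        for key in _INIT_KEYS
    }
    return Preset(name=name, params=params, raw=raw, **inits)
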