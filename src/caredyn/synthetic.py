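"""Synthetic prevalence data with the statistical structure the fitting
stage assumes: an ODE-driven mean and mean-parameterised beta observation
noise.

The bundled case-study-like fixture reproduces the fixed parameter block of
the South Australian CAMHS configuration exactly and overlays illustrative
generating values for the estimated quantities (the engagement and
progression rates), so that end-to-end parameter-recovery tests run without
any external data.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, Tuple

import numpy as np

from .inference import SERIES_IDS, FittingSetup, PrevalenceSeries, model_prevalence
from .params import DomainError, ModelParameters, load_preset

__all__ = [
    "SyntheticSpec",
    "draw_observations",
    "generate_prevalence_series",
    "case_study_fixture",
]

# Illustrative generating rates; chosen so the fixture sits in a regime
# comparable to the case study (capacity slightly below the upper fold),
# and freely overridable.  They are not fitted values.
DEFAULT_I_TRUE = 0.06
DEFAULT_V_TRUE = 0.30
DEFAULT_ALPHA = 2000.0  # observation noise of a few percent, relative


@dataclass(frozen=True)
class SyntheticSpec:
    """Complete recipe for one synthetic two-series data set."""

    params: ModelParameters  # includes the generating i and v, plus g, h
    P0: float
    C0: float
    t0: float
    m0: float                # initial moderate prevalence M0/P0
    s0: float                # initial severe prevalence S0/P0
    alpha: Dict[str, float]  # concentration per series id
    times: np.ndarray        # observation times (calendar years)
    seed: int

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.seed is None:
            raise DomainError("seed is mandatory")
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("observation times must be strictly increasing")
        for sid, a in self.alpha.items():
            if a <= 0:
                raise DomainError(f"alpha[{sid!r}] must be > 0")
        if not (0 < self.m0 < 1 and 0 < self.s0 < 1 and self.m0 + self.s0 < 1):
            raise DomainError("initial prevalences must be proportions summing < 1")

    def setup(self) -> FittingSetup:
        return FittingSetup(
            base_params=self.params, P0=self.P0, C0=self.C0, t0=self.t0
        )

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["params"] = self.params.to_dict()
        payload["times"] = self.times.tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            payload = json.load(fh)
        payload["params"] = ModelParameters(**payload["params"])
        payload["times"] = np.asarray(payload["times"], dtype=float)
        return cls(**payload)


def draw_observations(
    m: np.ndarray, alpha: float, rng: np.random.Generator, size=None
) -> np.ndarray:
    """Observation noise around the model prevalence m:
    y ~ Beta(alpha, alpha (1 - m) / m), so E[y] = m."""
    m = np.asarray(m, dtype=float)
    if np.any((m <= 0) | (m >= 1)):
        raise DomainError("model prevalence must lie strictly in (0, 1)")
    if alpha <= 0:
        raise DomainError("alpha must be > 0")
    y = rng.beta(alpha, alpha * (1.0 - m) / m, size=size)
    # guard against underflow to exact 0/1 at extreme concentrations
    return np.clip(y, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))


def generate_prevalence_series(
    spec: SyntheticSpec,
) -> Tuple[PrevalenceSeries, PrevalenceSeries]:
    """Draw the (moderate, severe) series defined by ``spec``.

    Each observation is y ~ Beta(alpha_j, alpha_j (1 - m) / m) around the
    simulated prevalence m, so E[y] = m.  Identical specs give identical
    output.
    """
    m_model = model_prevalence(
        spec.params.i, spec.params.v, spec.m0, spec.s0, spec.setup(), spec.times
    )
    rng = np.random.default_rng(spec.seed)
    out = []
    for sid in SERIES_IDS:
        m = m_model[sid]
        if np.any((m <= 0) | (m >= 1)):
            raise DomainError(
                f"model prevalence for '{sid}' leaves (0,1); inconsistent spec"
            )
        y = draw_observations(m, spec.alpha[sid], rng)
        out.append(PrevalenceSeries(series_id=sid, times=spec.times, values=y))
    return tuple(out)


def case_study_fixture(
    seed: int,
    i_true: float = DEFAULT_I_TRUE,
    v_true: float = DEFAULT_V_TRUE,
    alpha: float = DEFAULT_ALPHA,
    n_times: int = 6,
) -> Tuple[SyntheticSpec, Tuple[PrevalenceSeries, PrevalenceSeries]]:
    """A ready-made case-study-like data set.

    The fixed parameter block (gamma, u, k, theta, r, mu, eta, g, h, P0, C0)
    is the bundled case-study preset, taken as given; the generating rates
    and initial prevalences are illustrative.  Observations are semiannual
    from the start of 2017.
    """
    preset = load_preset("table2", i=i_true, v=v_true)
    times = 2017.0 + 0.5 * np.arange(n_times)
    spec = SyntheticSpec(
        params=preset.params,
        P0=preset.P0,
        C0=preset.C0,
        t0=2017.0,
        m0=0.04024,
        s0=0.02941,
        alpha={sid: float(alpha) for sid in SERIES_IDS},
        times=times,
        seed=int(seed),
    )
    return spec, generate_prevalence_series(spec)
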