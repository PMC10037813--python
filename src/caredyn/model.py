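"""Flow equations, time derivatives, and trajectory simulation.

The two engaged stocks evolve as

    dM/dt = (1-gamma) i (P-S-M) - v M - u M - rho M - mu M
    dS/dt =  gamma    i (P-S-M) + v M - u S - rho S - eta mu S

where ``rho = r C / (k M + theta k S)`` is the per-capita treatment-dependent
recovery rate.  The population and capacity grow linearly, dP/dt = g and
dC/dt = h.

The treatment terms are singular where total demand ``k M + theta k S``
vanishes: every treatment quantity is defined as zero there (no one engaged,
no one treated).  Away from the origin the per-capita rate grows without
bound as stocks shrink, while the absolute treatment outflow,
``rho (M + S) = r C (M+S)/(k M + theta k S)``, stays bounded between
``r C / (theta k)`` and ``r C / k``.  When this bounded outflow exceeds the
inflow ``i (P-S-M)``, trajectories reach the neighbourhood of the origin in
finite time and stay there: the "no unmet need" operating state, in which
people are treated and recover essentially as fast as they engage.  The
integrator detects this absorption and freezes the stocks at the floor value
instead of chasing the singularity.
"""
from __future__ import annotations

from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import DomainError, FlowRates, ModelParameters, SystemState

__all__ = [
    "treatment_rates",
    "derivatives",
    "simulate",
    "Derivatives",
    "TreatmentRates",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    """Integrator failure; carries the failing time."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (at t={t_fail})")
        self.t_fail = t_fail


class TreatmentRates(NamedTuple):
    percap_rate: float       # rho, 1/year
    patients_treated: float  # persons/year
    demand: float            # services/year


class Derivatives(NamedTuple):
    dM: float
    dS: float
    dP: float
    dC: float
    flows: FlowRates


def treatment_rates(
    M: float, S: float, C: float, params: ModelParameters
) -> TreatmentRates:
    """Per-capita treatment-dependent recovery rate, throughput, and demand.

    Demand is ``k M + theta k S`` services/year.  The per-capita recovery
    rate is ``r C / demand`` and the number of people treated per year is
    ``C (M + S) / demand``; both are taken as 0 when demand is 0.
    """
    if M < 0 or S < 0 or C < 0:
        raise DomainError(f"negative input: M={M}, S={S}, C={C}")
    demand = params.k * M + params.theta * params.k * S
    if demand == 0.0:
        return TreatmentRates(0.0, 0.0, 0.0)
    return TreatmentRates(
        percap_rate=params.r * C / demand,
        patients_treated=C * (M + S) / demand,
        demand=demand,
    )


def derivatives(state: SystemState, params: ModelParameters) -> Derivatives:
    """Time derivatives of (M, S, P, C) and the underlying flows."""
    p = params
    M, S, P, C = state.M, state.S, state.P, state.C
    rho, treated, demand = treatment_rates(M, S, C, p)
    not_engaged = P - S - M
    # Treatment flows divide per flow (r C M / demand) rather than using
    # rho * M: near-empty systems make rho overflow while the flow stays finite.
    flows = FlowRates(
        inflow_M=(1.0 - p.gamma) * p.i * not_engaged,
        inflow_S=p.gamma * p.i * not_engaged,
        progression=p.v * M,
        spont_recovery_M=p.u * M,
        spont_recovery_S=p.u * S,
        treat_recovery_M=p.r * C * M / demand if demand > 0 else 0.0,
        treat_recovery_S=p.r * C * S / demand if demand > 0 else 0.0,
        mortality_M=p.mu * M,
        mortality_S=p.eta * p.mu * S,
        demand=demand,
        patients_treated=treated,
    )
    dM = (
        flows.inflow_M
        - flows.progression
        - flows.spont_recovery_M
        - flows.treat_recovery_M
        - flows.mortality_M
    )
    dS = (
        flows.inflow_S
        + flows.progression
        - flows.spont_recovery_S
        - flows.treat_recovery_S
        - flows.mortality_S
    )
    return Derivatives(dM=dM, dS=dS, dP=p.g, dC=p.h, flows=flows)


def _rhs(t: float, y: np.ndarray, p: ModelParameters) -> list:
    M = max(y[0], 0.0)
    S = max(y[1], 0.0)
    P, C = y[2], y[3]
    demand = p.k * M + p.theta * p.k * S
    if demand > 0.0:
        treat_M = p.r * C * M / demand
        treat_S = p.r * C * S / demand
    else:
        treat_M = treat_S = 0.0
    not_engaged = P - S - M
    dM = (1.0 - p.gamma) * p.i * not_engaged - (p.v + p.u + p.mu) * M - treat_M
    dS = p.gamma * p.i * not_engaged + p.v * M - (p.u + p.eta * p.mu) * S - treat_S
    return [dM, dS, p.g, p.h]


def _absorbing(M: float, S: float, P: float, C: float, p: ModelParameters) -> bool:
    # Near the origin the treatment outflow tends to r*C*((1-gamma)+theta*gamma)
    # ... more precisely, incoming demand is k*i*P*((1-gamma)+theta*gamma)
    # services/year; the origin absorbs when capacity covers it.
    return p.r * C > p.k * p.i * P * ((1.0 - p.gamma) + p.theta * p.gamma)


def simulate(
    initial: SystemState,
    params: ModelParameters,
    horizon: float,
    output_times: Optional[Sequence[float]] = None,
    rtol: float = 1e-8,
    atol: float = 1e-6,
    method: str = "LSODA",
    floor_fraction: float = 1e-7,
) -> pd.DataFrame:
    """Integrate the model from ``initial`` for ``horizon`` years.

    Returns a DataFrame with columns t, M, S, P, C, one row per output time
    (default: 201 evenly spaced times).  Stocks are clamped at 0 in the
    output.  If the trajectory is absorbed at the near-zero boundary (total
    engaged below ``floor_fraction * P`` while treatment throughput exceeds
    inflow), the stocks are held at the absorption values for the remaining
    output times while P and C continue their linear growth.
    """
    if horizon <= 0:
        raise DomainError(f"horizon must be > 0, got {horizon}")
    t0 = initial.t
    t1 = t0 + horizon
    if output_times is None:
        times = np.linspace(t0, t1, 201)
    else:
        times = np.asarray(output_times, dtype=float)
        if times.size == 0:
            raise DomainError("output_times is empty")
        if times.min() < t0 - 1e-12 or times.max() > t1 + 1e-12:
            raise DomainError("output_times outside [t0, t0 + horizon]")

    floor = floor_fraction * initial.P

    def near_zero(t, y, p):
        return y[0] + y[1] - floor

    near_zero.terminal = True
    near_zero.direction = -1.0

    y0 = [initial.M, initial.S, initial.P, initial.C]
    sol = solve_ivp(
        _rhs,
        (t0, t1),
        y0,
        method=method,
        t_eval=times,
        rtol=rtol,
        atol=atol,
        events=near_zero,
        args=(params,),
        dense_output=False,
    )
    if sol.status == -1:
        raise IntegrationError(sol.message, float(sol.t[-1]) if sol.t.size else t0)

    out_t = list(sol.t)
    cols = [list(sol.y[j]) for j in range(4)]
    if sol.status == 1:  # absorbed at the near-zero boundary
        te = float(sol.t_events[0][0])
        ye = sol.y_events[0][0]
        M_abs, S_abs = max(ye[0], 0.0), max(ye[1], 0.0)
        if not _absorbing(M_abs, S_abs, ye[2], ye[3], params):
            # A transient graze of the floor without absorption: extremely
            # unusual; report it rather than silently freezing.
            raise IntegrationError(
                "trajectory reached the near-zero floor while the boundary "
                "state is not absorbing; reduce floor_fraction",
                te,
            )
        for t_rem in times[times > te]:
            out_t.append(float(t_rem))
            cols[0].append(M_abs)
            cols[1].append(S_abs)
            cols[2].append(ye[2] + params.g * (t_rem - te))
            cols[3].append(ye[3] + params.h * (t_rem - te))

    frame = pd.DataFrame(
        {
            "t": out_t,
            "M": np.maximum(cols[0], 0.0),
            "S": np.maximum(cols[1], 0.0),
            "P": cols[2],
            "C": cols[3],
        }
    )
    return frame.reset_index(drop=True)
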