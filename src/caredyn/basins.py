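"""Basins of attraction, the critical initial severe fraction, and the
time taken to reach the low-unmet-need state.

In the bistable capacity window the saddle's stable manifold separates
initial conditions that relax to the high-unmet-need equilibrium from those
that collapse to the near-zero ("no unmet need") state.  Along a line of
constant total engaged stocks, M = (1-f) T and S = f T, the basins meet at
a critical initial severe fraction f*: starting with too many severe
patients ties up capacity (each requires theta times the services) and the
system climbs back to high unmet need.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .equilibria import Equilibrium, find_equilibria
from .model import _rhs
from .params import DomainError, ModelParameters, SystemState

__all__ = [
    "BasinResult",
    "classify_basin",
    "critical_severe_fraction",
    "time_to_low_state",
]

CONVERGENCE_FRACTION = 1e-4  # convergence distance as a fraction of P
DEFAULT_HORIZON = 500.0      # years; convergence can be slow near the saddle


@dataclass(frozen=True)
class BasinResult:
    initial: Tuple[float, float]
    attractor_index: int
    attractor: Equilibrium
    converged: bool
    time_to_converge: float


def _stable_attractors(
    params: ModelParameters, P: float, C: float
) -> List[Equilibrium]:
    return [e for e in find_equilibria(params, P, C) if e.stability == "stable"]


def _distances(M: float, S: float, attractors: List[Equilibrium]) -> np.ndarray:
    return np.array(
        [np.hypot(M - a.M_star, S - a.S_star) for a in attractors]
    )


def classify_basin(
    initial_M: float,
    initial_S: float,
    params: ModelParameters,
    P: float,
    C: float,
    horizon: float = DEFAULT_HORIZON,
    rtol: float = 1e-8,
    atol: float = 1e-6,
) -> BasinResult:
    """Integrate from (initial_M, initial_S) at fixed P, C until the state
    is within ``1e-4 P`` of a stable equilibrium (the near-zero boundary
    attractor counts, reached when M + S falls below the same distance).

    If the horizon is reached first the result is flagged unconverged and
    reports the closest attractor.
    """
    if initial_M < 0 or initial_S < 0 or initial_M + initial_S > P:
        raise DomainError("invalid initial stocks")
    if horizon <= 0:
        raise DomainError("horizon must be > 0")
    p = params.replace(g=0.0, h=0.0)
    attractors = _stable_attractors(p, P, C)
    if not attractors:
        raise DomainError("no stable equilibrium at this (params, P, C)")
    tolP = CONVERGENCE_FRACTION * P

    d0 = _distances(initial_M, initial_S, attractors)
    if d0.min() < tolP:
        j = int(d0.argmin())
        return BasinResult(
            initial=(initial_M, initial_S),
            attractor_index=j,
            attractor=attractors[j],
            converged=True,
            time_to_converge=0.0,
        )

    events = []
    for a in attractors:
        if a.boundary:
            def ev(t, y, p, a=a):
                return y[0] + y[1] - tolP
        else:
            def ev(t, y, p, a=a):
                return np.hypot(y[0] - a.M_star, y[1] - a.S_star) - tolP
        ev.terminal = True
        ev.direction = -1.0
        events.append(ev)

    sol = solve_ivp(
        _rhs,
        (0.0, horizon),
        [initial_M, initial_S, P, C],
        method="LSODA",
        rtol=rtol,
        atol=atol,
        events=events,
        args=(p,),
    )
    fired = [j for j, te in enumerate(sol.t_events) if te.size > 0]
    if fired:
        j = fired[int(np.argmin([sol.t_events[j][0] for j in fired]))]
        return BasinResult(
            initial=(initial_M, initial_S),
            attractor_index=j,
            attractor=attractors[j],
            converged=True,
            time_to_converge=float(sol.t_events[j][0]),
        )
    dT = _distances(float(sol.y[0, -1]), float(sol.y[1, -1]), attractors)
    j = int(dT.argmin())
    return BasinResult(
        initial=(initial_M, initial_S),
        attractor_index=j,
        attractor=attractors[j],
        converged=False,
        time_to_converge=float(horizon),
    )


def critical_severe_fraction(
    total_engaged: float,
    params: ModelParameters,
    P: float,
    C: float,
    tol: float = 1e-3,
    horizon: float = DEFAULT_HORIZON,
) -> Optional[float]:
    """Critical initial severe fraction f* along M=(1-f)T, S=fT.

    Bisects the basin classification over f in [0, 1]; returns None when the
    regime is monostable or both endpoints fall in the same basin (the
    constant-total line does not cross the separatrix).
    """
    if total_engaged <= 0 or total_engaged > P:
        raise DomainError("total_engaged must be in (0, P]")
    if not 0.0 < tol < 0.1:
        raise DomainError("tol must be in (0, 0.1)")
    if len(_stable_attractors(params.replace(g=0.0, h=0.0), P, C)) < 2:
        return None

    def label(f: float) -> int:
        res = classify_basin(
            (1.0 - f) * total_engaged, f * total_engaged, params, P, C, horizon
        )
        return res.attractor_index

    f_lo, f_hi = 0.0, 1.0
    lab_lo, lab_hi = label(f_lo), label(f_hi)
    if lab_lo == lab_hi:
        return None
    while f_hi - f_lo > tol:
        mid = 0.5 * (f_lo + f_hi)
        if label(mid) == lab_lo:
            f_lo = mid
        else:
            f_hi = mid
    return 0.5 * (f_lo + f_hi)


def time_to_low_state(
    initial: SystemState,
    params: ModelParameters,
    P: float,
    C: float,
    epsilon: float,
    horizon: float = DEFAULT_HORIZON,
    rtol: float = 1e-8,
    atol: float = 1e-6,
) -> Optional[float]:
    """First time at which total engaged stocks fall below ``epsilon * P``.

    Returns 0 if the start is already below the threshold, and None if the
    threshold is never reached within the horizon (e.g. the start lies in
    the high-unmet-need basin).  Larger capacities above the upper fold make
    this transition faster.
    """
    if not 0.0 < epsilon <= 0.01:
        raise DomainError("epsilon must be in (0, 0.01]")
    if initial.M + initial.S < epsilon * P:
        return 0.0
    p = params.replace(g=0.0, h=0.0)

    def ev(t, y, p):
        return y[0] + y[1] - epsilon * P

    ev.terminal = True
    ev.direction = -1.0
    sol = solve_ivp(
        _rhs,
        (0.0, horizon),
        [initial.M, initial.S, P, C],
        method="LSODA",
        rtol=rtol,
        atol=atol,
        events=ev,
        args=(p,),
    )
    if sol.t_events[0].size > 0:
        return float(sol.t_events[0][0])
    return None
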