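"""Steady states of the stock-flow model and their local stability.

With the population and capacity held fixed (g = h = 0), setting
dM/dt = dS/dt = 0 and writing ``rho = r C / (k M + theta k S)`` for the
per-capita treatment rate, the two balance equations reduce to explicit
expressions for the severe-to-mild ratio ``x = S/M`` and the stock ``M``:

    x(rho) = [gamma/(1-gamma) (v + u + mu + rho) + v] / (u + eta mu + rho)
    M(rho) = (1-gamma) i P / [(v + u + mu + rho) + (1-gamma) i (1 + x(rho))]

so interior equilibria are exactly the roots of the scalar consistency
equation

    g(rho) := rho * k * M(rho) * (1 + theta * x(rho)) = r * C,

where the left-hand side is the capacity that would sustain the per-capita
treatment rate ``rho``.  The curve g rises from 0, peaks, and decays to the
limit ``g_inf = k i P ((1-gamma) + theta gamma)`` — the services demand
generated per year by the engagement inflow alone.  Hence:

* ``r C < g_inf``: one interior equilibrium (high unmet need, stable);
* ``g_inf < r C < max g``: two interior equilibria (the high state and a
  saddle) plus an attracting boundary state at the origin, where treatment
  throughput exceeds the engagement inflow and people are treated as they
  engage ("no unmet need");
* ``r C > max g``: only the boundary state remains.

The boundary state is not an interior root (the treatment terms are
singular at the origin) but it is where trajectories settle, so it is
returned as a flagged ``Equilibrium`` with zero stocks; the two capacities
at which the count of equilibria changes are the saddle-node (fold) points.

The reduction is verified at run time: every root is checked against the
residual of :func:`caredyn.model.derivatives`.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq, minimize_scalar, root

from .model import derivatives
from .params import DomainError, ModelParameters, SystemState

__all__ = [
    "Equilibrium",
    "find_equilibria",
    "find_equilibria_newton",
    "stability_classify",
    "jacobian",
    "equilibria_frame",
]

STABILITY_TOL = 1e-10  # 1/year; marginal band for eigenvalue real parts

_LOG_RHO_LO, _LOG_RHO_HI = np.log(1e-9), np.log(1e12)


@dataclass(frozen=True)
class Equilibrium:
    """A steady state of (M, S) at fixed P and C.

    ``boundary`` marks the near-zero "no unmet need" state, which sits on
    the domain boundary where the treatment terms are singular: its stocks
    are zero, its residual is zero by convention (inflow is treated on
    arrival) and no Jacobian eigenvalues exist there (NaN).
    """

    M_star: float
    S_star: float
    residual_norm: float                  # persons/year
    eigenvalues: Tuple[complex, complex]  # 1/year
    stability: str                        # stable | unstable | marginal
    boundary: bool = False

    @property
    def total(self) -> float:
        return self.M_star + self.S_star


def _curve(params: ModelParameters, P: float):
    """Return x(rho), M(rho), g(rho) evaluators (vectorised over rho)."""
    p = params
    if p.gamma >= 1.0:
        raise DomainError("gamma must be < 1 for the equilibrium reduction")
    gg = p.gamma / (1.0 - p.gamma)
    loss_M = p.v + p.u + p.mu

    def parts(rho):
        x = (gg * (loss_M + rho) + p.v) / (p.u + p.eta * p.mu + rho)
        M = (1.0 - p.gamma) * p.i * P / ((loss_M + rho) + (1.0 - p.gamma) * p.i * (1.0 + x))
        return x, M

    def g(rho):
        x, M = parts(rho)
        return rho * p.k * M * (1.0 + p.theta * x)

    return parts, g


def boundary_inflow_demand(params: ModelParameters, P: float) -> float:
    """Services demand per year generated by the engagement inflow alone,
    ``k i P ((1-gamma) + theta gamma)`` — the large-rho limit of the
    consistency curve.  The near-zero boundary state is attracting iff
    ``r C`` exceeds this."""
    p = params
    return p.k * p.i * P * ((1.0 - p.gamma) + p.theta * p.gamma)


def _interior_roots(
    params: ModelParameters, P: float, C: float, n_grid: int
) -> List[float]:
    """Roots (in rho) of g(rho) = r C via log-grid scan with refined extrema."""
    _, g = _curve(params, P)
    target = params.r * C

    def G(logrho):
        return g(np.exp(logrho)) - target

    logr = np.linspace(_LOG_RHO_LO, _LOG_RHO_HI, n_grid)
    vals = g(np.exp(logr)) - target

    # Refine interior extrema so near-fold root pairs are not missed by the
    # grid: a fold is a tangency of g with the level r*C.
    knots = list(zip(logr, vals))
    dv = np.diff(vals)
    for j in np.where(np.sign(dv[:-1]) * np.sign(dv[1:]) < 0)[0]:
        lo, hi = logr[j], logr[j + 2]
        sign = -1.0 if dv[j] > 0 else 1.0  # minimise -G at a local max
        res = minimize_scalar(
            lambda lr: sign * G(lr), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-13},
        )
        knots.append((float(res.x), float(G(res.x))))
    knots.sort(key=lambda kv: kv[0])

    roots = []
    for (la, va), (lb, vb) in zip(knots[:-1], knots[1:]):
        if not (np.isfinite(va) and np.isfinite(vb)):
            continue
        if va == 0.0:
            roots.append(np.exp(la))
        elif va * vb < 0.0:
            lr = brentq(G, la, lb, xtol=1e-14, rtol=8.9e-16)
            roots.append(float(np.exp(lr)))
    return roots


def jacobian(
    M: float, S: float, params: ModelParameters, P: float, C: float
) -> np.ndarray:
    """Analytic Jacobian of (dM/dt, dS/dt) with respect to (M, S)."""
    p = params
    D = p.k * M + p.theta * p.k * S
    if D <= 0:
        raise DomainError("Jacobian undefined where demand is zero")
    rC = p.r * C
    J11 = -(1.0 - p.gamma) * p.i - (p.v + p.u + p.mu) - rC * p.theta * p.k * S / D**2
    J12 = -(1.0 - p.gamma) * p.i + rC * p.theta * p.k * M / D**2
    J21 = -p.gamma * p.i + p.v + rC * p.k * S / D**2
    J22 = -p.gamma * p.i - (p.u + p.eta * p.mu) - rC * p.k * M / D**2
    return np.array([[J11, J12], [J21, J22]])


def _residual(
    M: float, S: float, params: ModelParameters, P: float, C: float
) -> float:
    d = derivatives(SystemState(t=0.0, M=M, S=S, P=P, C=C), params)
    return float(np.hypot(d.dM, d.dS))


def stability_classify(
    eq_location: Tuple[float, float],
    params: ModelParameters,
    P: float,
    C: float,
    tol: float = STABILITY_TOL,
) -> Equilibrium:
    """Classify an equilibrium point by the eigenvalues of its Jacobian.

    The point must satisfy the steady-state equations to within
    ``1e-6 * P`` persons/year, and demand must be positive there.
    """
    M, S = eq_location
    res = _residual(M, S, params, P, C)
    if res > 1e-6 * P:
        raise DomainError(
            f"({M}, {S}) is not an equilibrium: residual {res:.3g} persons/year"
        )
    eig = np.linalg.eigvals(jacobian(M, S, params, P, C))
    re = np.real(eig)
    if np.all(re < -tol):
        label = "stable"
    elif np.any(re > tol):
        label = "unstable"
    else:
        label = "marginal"
    return Equilibrium(
        M_star=float(M),
        S_star=float(S),
        residual_norm=res,
        eigenvalues=(complex(eig[0]), complex(eig[1])),
        stability=label,
        boundary=False,
    )


def find_equilibria(
    params: ModelParameters,
    P: float,
    C: float,
    n_grid: int = 10_000,
    include_boundary: bool = True,
) -> List[Equilibrium]:
    """All equilibria of the model at fixed P and C, ordered by total stocks.

    Interior roots are found by scanning the scalar consistency equation in
    the per-capita treatment rate (see module docstring) and polishing each
    bracket with Brent's method; each is verified against the residual of
    the flow derivatives and classified by its Jacobian eigenvalues.  When
    the near-zero boundary state is attracting it is appended as a flagged
    boundary equilibrium.
    """
    if P <= 0 or C < 0:
        raise DomainError(f"require P > 0 and C >= 0, got P={P}, C={C}")
    parts, _ = _curve(params, P)
    eqs: List[Equilibrium] = []

    if C == 0.0:
        # No treatment: the balance equations are linear with a unique root.
        x, M = parts(0.0)
        eqs.append(stability_classify((M, x * M), params, P, C))
    else:
        locations = []
        for rho in _interior_roots(params, P, C, n_grid):
            x, M = parts(rho)
            locations.append((M, x * M))
        # Deduplicate within 1e-6 * P in the (M, S) plane.
        kept: List[Tuple[float, float]] = []
        for loc in sorted(locations, key=lambda ms: ms[0] + ms[1]):
            if all(np.hypot(loc[0] - q[0], loc[1] - q[1]) > 1e-6 * P for q in kept):
                kept.append(loc)
        for M, S in kept:
            if M > 0 and S >= 0 and M + S < P:
                eqs.append(stability_classify((M, S), params, P, C))

    if include_boundary and params.r * C > boundary_inflow_demand(params, P):
        eqs.append(
            Equilibrium(
                M_star=0.0,
                S_star=0.0,
                residual_norm=0.0,
                eigenvalues=(complex(np.nan), complex(np.nan)),
                stability="stable",
                boundary=True,
            )
        )
    return sorted(eqs, key=lambda e: e.total)


def find_equilibria_newton(
    params: ModelParameters,
    P: float,
    C: float,
    n_starts: int = 200,
    seed: int = 0,
) -> List[Tuple[float, float]]:
    """Interior equilibria by naive multi-start Newton on the 2-D system.

    An independent cross-check of the scalar-reduction solver; returns
    deduplicated (M*, S*) locations.
    """
    rng = np.random.default_rng(seed)

    def fun(ms):
        M, S = ms
        if M <= 0 or S < 0 or M + S >= P:
            return [1e12, 1e12]
        d = derivatives(SystemState(t=0.0, M=M, S=S, P=P, C=C), params)
        return [d.dM, d.dS]

    found: List[Tuple[float, float]] = []
    # Log-uniform starts cover both the near-zero and the high branch.
    for _ in range(n_starts):
        M0 = 10.0 ** rng.uniform(0, np.log10(P))
        S0 = 10.0 ** rng.uniform(0, np.log10(P))
        if M0 + S0 >= P:
            continue
        sol = root(fun, [M0, S0], method="hybr", tol=1e-12)
        if not sol.success:
            continue
        M, S = sol.x
        if not (M > 0 and S >= 0 and M + S < P):
            continue
        if _residual(M, S, params, P, C) > 1e-6 * P:
            continue
        if all(np.hypot(M - q[0], S - q[1]) > 1e-6 * P for q in found):
            found.append((float(M), float(S)))
    return sorted(found, key=lambda ms: ms[0] + ms[1])


def equilibria_frame(eqs: List[Equilibrium], C: float):
    """Tabulate equilibria as a DataFrame (columns as in the text output)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "C": C,
            "M_star": [e.M_star for e in eqs],
            "S_star": [e.S_star for e in eqs],
            "eig1_re": [e.eigenvalues[0].real for e in eqs],
            "eig1_im": [e.eigenvalues[0].imag for e in eqs],
            "eig2_re": [e.eigenvalues[1].real for e in eqs],
            "eig2_im": [e.eigenvalues[1].imag for e in eqs],
            "stability": [e.stability for e in eqs],
            "boundary": [e.boundary for e in eqs],
        }
    )
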