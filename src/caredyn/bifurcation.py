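"""Capacity sweeps, saddle-node (fold) location, and parameter sensitivity.

As services capacity C increases, a stable high-unmet-need equilibrium and
a saddle appear alongside the attracting near-zero state between two fold
capacities: the lower fold b' (the smallest C at which the near-zero branch
exists) and the upper fold b, also written C_b (the largest C at which the
high-unmet-need pair survives).  Between them the system is bistable and the
capacity required to trigger the collapse of unmet need (b) exceeds the
capacity required to sustain it (b') — hysteresis.

Folds are located by bisection on the number of equilibria, which is robust
for this cheap two-dimensional system (no continuation machinery needed).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .equilibria import Equilibrium, find_equilibria
from .params import DomainError, ModelParameters

__all__ = [
    "BifurcationDiagram",
    "sweep_capacity",
    "locate_folds",
    "sensitivity_sweep",
    "SENSITIVITY_PARAMS",
]

SENSITIVITY_PARAMS = ("i", "v", "gamma", "r", "theta")

DEFAULT_BRACKET = (0.0, 2e6)  # services/year; scale-dependent (fits P ~ 1e6)


@dataclass(frozen=True)
class BifurcationDiagram:
    """Equilibria over a capacity grid plus located fold capacities."""

    capacity_grid: np.ndarray
    equilibria_by_capacity: List[List[Equilibrium]]
    fold_lower: Optional[float]  # b'
    fold_upper: Optional[float]  # b, C_b

    def counts(self) -> np.ndarray:
        return np.array([len(eqs) for eqs in self.equilibria_by_capacity])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for C, eqs in zip(self.capacity_grid, self.equilibria_by_capacity):
            for branch_id, eq in enumerate(eqs):
                rows.append(
                    {
                        "C": C,
                        "branch_id": branch_id,
                        "M_star": eq.M_star,
                        "S_star": eq.S_star,
                        "stability": eq.stability,
                        "boundary": eq.boundary,
                    }
                )
        return pd.DataFrame(rows)

    def fold_summary(self) -> dict:
        return {"fold_lower": self.fold_lower, "fold_upper": self.fold_upper}


def _count(params: ModelParameters, P: float, C: float, n_grid: int = 4000) -> int:
    return len(find_equilibria(params, P, C, n_grid=n_grid))


def _bisect_edge(
    params: ModelParameters,
    P: float,
    C_single: float,
    C_multi: float,
    tol: float,
) -> float:
    """Bisect between a single-equilibrium capacity and a multi-equilibrium
    capacity; returns the transition point (the side with >1 equilibria)."""
    while abs(C_multi - C_single) > tol:
        mid = 0.5 * (C_single + C_multi)
        if _count(params, P, mid) > 1:
            C_multi = mid
        else:
            C_single = mid
    return C_multi


def locate_folds(
    params: ModelParameters,
    P: float,
    bracket: Tuple[float, float] = DEFAULT_BRACKET,
    tol: float = 1.0,
    n_scan: int = 128,
) -> Tuple[Optional[float], Optional[float]]:
    """Locate the two fold capacities by bisection on the equilibrium count.

    Returns ``(fold_lower, fold_upper)``; a fold is ``None`` when the count
    never changes inside the bracket on that side (no bistability, or the
    bracket does not span the fold).
    """
    if tol <= 0:
        raise DomainError(f"tol must be > 0, got {tol}")
    C_lo, C_hi = bracket
    if not 0 <= C_lo < C_hi:
        raise DomainError(f"invalid bracket {bracket}")
    grid = np.linspace(C_lo, C_hi, n_scan)
    multi = np.array([_count(params, P, C) > 1 for C in grid])
    if not multi.any():
        return None, None
    idx = np.where(multi)[0]
    fold_lower = None
    fold_upper = None
    if idx[0] > 0:
        fold_lower = _bisect_edge(params, P, grid[idx[0] - 1], grid[idx[0]], tol)
    if idx[-1] < n_scan - 1:
        fold_upper = _bisect_edge(params, P, grid[idx[-1] + 1], grid[idx[-1]], tol)
    return fold_lower, fold_upper


def sweep_capacity(
    params: ModelParameters,
    P: float,
    C_grid: Sequence[float],
    fold_tol: float = 1.0,
) -> BifurcationDiagram:
    """Equilibria at every capacity in ``C_grid`` plus fold refinement.

    ``C_grid`` must be sorted ascending.  Folds are refined by bisection
    inside the grid intervals where the equilibrium count changes, and are
    absent when it never does.
    """
    C_grid = np.asarray(C_grid, dtype=float)
    if C_grid.size == 0:
        raise DomainError("empty capacity grid")
    if np.any(np.diff(C_grid) <= 0) or C_grid[0] < 0:
        raise DomainError("capacity grid must be sorted ascending and nonnegative")
    eqs_by_C = [find_equilibria(params, P, C) for C in C_grid]
    multi = np.array([len(eqs) > 1 for eqs in eqs_by_C])
    fold_lower = fold_upper = None
    if multi.any():
        idx = np.where(multi)[0]
        if idx[0] > 0:
            fold_lower = _bisect_edge(
                params, P, C_grid[idx[0] - 1], C_grid[idx[0]], fold_tol
            )
        if idx[-1] < C_grid.size - 1:
            fold_upper = _bisect_edge(
                params, P, C_grid[idx[-1] + 1], C_grid[idx[-1]], fold_tol
            )
    return BifurcationDiagram(
        capacity_grid=C_grid,
        equilibria_by_capacity=eqs_by_C,
        fold_lower=fold_lower,
        fold_upper=fold_upper,
    )


def sensitivity_sweep(
    params: ModelParameters,
    P: float,
    focal: str,
    values: Sequence[float],
    bracket: Tuple[float, float] = DEFAULT_BRACKET,
    tol: float = 1.0,
) -> pd.DataFrame:
    """Fold capacities as one focal parameter varies, all others fixed.

    ``focal`` must be one of ``i``, ``v``, ``gamma``, ``r``, ``theta``.
    Returns a DataFrame with one row per focal value; fold columns are NaN
    where bistability is disabled.
    """
    if focal not in SENSITIVITY_PARAMS:
        raise DomainError(
            f"unknown focal parameter '{focal}'; expected one of {SENSITIVITY_PARAMS}"
        )
    rows = []
    for value in values:
        p = params.replace(**{focal: float(value)})
        lo, hi = locate_folds(p, P, bracket=bracket, tol=tol)
        rows.append(
            {
                "focal": focal,
                "value": float(value),
                "fold_lower": np.nan if lo is None else lo,
                "fold_upper": np.nan if hi is None else hi,
                "bistable": lo is not None or hi is not None,
            }
        )
    return pd.DataFrame(rows)
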