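"""Bayesian calibration of the engagement and progression rates to
prevalence time series.

The free parameter vector is phi = (i, v, m0, s0): the per-capita services
engagement rate, the per-capita disease progression rate, and the initial
moderate and severe prevalences (M0/P0 and S0/P0).  Observed prevalences
y_j(t) are modelled as beta-distributed around the simulated model
prevalence m_j(t, phi) with a mean parameterisation,

    y_j(t) | phi, alpha_j  ~  Beta(alpha_j, alpha_j (1 - m_j) / m_j),

whose mean is exactly m_j and whose concentration alpha_j sets the
observation noise.  Observations are independent given phi, so the joint
log likelihood is the sum over series and time points.  Priors are
truncated normals (an upper-truncated half-normal for each alpha_j when the
concentrations are estimated rather than fixed).

Sampling uses an affine-invariant ensemble sampler; the target density, not
the sampler brand, is what matters, and convergence is diagnosed with
split-chain R-hat across walkers.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize
from scipy.special import betaln
from scipy.stats import norm, truncnorm

from .bifurcation import DEFAULT_BRACKET, BifurcationDiagram, locate_folds, sweep_capacity
from .model import _rhs
from .params import DomainError, ModelParameters, load_preset

logger = logging.getLogger(__name__)

__all__ = [
    "PrevalenceSeries",
    "TruncatedNormal",
    "PriorSpec",
    "FittingSetup",
    "PosteriorDraws",
    "PosteriorBifurcation",
    "beta_loglikelihood",
    "model_prevalence",
    "log_posterior",
    "sample_posterior",
    "posterior_bifurcation",
    "read_series",
    "write_series",
]

SERIES_IDS = ("moderate", "severe")


@dataclass(frozen=True)
class PrevalenceSeries:
    """One observed (or synthetic) prevalence time series."""

    series_id: str
    times: np.ndarray   # calendar years, strictly increasing
    values: np.ndarray  # proportions strictly inside (0, 1)

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or times.shape != values.shape:
            raise DomainError("times and values must be 1-D and equal length")
        if times.size and np.any(np.diff(times) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any((values <= 0) | (values >= 1)):
            raise DomainError("prevalence values must lie strictly in (0, 1)")


def read_series(path) -> Dict[str, PrevalenceSeries]:
    """Read prevalence series from delimited text (series_id, time, value)."""
    table = pd.read_csv(path)
    out = {}
    for sid, grp in table.groupby("series_id"):
        grp = grp.sort_values("time")
        out[str(sid)] = PrevalenceSeries(
            series_id=str(sid),
            times=grp["time"].to_numpy(),
            values=grp["value"].to_numpy(),
        )
    return out


def write_series(series: Iterable[PrevalenceSeries], path) -> None:
    frames = [
        pd.DataFrame({"series_id": s.series_id, "time": s.times, "value": s.values})
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


@dataclass(frozen=True)
class TruncatedNormal:
    """normal(loc, scale) truncated to [lower, upper]; scale is an SD."""

    loc: float
    scale: float
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self):
        if self.scale <= 0:
            raise DomainError("scale must be > 0")
        if not self.lower < self.upper:
            raise DomainError("require lower < upper")
        # Precompute the log normalising constant (truncation mass).
        a = (self.lower - self.loc) / self.scale
        b = (self.upper - self.loc) / self.scale
        mass = norm.cdf(b) - norm.cdf(a)
        object.__setattr__(
            self,
            "_log_norm",
            -0.5 * np.log(2.0 * np.pi) - np.log(self.scale) - np.log(mass),
        )

    def _frozen(self):
        a = (self.lower - self.loc) / self.scale
        b = (self.upper - self.loc) / self.scale
        return truncnorm(a, b, loc=self.loc, scale=self.scale)

    def logpdf(self, x: float) -> float:
        if not self.lower <= x <= self.upper:
            return -np.inf
        z = (x - self.loc) / self.scale
        return float(-0.5 * z * z + self._log_norm)

    def rvs(self, rng: np.random.Generator, size=None):
        return self._frozen().rvs(size=size, random_state=rng)

    def ppf(self, q):
        return self._frozen().ppf(q)


@dataclass(frozen=True)
class PriorSpec:
    """Priors for phi and for the beta concentrations.

    ``alpha_fixed`` maps series id -> fixed concentration; when it is None
    each alpha_j is estimated under ``alpha_prior`` (a half-normal on the
    concentration scale by default).
    """

    i: TruncatedNormal
    v: TruncatedNormal
    m0: TruncatedNormal
    s0: TruncatedNormal
    alpha_prior: Optional[TruncatedNormal] = None
    alpha_fixed: Optional[Dict[str, float]] = None

    def __post_init__(self):
        if (self.alpha_prior is None) == (self.alpha_fixed is None):
            raise DomainError("specify exactly one of alpha_prior / alpha_fixed")

    @property
    def estimate_alpha(self) -> bool:
        return self.alpha_fixed is None

    @classmethod
    def table2(
        cls,
        alpha_scale: float = 1e4,
        alpha_fixed: Optional[Dict[str, float]] = None,
    ) -> "PriorSpec":
        """The case-study priors: half-normal(0.1) rates, tight truncated
        normals on the initial prevalences."""
        kwargs = dict(
            i=TruncatedNormal(0.0, 0.1, lower=0.0),
            v=TruncatedNormal(0.0, 0.1, lower=0.0),
            m0=TruncatedNormal(0.04024, 0.001006, lower=0.0, upper=1.0),
            s0=TruncatedNormal(0.02941, 0.0007352, lower=0.0, upper=1.0),
        )
        if alpha_fixed is not None:
            return cls(alpha_fixed=dict(alpha_fixed), **kwargs)
        return cls(alpha_prior=TruncatedNormal(0.0, alpha_scale, lower=0.0), **kwargs)

    def param_names(self, series_ids: Sequence[str] = SERIES_IDS) -> Tuple[str, ...]:
        names = ["i", "v", "m0", "s0"]
        if self.estimate_alpha:
            names += [f"alpha_{sid}" for sid in series_ids]
        return tuple(names)

    def log_prior(self, phi: np.ndarray, series_ids: Sequence[str] = SERIES_IDS) -> float:
        lp = (
            self.i.logpdf(phi[0])
            + self.v.logpdf(phi[1])
            + self.m0.logpdf(phi[2])
            + self.s0.logpdf(phi[3])
        )
        if self.estimate_alpha:
            for a in phi[4 : 4 + len(series_ids)]:
                if a <= 0:
                    return -np.inf
                lp += self.alpha_prior.logpdf(a)
        return lp

    def sample(self, rng: np.random.Generator, series_ids: Sequence[str] = SERIES_IDS):
        phi = [
            self.i.rvs(rng),
            self.v.rvs(rng),
            self.m0.rvs(rng),
            self.s0.rvs(rng),
        ]
        if self.estimate_alpha:
            phi += [float(self.alpha_prior.rvs(rng)) for _ in series_ids]
        return np.array(phi, dtype=float)


@dataclass(frozen=True)
class FittingSetup:
    """Everything held fixed during fitting: the non-phi model parameters,
    the initial population and capacity, and the calendar start time."""

    base_params: ModelParameters
    P0: float
    C0: float
    t0: float = 2017.0

    @classmethod
    def table2(cls, t0: float = 2017.0) -> "FittingSetup":
        preset = load_preset("table2", i=0.0, v=0.0)
        return cls(
            base_params=preset.params, P0=preset.P0, C0=preset.C0, t0=t0
        )


def beta_loglikelihood(y: float, m: float, alpha: float) -> float:
    """Log density of the mean-parameterised beta observation model.

    First shape alpha, second shape alpha (1 - m) / m, so the mean is m.
    """
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    if np.any((y <= 0) | (y >= 1)) or np.any((m <= 0) | (m >= 1)):
        raise DomainError("y and m must lie strictly in (0, 1)")
    if alpha <= 0:
        raise DomainError("alpha must be > 0")
    b = alpha * (1.0 - m) / m
    out = (alpha - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y) - betaln(alpha, b)
    return float(out) if out.ndim == 0 else out


def model_prevalence(
    i: float,
    v: float,
    m0: float,
    s0: float,
    setup: FittingSetup,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-6,
) -> Dict[str, np.ndarray]:
    """Simulated prevalences {moderate: M/P, severe: S/P} at calendar times.

    The run starts at ``setup.t0`` from stocks (m0 P0, s0 P0) with the
    population and capacity growing at the fixed rates g and h.
    """
    times = np.asarray(times, dtype=float)
    if times.size and times.min() < setup.t0 - 1e-9:
        raise DomainError("observation times precede the initial time t0")
    p = setup.base_params.replace(i=float(i), v=float(v))
    t1 = max(float(times.max()), setup.t0) if times.size else setup.t0
    if t1 == setup.t0:
        return {"moderate": np.full_like(times, m0), "severe": np.full_like(times, s0)}

    # P and C evolve linearly, so only (M, S) need integrating.
    t0_, P0, C0 = setup.t0, setup.P0, setup.C0
    kk, thk = p.k, p.theta * p.k
    loss_M0 = p.v + p.u + p.mu
    loss_S0 = p.u + p.eta * p.mu
    gi, gi1 = p.gamma * p.i, (1.0 - p.gamma) * p.i

    def rhs(t, y):
        M, S = y
        P = P0 + p.g * (t - t0_)
        C = C0 + p.h * (t - t0_)
        dem = kk * M + thk * S
        rho = p.r * C / dem if dem > 0.0 else 0.0
        free = P - S - M
        return (gi1 * free - (loss_M0 + rho) * M,
                gi * free + p.v * M - (loss_S0 + rho) * S)

    sol = solve_ivp(
        rhs,
        (t0_, t1),
        [m0 * setup.P0, s0 * setup.P0],
        method="RK45",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"prevalence simulation failed: {sol.message}")
    P = P0 + p.g * (sol.t - t0_)
    return {"moderate": sol.y[0] / P, "severe": sol.y[1] / P}


def log_posterior(
    phi: np.ndarray,
    data: Sequence[PrevalenceSeries],
    priors: PriorSpec,
    setup: FittingSetup,
) -> float:
    """Log posterior density of phi (unnormalised).

    Outside the truncation bounds, or where the simulation fails or leaves
    (0, 1), the density is -inf (the region is simply rejected).
    """
    phi = np.asarray(phi, dtype=float)
    data = list(data)
    series_ids = tuple(s.series_id for s in data) or SERIES_IDS
    lp = priors.log_prior(phi, series_ids)
    if not np.isfinite(lp):
        return -np.inf
    if not data:
        return lp
    i, v, m0, s0 = phi[:4]
    if m0 <= 0 or s0 <= 0 or m0 + s0 >= 1:
        return -np.inf
    all_times = np.unique(np.concatenate([s.times for s in data]))
    try:
        m_model = model_prevalence(i, v, m0, s0, setup, all_times)
    except Exception as exc:  # failed simulation == rejected region
        logger.warning("simulation failed at phi=%s: %s", phi, exc)
        return -np.inf
    for j, s in enumerate(data):
        if priors.estimate_alpha:
            alpha = phi[4 + j]
        else:
            alpha = priors.alpha_fixed[s.series_id]
        m = m_model[s.series_id][np.searchsorted(all_times, s.times)]
        if np.any((m <= 0) | (m >= 1)):
            return -np.inf
        lp += float(np.sum(beta_loglikelihood(s.values, m, alpha)))
    return lp


@dataclass
class PosteriorDraws:
    """Post-warmup MCMC draws with summaries and convergence diagnostics."""

    chain: np.ndarray            # (n_steps, n_walkers, ndim)
    names: Tuple[str, ...]
    rhat: Dict[str, float]
    acceptance: float
    converged: bool = field(default=False)

    def to_frame(self) -> pd.DataFrame:
        flat = self.chain.reshape(-1, self.chain.shape[-1])
        return pd.DataFrame(flat, columns=list(self.names))

    def quantile(self, name: str, q) -> np.ndarray:
        j = self.names.index(name)
        return np.quantile(self.chain[:, :, j], q)

    def summary(self) -> Dict[str, Dict[str, float]]:
        out = {}
        for j, name in enumerate(self.names):
            x = self.chain[:, :, j].ravel()
            out[name] = {
                "median": float(np.median(x)),
                "q2.5": float(np.quantile(x, 0.025)),
                "q97.5": float(np.quantile(x, 0.975)),
            }
        return out


def sample_posterior(
    data: Sequence[PrevalenceSeries],
    priors: PriorSpec,
    setup: FittingSetup,
    seed: int,
    n_walkers: int = 32,
    n_steps: int = 300,
    n_warmup: int = 400,
    rhat_threshold: float = 1.01,
) -> PosteriorDraws:
    """Draw from the posterior with an affine-invariant ensemble sampler.

    ``seed`` is mandatory; identical inputs give identical draws.  An
    unconverged run (any split R-hat above ``rhat_threshold``) is returned
    with ``converged=False`` and a logged warning, never silently.
    """
    if seed is None:
        raise DomainError("seed is mandatory for reproducibility")
    data = list(data)
    series_ids = tuple(s.series_id for s in data) or SERIES_IDS
    names = priors.param_names(series_ids)
    ndim = len(names)
    if n_walkers < 2 * ndim:
        raise DomainError(f"need at least {2 * ndim} walkers for {ndim} parameters")
    rng = np.random.default_rng(seed)

    # Walkers start in a small ball around a cheap posterior-mode estimate
    # (best of a handful of prior draws, polished by Nelder-Mead); this
    # removes the long coalescence transient of prior-dispersed ensembles.
    candidates = []
    attempts = 0
    while len(candidates) < 32 and attempts < 32_000:
        phi = priors.sample(rng, series_ids)
        lp = log_posterior(phi, data, priors, setup)
        if np.isfinite(lp):
            candidates.append((lp, phi))
        attempts += 1
    if not candidates:
        raise RuntimeError("could not initialise walkers from the prior")
    if not data:
        # Prior-only target: a prior-dispersed ensemble is already correct.
        p0 = []
        while len(p0) < n_walkers:
            phi = priors.sample(rng, series_ids)
            if np.isfinite(priors.log_prior(phi, series_ids)):
                p0.append(phi)
        return _run_ensemble(
            np.array(p0), data, priors, setup, names, rng,
            n_walkers, n_steps, n_warmup, rhat_threshold,
        )
    best = max(candidates, key=lambda c: c[0])[1]
    if data:
        opt = minimize(
            lambda q: -log_posterior(q, data, priors, setup),
            best,
            method="Nelder-Mead",
            options={"maxfev": 400, "xatol": 1e-8, "fatol": 1e-6},
        )
        if np.isfinite(opt.fun):
            best = opt.x
    scales = np.abs(best) * 1e-3 + 1e-8
    p0 = []
    attempts = 0
    while len(p0) < n_walkers:
        phi = best + scales * rng.standard_normal(ndim)
        if np.isfinite(log_posterior(phi, data, priors, setup)):
            p0.append(phi)
        attempts += 1
        if attempts > 1000 * n_walkers:
            raise RuntimeError("could not initialise the walker ensemble")

    return _run_ensemble(
        np.array(p0), data, priors, setup, names, rng,
        n_walkers, n_steps, n_warmup, rhat_threshold,
    )


def _run_ensemble(
    p0, data, priors, setup, names, rng, n_walkers, n_steps, n_warmup, rhat_threshold
) -> PosteriorDraws:
    sampler = emcee.EnsembleSampler(
        n_walkers, p0.shape[1], log_posterior, args=(data, priors, setup)
    )
    sampler.random_state = np.random.RandomState(
        int(rng.integers(0, 2**31 - 1))
    ).get_state()
    sampler.run_mcmc(p0, n_warmup + n_steps, progress=False)
    chain = sampler.get_chain(discard=n_warmup)  # (n_steps, n_walkers, ndim)

    rhat = {}
    for j, name in enumerate(names):
        rhat[name] = float(az.rhat(chain[:, :, j].T))
    converged = all(np.isfinite(r) and r < rhat_threshold for r in rhat.values())
    if not converged:
        logger.warning("MCMC not converged: R-hat %s", rhat)
    return PosteriorDraws(
        chain=chain,
        names=names,
        rhat=rhat,
        acceptance=float(np.mean(sampler.acceptance_fraction)),
        converged=converged,
    )


@dataclass(frozen=True)
class PosteriorBifurcation:
    """Fold points (and optionally full diagrams) pushed forward through
    the posterior."""

    per_draw: pd.DataFrame            # columns i, v, fold_lower, fold_upper
    median_phi: Dict[str, float]
    median_folds: Tuple[Optional[float], Optional[float]]
    diagrams: List[BifurcationDiagram]


def posterior_bifurcation(
    draws: PosteriorDraws,
    n_subsample: int,
    seed: int,
    base_params: ModelParameters,
    P: float,
    C_grid: Optional[Sequence[float]] = None,
    bracket: Tuple[float, float] = (0.0, 5e5),
    fold_tol: float = 1.0,
) -> PosteriorBifurcation:
    """Equilibrium analysis for a posterior subsample of (i, v).

    For each sampled phi the non-phi parameters stay fixed (and g = h = 0,
    the equilibrium-analysis convention); folds are located per draw and at
    the posterior-median phi.
    """
    flat = draws.to_frame()
    if n_subsample > len(flat):
        raise DomainError("n_subsample exceeds the number of draws")
    rng = np.random.default_rng(seed)
    rows = flat.iloc[rng.choice(len(flat), size=n_subsample, replace=False)]
    analysis_params = base_params.replace(g=0.0, h=0.0)

    records = []
    diagrams = []
    for _, row in rows.iterrows():
        p = analysis_params.replace(i=float(row["i"]), v=float(row["v"]))
        lo, hi = locate_folds(p, P, bracket=bracket, tol=fold_tol)
        records.append(
            {
                "i": float(row["i"]),
                "v": float(row["v"]),
                "fold_lower": np.nan if lo is None else lo,
                "fold_upper": np.nan if hi is None else hi,
            }
        )
        if C_grid is not None:
            diagrams.append(sweep_capacity(p, P, C_grid))

    med_i = float(np.median(flat["i"]))
    med_v = float(np.median(flat["v"]))
    p_med = analysis_params.replace(i=med_i, v=med_v)
    median_folds = locate_folds(p_med, P, bracket=bracket, tol=fold_tol)
    return PosteriorBifurcation(
        per_draw=pd.DataFrame(records),
        median_phi={"i": med_i, "v": med_v},
        median_folds=median_folds,
        diagrams=diagrams,
    )
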