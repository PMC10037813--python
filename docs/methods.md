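# Methods

## The model

`caredyn` implements a deterministic stock-flow (system-dynamics) model of
the interaction between specialised mental-health services capacity and
disease progression. Two stocks are tracked: people with mild/moderate
disorders (`M`) and people with severe disorders (`S`) who have engaged
with specialised services, inside a total population `P` served by a
capacity of `C` services per year:

    dM/dt = (1−γ) i (P−S−M) − v M − u M − ρ M − μ M
    dS/dt =  γ    i (P−S−M) + v M − u S − ρ S − η μ S
    dP/dt = g
    dC/dt = h

with the per-capita treatment-dependent recovery rate

    ρ = r C / (k M + θ k S).

People engage with services at per-capita rate `i` (a fraction `γ` already
severe), progress from mild/moderate to severe at rate `v`, recover
spontaneously (or age out of the cohort) at rate `u`, and die at rates `μ`
and `ημ`. Treating a mild/moderate patient takes `k` services; a severe
patient takes `θk` (`θ ≥ 1`). Total demand is `kM + θkS` services/year;
a proportion `r` of treated patients recover. Because severe patients
consume more services per head, rising severity crowds out treatment,
which raises progression, which raises severity — the reinforcing loop
responsible for everything interesting below.

### Parameters

| symbol | meaning | unit | generic preset | case-study preset |
|---|---|---|---|---|
| i | services engagement rate | 1/yr | 0.05496 | estimated |
| γ | proportion severe at first engagement | – | 0 | 0.03468 |
| v | disease progression rate | 1/yr | 0.5882 | estimated |
| u | spontaneous recovery / ageing-out rate | 1/yr | 0.3096 | 0.05556 (=1/18) |
| k | services per mild/moderate patient | serv./person | 2 | 1.9423 |
| θ | severe-vs-mild services ratio | – | 10 | 9.3923 |
| r | proportion recovering when treated | – | 0.4460 | 0.6029 |
| μ | mortality, mild/moderate | 1/yr | 0.008772 | 0.0004225 |
| η | mortality hazard ratio, severe | – | 1.3971 | 1.2190 |
| g | population growth | persons/yr | 0 | 1823.6364 |
| h | capacity growth | serv./yr per yr | 0 | 970.2012 |

The generic preset (`table1`) uses P = 1,000,000 and leaves the initial
stocks and capacity as scenario choices. In the case-study preset
(`table2`, a child-and-adolescent cohort), `u` is an ageing outflow (1/18
per year, spontaneous recovery taken as zero) and `i`, `v` and the initial
prevalences are estimated from data. The generic preset's `i` and `v` were
chosen upstream so that equilibrium M and S equal 4.7% and 6.2% of the
population; the capacity at which that calibration holds is not part of
the preset and is deliberately not hard-coded.

## Equilibria and the boundary state

With `g = h = 0`, setting both stock derivatives to zero and writing
`x = S/M` gives an explicit chain `x(ρ)`, `M(ρ)` (see the `equilibria`
module docstring), so interior equilibria are roots of one scalar equation

    g(ρ) := ρ k M(ρ) (1 + θ x(ρ)) = r C.

The left side — the capacity that would sustain treatment rate ρ — rises
from 0 to a single maximum and decays to the limit
`g∞ = k i P ((1−γ) + θγ)`, the services demand generated per year by the
engagement inflow alone. Consequently the interior system has at most two
equilibria: a stable high-unmet-need state (small ρ, large stocks) and a
saddle (large ρ, small stocks).

The third state of the bistable regime — "no unmet need" — is a *boundary*
attractor, not an interior root. Near the origin the treatment outflow
`ρ(M+S) = rC(M+S)/(kM+θkS)` is bounded and stock-independent
(direction-dependent between `rC/(θk)` and `rC/k`), so once
`rC > g∞` it exceeds the engagement inflow and trajectories reach the
neighbourhood of the origin in finite time and stay: people are treated
and recover essentially as they engage. `find_equilibria` returns this
state as a flagged `Equilibrium` with zero stocks, stability "stable",
zero residual by convention, and NaN eigenvalues (the Jacobian is singular
at the origin). All counts below include it.

Root-finding scans a log-spaced grid of 10⁴ points in ρ ∈ [10⁻⁹, 10¹²]
(a monotone transform of total demand; unlike `S/M`, ρ has a
parameter-independent domain), inserts Brent-refined local extrema so that
near-fold root pairs are never straddled, polishes each sign change with
Brent's method to machine precision, deduplicates within 10⁻⁶·P in the
(M,S) plane, and verifies every root against the residual of the flow
derivatives (≤ 10⁻⁹·P per year in practice). A naive multi-start 2-D
Newton solver is kept as an independent cross-check and exercised in the
tests. Stability is classified from the analytic 2×2 Jacobian with a
marginal band of 10⁻¹⁰/yr on eigenvalue real parts.

## Folds, hysteresis, sensitivity

The equilibrium count as capacity rises is 1 → 3 → 1. The lower fold b′
(smallest C sustaining the near-zero branch) is where `rC` crosses `g∞`;
for γ = 0 this reduces exactly to the closed form `b′ = k i P / r`. The
upper fold b = C_b (largest C at which the high-unmet-need pair survives)
is where `rC` crosses `max g` — an interior saddle-node at which the
stable state and the saddle coalesce and the leading eigenvalue crosses
zero. At the lower fold the mechanism is instead a boundary collision (the
saddle escapes to the origin), so no interior pair coalesces there.

`locate_folds` finds both by bisection on the equilibrium count (a coarse
scan over the bracket, default (0, 2×10⁶) services/year for million-person
populations, then edge bisection to a default tolerance of 1 service/year).
Continuation methods are unnecessary for a 2-D system this cheap. With the
generic preset the folds land at 246,457 and 688,626 services/year;
between them the system is bistable and hysteretic — capacity must exceed
b to trigger the collapse of unmet need but only b′ to sustain it.

`sensitivity_sweep` varies one of {i, v, γ, r, θ} with the others fixed:
C_b increases with i, v and θ, decreases with r, and bistability disappears
entirely for θ = 1 (severity then has no service-cost penalty, disabling
the loop) and for γ above roughly 0.55–0.6.

## Basins of attraction

In the bistable window the saddle's stable manifold separates the two
basins. `classify_basin` integrates an initial condition until it is
within 10⁻⁴·P (Euclidean distance in the (M,S) plane; configurable) of a
stable equilibrium, with the near-zero attractor reached when `M+S` falls
below the same distance; the default horizon is 500 years because
convergence near the separatrix is slow. `critical_severe_fraction`
bisects the initial severe fraction along a constant-total line; the
threshold exists only where that line crosses the separatrix, rises with
capacity (more capacity enlarges the collapse basin), and is of order 0.1
at generic-preset capacities in the bistable window. `time_to_low_state`
reports the first passage of `M+S` below ε·P and is strictly faster at
larger capacity.

## Simulation

Trajectories use `scipy.integrate.solve_ivp` (LSODA, rtol 10⁻⁸, atol 10⁻⁶
persons). The treatment term makes the collapse to the origin a finite-time
singularity (ρ → ∞), which no ODE integrator should chase: a terminal
event at `M+S = 10⁻⁷·P` detects absorption, the absorbing condition
`rC > g∞` is verified at the event, and the stocks are then held at the
floor value while P and C continue their linear growth. Reported stocks
are clamped at zero. Time is in years throughout, with no intra-year
discretisation semantics.

## Bayesian calibration

The fit estimates φ = (i, v, m₀, s₀) — the two rates plus initial moderate
and severe prevalences — from two prevalence series. Observations follow a
mean-parameterised beta likelihood,
`y ~ Beta(α_j, α_j(1−m_j)/m_j)` with `m_j(t, φ)` the simulated prevalence
(stock/P) from a run with g and h active, observations independent given
φ. Priors: half-normal(0.1) on i and v (scale = SD), truncated normals
normal(0.04024, 0.001006) and normal(0.02941, 0.0007352) on m₀ and s₀.
The concentrations α_j are estimated by default under a half-normal prior
of scale 10⁴ on the concentration scale — a weakly-informative choice made
here, not a given of the problem — with a switch to fix them instead.

Sampling uses the `emcee` affine-invariant ensemble (the target density,
not the sampler brand, is the content): 32 walkers, 400 warmup + 300 kept
steps by default, initialised in a small ball around a cheap posterior-mode
estimate (best of 32 prior draws, polished by Nelder-Mead), or dispersed
from the prior when there is no data. Runs are deterministic given the
seed. Split R-hat is computed across walkers per parameter; runs with any
R-hat ≥ 1.01 are flagged `converged=False` (never silently returned) —
walker-ensemble chains are autocorrelated, so at these default lengths the
flag is usually raised even when posterior summaries are already accurate
to well within their Monte-Carlo error; longer runs clear it.
`posterior_bifurcation` pushes a seeded subsample of draws (100 by
default, mirroring the original analysis) through the fold analysis with
g = h = 0 and the non-φ parameters fixed.

## Synthetic data

The generator emulates the case-study inputs: two series (moderate,
severe), semiannual from 2017.0 to 2019.5 (six points — the cadence of the
original series is not published, so this is a package choice), beta noise
of concentration α = 2000 per series (a few percent relative noise — large
enough to exercise the likelihood, small enough for recovery from six
points). The fixture's generating rates default to i = 0.06, v = 0.30:
illustrative values placing the system slightly below its critical
capacity like the real case study, *not* fitted values. Initial
prevalences sit at the prior locations (≈0.04, ≈0.03) so priors remain
informative in recovery tests.

What the generator does not emulate: the upstream survey estimation and
perceived-need adjustment of the real prevalence series, reporting
artefacts, or any model misspecification — passing recovery tests shows
the pipeline is self-consistent at realistic noise, not that the model is
correct for real data. The real posterior (and hence the published
case-study fold capacities, which depend on it) is out of reproducible
scope because the observed series exist only in graphical form.

## Numerical choices and limitations

* Treatment quantities are defined as 0 where demand is 0 (continuous
  extension: no one engaged, no one treated); equilibrium analysis handles
  the near-zero regime through the boundary state described above.
* Fold bisection tolerance 1 service/year (matching integer reporting);
  fold locations are invariant to doubling the scan density.
* The equilibrium reduction requires γ < 1; γ = 1 (everyone severe at
  entry) is rejected rather than special-cased.
* Problem sizes in the test suite are chosen to keep the full run at a few
  minutes: recovery uses 10 replicates × (16 walkers, 300+200 steps), the
  pushforward 100 draws; the deterministic fold analysis runs in seconds.
* No age structure, diagnosis mix, provider geography, or stochastic
  (demographic-noise) dynamics; local stability only, no global proofs;
  one-parameter sensitivity only (no two-parameter cusp tracking); no
  full 2-D separatrix reconstruction beyond the 1-D threshold scan.
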