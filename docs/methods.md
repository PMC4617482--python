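# Methods

This note documents the models, estimators and numerical choices behind
`condrobust`, and what the shipped test conditions do and do not establish.

## Model abstraction

A `DynamicalModel` is a deterministic ODE system `dx/dt = f(x, u, p)` with
named states (concentrations, nM), kinetic parameters, piecewise-constant
external inputs, and optional conservation totals `x_i^T` bounding
activation/deactivation cycles.  The evaluation function ζ maps one
trajectory to a scalar z; built-ins are the trapezoidal area of a target
trace, its maximum, and the grid time of its first maximum (ties resolve to
the earliest grid point, so an all-constant trace legally reports 0).
Closed-form fixtures expose the same surface through `evaluate_matrix`, so
every downstream stage is agnostic to whether z comes from simulation or
algebra.

### Pulse generator

Two states: a repressor R2 and the output Y, both driven by the input S1
through a Hill function with exponent 3, with R2 repressing Y production
(an incoherent feedforward loop, hence a pulse).  Nominal values:
k1 = 5 nM/min, K1 = 1 nM, k12 = 20 nM/min, K2 = 100 nM, λ2 = 0.01 /min,
λ = 0.04 /min; input 470 nM for 50 min, then 0.  The Hill exponents are
structural constants and are excluded from the sampled space, which is the
six kinetic parameters with factor-10 multiplicative bounds.

The simulation horizon is 500 min with a 2001-point uniform grid
(0.25 min resolution).  The horizon is a package choice: at the slowest
sampled decay (λ = 0.004 /min) the pulse has decayed substantially by
500 min, and the area objective is insensitive to further extension at the
nominal λ.  The grid resolves the conditioned time-to-maximum (~1.4 min)
to well under the half-minute level that matters for that objective.

### EGFR-IGF1R network

Ten states: the receptors EGFR (x1) and IGF1R (x2) decay after ligand
binding and drive a Michaelis-Menten activation cascade through the MAPK
and PI3K branches; x7 is active ERK (ERK*), the proliferation indicator,
and the evaluation function is the area under the ERK* trace over a 30-min
horizon on a 1000-point grid.  Non-receptor states start at 0 (inactive
forms), standard for activation-cascade models: the cascade is driven
entirely by the receptor decay terms.  Three constant inputs u1..u3 feed
the recovery/deactivation fluxes.  The 39 kinetic parameters are sampled;
initial receptor levels can be appended to the space as two extra
dimensions (`extend_with_initial_conditions`) so they are perturbed jointly.

Two transcription quirks are kept explicit rather than silently repaired:

* the x3 deactivation flux contains a factor written as a species "x13"
  that no ten-state assignment resolves; it is a named constant
  (`x13_constant`, default 1.0).
* the x5 recovery flux is driven by x7 in the original formulation.  That
  term does not vanish when x5 is exhausted, so it is not mass-conserving
  and can push x5 negative.  `x5_recovery="verbatim"` keeps it;
  `x5_recovery="x5"` substitutes the dimensionally consistent form, which
  the package uses for quantitative runs (conservation bounds
  0 ≤ x_i ≤ x_i^T then hold to solver tolerance for every tested draw).

**Placeholder values.** The published nominal parameters reside in
supplementary material and must be supplied as a CSV; the shipped
placeholders (all rates 1, pools and receptors 10 nM, inputs 3) are
non-canonical by construction.  They were chosen so the wild-type cascade
is *responsive but not saturated*: transient ERK* stays inside its
conserved pool for most parameter draws, fewer than ~10 % of draws sit
near the output ceiling, and the population density of the ERK* area is
strongly right-skewed (mode ≪ mean), the qualitative shape reported for
this network.  With saturating placeholders the output density degenerates
at its ceiling and conditioning effects cannot be measured meaningfully.

## Sampling

Latin hypercube sampling with linearly spaced strata: for each of the q
dimensions, the bounds are cut into N equal-width strata, each stratum
receives exactly one sample placed uniformly at random, and strata are
permuted independently per dimension (scipy's `qmc.LatinHypercube`;
`midpoint=True` gives centered placements for debugging).  Log-scaled
dimensions stratify equally in log space (available behind a flag, unused
by the default analyses).  Realization r derives its seed as
`base_seed + r`, making every sample set individually replayable.

## Partitioning and conditional densities

The lower/upper sets are realized as empirical order statistics: L holds
the `round(α·N_eff)` smallest outputs and U the equally many largest, both
taken from the ends of one stable ascending sort, so threshold ties resolve
by ascending row index and L ∩ U = ∅ whenever α ≤ 0.5.  Failed simulations
(solver non-convergence, or a state below −10⁻⁶ nM) are masked, counted,
and excluded from N_eff; more than 5 % failures aborts the run as an
ill-posed space.

Conditional densities are plain Gaussian-kernel estimates on a 1024-point
uniform grid spanning each parameter's *sampling bounds* (not the
conditioned sample range — a bounds-spanning grid makes densities
comparable across realizations and lets the MIRI quadrature use one shared
grid).  Bandwidth is Silverman's rule, `0.9·min(sd, IQR/1.34)·n^{-1/5}`,
with a positive floor of 10⁻³ of the bounds width that also covers
zero-variance input.  No boundary reflection is applied; mass leaking past
the box edges keeps the grid integral slightly below 1 (≥ 0.95 in
practice), which slightly compresses MIRI values near the bounds but
affects both conditional densities alike.

## MIRI and conditioning

`μ_i = ∫ |f_{P_i|U} − f_{P_i|L}| dp_i` by trapezoidal quadrature on the
shared grid; μ is symmetric and bounded in [0, 2] (total-variation bound).
Parameters are ranked by *descending* μ — the parameters with the largest
shift between the two conditional densities are the influential ones —
with ties broken by declaration order.  The default conditioning-set size
is k = 3, a user input; α defaults to 0.1 and a warning is raised when
N < 1000/α, the guideline that keeps each conditioned tail at the ~1000
samples needed for a stable density estimate.

Conditioning fixes each selected parameter at the grid argmax (mode) of its
upper-set density when maximizing, lower-set when minimizing; argmax ties
take the smallest grid value.  The conditional re-analysis draws a *fresh*
Latin hypercube over the free parameters with the conditioned columns
exactly constant, rather than filtering the original sample set — this
matches how conditioned simulations are normally reported and gives f_{Z|K}
a full-size sample.  Multi-objective selection takes one top-μ parameter
per objective in priority order (default: declaration order), each
objective skipping parameters already claimed; the conflict rule is a
package invention, as the reference experiments contain no conflicts.

## Numerical integration

LSODA (stiff-capable, adaptive) via `scipy.integrate.odeint` with
rtol = 10⁻⁶, atol = 10⁻⁹, sampled onto the uniform output grid.  The
integration is split at every input switch time so the solver never steps
across a discontinuity.  Negative excursions are classified by a clamp
tolerance of 10⁻⁶ nM: shallower dips (ordinary solver noise at the atol
scale) are clipped to zero, deeper ones flag the sample as failed.
Michaelis-Menten fluxes are evaluated unclipped on purpose: when solver
noise pushes a state marginally past a conservation boundary the flux
changes sign and restores it, which keeps trajectories inside [0, x_i^T]
without projection.

## Determinism and parallelism

Identical (model, parameters, horizon, grid) give bit-identical
trajectories within a run environment.  Batch evaluation splits rows into
contiguous chunks whose results are reassembled in row order, so output is
invariant to the worker count; the end-to-end pipeline writes byte-identical
artifacts when re-run from the same config and base seed.

## Problem sizes used by the shipped analyses

The default study conditions are N = 10000 samples, α = 0.1, factor-10
bounds.  Ranking-stability statistics are computed over 10 independent
realizations (the original experiments used 100; 10 realizations at
N = 10000 already separate the leading MIRI group cleanly and keep the test
suite fast).  The acceptance script averages the conditioning modes over 3
realizations.  The EGFR-IGF1R directional checks use N = 2000 with the
placeholder values — their tails of 200 samples are below the 1000-sample
guideline and are flagged by the logged warning; they support directional
conclusions (mean and variance shrink under silencing conditioning), not
precise density estimates.

## What the fixtures show — and what they do not

The identity and linear fixtures have analytically known conditional
marginals, so they pin down the estimators: a driving parameter's μ must
approach 2 (top/bottom α-slices of its range are disjoint), inert
parameters must stay near 0, weight magnitude must order μ, and a negative
weight must swap the L/U modes.  The analytic normal-pair oracle checks the
MIRI quadrature against the closed form 2(2Φ(Δ/2σ)−1) to 10⁻³.  Passing
these establishes the correctness of the machinery, not the biological
fidelity of any ODE model; and the EGFR-IGF1R placeholder runs establish
directional conditioning behavior only — quantitative reproduction of the
published proliferation statistics requires the supplementary nominal
values.

## Known limitations

* Uniform prior only; no correlated or non-uniform parameter priors.
* No SBML import, stochastic (SSA) or delay simulation.
* KDE without boundary correction biases densities within one bandwidth of
  the box edges; conditioning values at the very edge of a bound inherit
  that bias (the recovered λ modes sit near, not at, the published values).
* The time-to-maximum objective is quantized to the output grid step.
* Sobol/optimized-LHS sampling and the Borgonovo δ indicator are out of
  scope; only the two-tail MIRI is implemented.
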