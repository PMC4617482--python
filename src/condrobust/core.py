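"""Core of the conditional robustness analysis.

Given a sample set P_S drawn from the parameter space and the aligned vector
of evaluation values Z, this module

* partitions Z into the lower and upper probability-alpha tails L and U
  (empirical order statistics),
* aggregates the corresponding parameter subsets P_L and P_U,
* estimates per-parameter conditional densities f_{P_i|L} and f_{P_i|U} with
  a Gaussian kernel estimator, and
* computes the moment-independent robustness indicator (MIRI)

      mu_i = integral | f_{P_i|U} - f_{P_i|L} | dp_i,

  the L1 distance between the two conditional densities, bounded in [0, 2];
  parameters are ranked by descending mu.

It also provides the Monte-Carlo estimate of the Kitano robustness measure,
the integral of the evaluation function over the parameter space under the
uniform prior, realized as the sample mean of Z.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .models import (
    DynamicalModel,
    EvaluationFunction,
    IntegrationError,
    SimulationConfig,
    evaluate,
    integrate_model,
)
from .sampling import ParameterSpace, SampleSet

logger = logging.getLogger(__name__)

__all__ = [
    "OutputSamples",
    "Partition",
    "ConditionalDensity",
    "MiriTable",
    "evaluate_batch",
    "partition_output",
    "partition_interval",
    "conditional_parameter_sets",
    "estimate_density",
    "miri",
    "miri_table",
    "rank_parameters",
    "kitano_robustness",
    "conditional_densities",
    "validate_sample_budget",
]

#: Conditioned subsamples below this size give unreliable density estimates.
MIN_DENSITY_SAMPLES = 1000
#: Abort threshold on the fraction of solver failures in a batch.
MAX_FAILURE_FRACTION = 0.05


@dataclass(frozen=True)
class OutputSamples:
    """Evaluation values aligned row-for-row with a SampleSet.

    ``values[i]`` was produced from sample row ``i``; rows whose simulation
    failed carry NaN and are masked out of every downstream count.
    """

    values: np.ndarray
    fn_name: str
    valid: np.ndarray

    def __post_init__(self):
        if self.values.shape != self.valid.shape:
            raise ValueError("values and validity mask must align")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def n_effective(self) -> int:
        return int(self.valid.sum())

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


@dataclass(frozen=True)
class Partition:
    """Index sets of the extreme outputs for a tail probability alpha.

    ``lower_indices`` / ``upper_indices`` hold the round(alpha * N_eff)
    smallest / largest values (original row indices); ``lower_threshold`` and
    ``upper_threshold`` are the boundary order statistics.
    """

    alpha: float
    lower_indices: np.ndarray
    upper_indices: np.ndarray
    lower_threshold: float
    upper_threshold: float


@dataclass(frozen=True)
class ConditionalDensity:
    """A kernel (or analytic) density on a uniform grid over known bounds."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    parameter: str = ""
    source: str = "unconditional"  # one of L, U, unconditional

    def __post_init__(self):
        if self.grid.shape != self.density.shape:
            raise ValueError("grid and density must have the same shape")

    @property
    def mode(self) -> float:
        """Grid argmax; ties resolve to the smallest grid value."""
        return float(self.grid[int(np.argmax(self.density))])

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass(frozen=True)
class MiriTable:
    """Per-parameter MIRI values with their descending ranking."""

    parameters: tuple[str, ...]
    mu: np.ndarray
    alpha: float
    seed: int | None = None

    def __post_init__(self):
        if self.mu.shape != (len(self.parameters),):
            raise ValueError("one mu per parameter required")

    @property
    def ranking(self) -> tuple[str, ...]:
        """Parameters by descending mu; ties keep declaration order."""
        order = np.argsort(-self.mu, kind="stable")
        return tuple(self.parameters[i] for i in order)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": self.parameters, "miri": self.mu})


# ---------------------------------------------------------------------------
# Batch evaluation
# ---------------------------------------------------------------------------

def _split_columns(model: DynamicalModel, space: ParameterSpace):
    """Map sample columns to model parameters and initial-condition
    overrides (columns named ``<state>_0``)."""
    param_cols, ic_cols = {}, {}
    for j, name in enumerate(space.names):
        if name in model.parameter_names:
            param_cols[name] = j
        elif name.endswith("_0") and name[:-2] in model.state_names:
            ic_cols[name[:-2]] = j
        else:
            raise ValueError(
                f"sample column {name!r} matches neither a parameter nor an "
                f"initial condition of model {model.name!r}")
    missing = set(model.parameter_names) - set(param_cols)
    if missing:
        raise ValueError(f"sample set lacks model parameters: {sorted(missing)}")
    return param_cols, ic_cols


def _evaluate_rows(model, rows, param_order, ic_states, ic_idx, fns, sim):
    out = np.full((len(rows), len(fns)), np.nan)
    ok = np.zeros(len(rows), dtype=bool)
    for i, row in enumerate(rows):
        params = row[param_order]
        overrides = {s: row[j] for s, j in zip(ic_states, ic_idx)}
        try:
            traj = integrate_model(
                model, params, horizon=sim.horizon, grid_size=sim.grid_size,
                rtol=sim.rtol, atol=sim.atol, clamp_tol=sim.clamp_tol,
                initial_state=overrides or None,
            )
        except IntegrationError:
            continue
        out[i] = [evaluate(traj, fn) for fn in fns]
        ok[i] = True
    return out, ok


def evaluate_batch(
    model,
    samples: SampleSet,
    fn: EvaluationFunction | Sequence[EvaluationFunction],
    sim: SimulationConfig | None = None,
    n_workers: int = 1,
) -> OutputSamples | dict[str, OutputSamples]:
    """Evaluate z = zeta(p) for every sample row.

    Accepts a single evaluation function or several; with several, each
    trajectory is simulated once and summarized by every function (the
    result is a dict keyed by function name).  Work is split into
    row-contiguous chunks so the result is identical for any worker count.
    Closed-form fixture models (anything exposing ``evaluate_matrix``) bypass
    the ODE integrator entirely.

    Aborts if more than 5 % of the simulations fail (the space is then
    likely ill-posed); individual failures are masked and counted.
    """
    fns = [fn] if isinstance(fn, EvaluationFunction) else list(fn)
    single = isinstance(fn, EvaluationFunction)
    n = samples.n

    if hasattr(model, "evaluate_matrix"):
        values = {f.name: np.asarray(model.evaluate_matrix(samples.matrix),
                                     dtype=float) for f in fns}
        valid = np.ones(n, dtype=bool)
    else:
        sim = sim or SimulationConfig()
        param_cols, ic_cols = _split_columns(model, samples.space)
        param_order = np.array([param_cols[p] for p in model.parameter_names])
        ic_states = tuple(ic_cols)
        ic_idx = np.array([ic_cols[s] for s in ic_states], dtype=int)

        n_workers = max(1, int(n_workers))
        bounds = np.linspace(0, n, n_workers + 1).astype(int)
        chunks = [samples.matrix[a:b] for a, b in zip(bounds, bounds[1:]) if b > a]
        if n_workers == 1:
            results = [_evaluate_rows(model, chunks[0], param_order,
                                      ic_states, ic_idx, fns, sim)]
        else:
            results = Parallel(n_jobs=n_workers, prefer="processes")(
                delayed(_evaluate_rows)(model, c, param_order, ic_states,
                                        ic_idx, fns, sim)
                for c in chunks
            )
        out = np.vstack([r[0] for r in results])
        valid = np.concatenate([r[1] for r in results])
        n_failed = n - int(valid.sum())
        if n_failed:
            logger.warning("%d/%d simulations failed and were masked", n_failed, n)
        if n_failed > MAX_FAILURE_FRACTION * n:
            raise RuntimeError(
                f"{n_failed}/{n} simulations failed (> {MAX_FAILURE_FRACTION:.0%}); "
                "the parameter space is likely ill-posed for this model")
        values = {f.name: out[:, k] for k, f in enumerate(fns)}

    results = {
        name: OutputSamples(values=v, fn_name=name, valid=valid)
        for name, v in values.items()
    }
    return results[fns[0].name] if single else results


# ---------------------------------------------------------------------------
# Output partitioning
# ---------------------------------------------------------------------------

def partition_output(out: OutputSamples, alpha: float) -> Partition:
    """Lower/upper tail sets of the output sample set.

    L holds the round(alpha * N_eff) smallest values, U the equally many
    largest; ties at a threshold resolve by ascending original row index
    (both sets are taken from the ends of one stable ascending ordering, so
    L and U are disjoint whenever alpha <= 0.5).
    """
    if not 0 < alpha <= 0.5:
        raise ValueError("alpha must lie in (0, 0.5]")
    idx = np.flatnonzero(out.valid)
    n_eff = idx.size
    n_tail = int(round(alpha * n_eff))
    if n_tail < 1:
        raise ValueError(
            f"alpha={alpha} with N_effective={n_eff} selects an empty tail")
    order = idx[np.argsort(out.values[idx], kind="stable")]
    lower = order[:n_tail]
    upper = order[n_eff - n_tail:]
    return Partition(
        alpha=float(alpha),
        lower_indices=lower,
        upper_indices=upper,
        lower_threshold=float(out.values[lower[-1]]),
        upper_threshold=float(out.values[upper[0]]),
    )


def partition_interval(out: OutputSamples, a: float, b: float):
    """Indices with a < z < b and the empirical probability of that event."""
    if not a < b:
        raise ValueError("need a < b")
    mask = out.valid & (out.values > a) & (out.values < b)
    indices = np.flatnonzero(mask)
    return indices, indices.size / out.n_effective


def conditional_parameter_sets(
    samples: SampleSet, part: Partition
) -> tuple[np.ndarray, np.ndarray]:
    """Row subsets (P_U, P_L) of the sample matrix whose outputs fall in the
    upper / lower set."""
    if part.lower_indices.size == 0 or part.upper_indices.size == 0:
        raise ValueError("partition has an empty tail set")
    if part.lower_indices.max() >= samples.n or part.upper_indices.max() >= samples.n:
        raise ValueError("partition indices exceed sample count (alignment mismatch)")
    return samples.matrix[part.upper_indices], samples.matrix[part.lower_indices]


# ---------------------------------------------------------------------------
# Conditional density estimation and MIRI
# ---------------------------------------------------------------------------

def silverman_bandwidth(values: np.ndarray, floor: float) -> float:
    """Silverman's rule-of-thumb bandwidth with a positive floor."""
    n = values.size
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread = min(x for x in (sd, iqr / 1.34) if x > 0) if max(sd, iqr) > 0 else 0.0
    return max(0.9 * spread * n ** (-0.2), floor)


def estimate_density(
    values: Sequence[float],
    bounds: tuple[float, float],
    grid_size: int = 1024,
    bandwidth: float | None = None,
    parameter: str = "",
    source: str = "unconditional",
) -> ConditionalDensity:
    """Gaussian kernel density estimate on a uniform grid spanning ``bounds``.

    The estimate is the plain superposition of Gaussian kernels (no boundary
    reflection), so some probability mass leaks past the box edges; the grid
    integral is therefore <= 1 but stays above ~0.95 in practice.  Bandwidth
    defaults to Silverman's rule with a positive floor of 1e-3 times the
    bounds width (which also covers zero-variance input).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 10:
        raise ValueError("need at least 10 values for a density estimate")
    if v.size < MIN_DENSITY_SAMPLES:
        logger.warning(
            "density for %r estimated from %d values (< %d recommended)",
            parameter or "<unnamed>", v.size, MIN_DENSITY_SAMPLES)
    lo, hi = float(bounds[0]), float(bounds[1])
    if not lo < hi:
        raise ValueError("bounds must satisfy lo < hi")
    bw = float(bandwidth) if bandwidth else silverman_bandwidth(v, 1e-3 * (hi - lo))
    grid = np.linspace(lo, hi, int(grid_size))
    u = (grid[:, None] - v[None, :]) / bw
    density = np.exp(-0.5 * u * u).sum(axis=1) / (v.size * bw * np.sqrt(2 * np.pi))
    return ConditionalDensity(grid=grid, density=density, bandwidth=bw,
                              parameter=parameter, source=source)


def miri(f_upper: ConditionalDensity, f_lower: ConditionalDensity) -> float:
    """Moment-independent robustness indicator: the L1 distance between the
    upper- and lower-conditioned densities (trapezoidal quadrature)."""
    if f_upper.grid.shape != f_lower.grid.shape or not np.allclose(
            f_upper.grid, f_lower.grid):
        raise ValueError("densities must share the same grid")
    return float(np.trapezoid(np.abs(f_upper.density - f_lower.density),
                              f_upper.grid))


def conditional_densities(
    samples: SampleSet,
    part: Partition,
    grid_size: int = 1024,
) -> dict[str, dict[str, ConditionalDensity]]:
    """Per-parameter conditional densities f_{P_i|U} and f_{P_i|L}, each on
    a grid spanning that parameter's sampling bounds."""
    p_upper, p_lower = conditional_parameter_sets(samples, part)
    out: dict[str, dict[str, ConditionalDensity]] = {}
    for j, name in enumerate(samples.space.names):
        bounds = samples.space.bounds(name)
        out[name] = {
            "U": estimate_density(p_upper[:, j], bounds, grid_size,
                                  parameter=name, source="U"),
            "L": estimate_density(p_lower[:, j], bounds, grid_size,
                                  parameter=name, source="L"),
        }
    return out


def miri_table(
    densities: Mapping[str, Mapping[str, ConditionalDensity]],
    alpha: float,
    seed: int | None = None,
) -> MiriTable:
    """Assemble the MIRI table from per-parameter conditional densities."""
    names = tuple(densities)
    mu = np.array([miri(densities[n]["U"], densities[n]["L"]) for n in names])
    return MiriTable(parameters=names, mu=mu, alpha=alpha, seed=seed)


def rank_parameters(table: MiriTable, k: int) -> tuple[str, ...]:
    """Top-k parameter names by descending MIRI."""
    if k > len(table.parameters):
        raise ValueError("k exceeds the number of parameters")
    return table.ranking[:k]


def kitano_robustness(out: OutputSamples) -> float:
    """Monte-Carlo estimate of the robustness measure: the integral of the
    evaluation function over the parameter space under the uniform prior,
    i.e. the sample mean of Z."""
    if out.n_effective == 0:
        raise ValueError("no valid output samples")
    return float(out.valid_values.mean())


def validate_sample_budget(n: int, alpha: float) -> None:
    """Warn when N < 1000/alpha, the guideline lower bound that keeps each
    conditioned tail large enough for reliable density estimation."""
    if n < MIN_DENSITY_SAMPLES / alpha:
        warnings.warn(
            f"N={n} is below the recommended lower bound "
            f"{MIN_DENSITY_SAMPLES}/alpha = {MIN_DENSITY_SAMPLES / alpha:.0f}; "
            "conditioned density estimates may be unreliable",
            UserWarning, stacklevel=2)
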