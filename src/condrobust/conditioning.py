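"""Conditioning-set selection and conditional re-analysis.

After MIRI ranking, the top parameters form the *conditioning set* K: each
is pinned to the mode of its conditional density — the density conditioned
on the upper output set when the objective is to maximize z, on the lower
set when minimizing.  The analysis is then re-run with those dimensions
fixed (fresh Latin hypercube draws over the free parameters) and the shift
of the conditional output density f_{Z|K} relative to the unconditional one
is summarized by mean, variance and mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ConditionalDensity,
    MiriTable,
    OutputSamples,
    Partition,
    conditional_densities,
    estimate_density,
    evaluate_batch,
    miri_table,
    partition_output,
)
from .models import DynamicalModel, EvaluationFunction, SimulationConfig
from .sampling import ParameterSpace, SampleSet, realization_seed, sample_l2hs

__all__ = [
    "ConditioningEntry",
    "ConditioningSet",
    "DensityStats",
    "RealizationSummary",
    "select_conditioning_set",
    "conditional_analysis",
    "density_stats",
    "multiobjective_select",
    "run_realization",
    "repeat_realizations",
]


@dataclass(frozen=True)
class ConditioningEntry:
    parameter: str
    value: float
    source: str           # "L" or "U": which conditional density the mode came from
    objective: str = ""


@dataclass(frozen=True)
class ConditioningSet:
    """Selected parameters with their fixed values (conditional-density
    modes) and the objective direction that chose them."""

    entries: tuple[ConditioningEntry, ...]
    direction: str = ""

    def __post_init__(self):
        names = [e.parameter for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameters in conditioning set")

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(e.parameter for e in self.entries)

    def as_mapping(self) -> dict[str, float]:
        return {e.parameter: e.value for e in self.entries}

    def to_json(self) -> str:
        return json.dumps(
            {"direction": self.direction,
             "entries": [asdict(e) for e in self.entries]},
            indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ConditioningSet":
        obj = json.loads(text)
        return cls(entries=tuple(ConditioningEntry(**e) for e in obj["entries"]),
                   direction=obj.get("direction", ""))


@dataclass(frozen=True)
class DensityStats:
    """Summary of an output sample set: mean, unbiased variance, KDE mode."""

    mean: float
    variance: float
    mode: float


@dataclass(frozen=True)
class RealizationSummary:
    """Box statistics of per-parameter MIRI across independent realizations
    (median, quartiles, 1.5*IQR whiskers, outlier counts)."""

    parameters: tuple[str, ...]
    mu_matrix: np.ndarray  # realizations x parameters
    seeds: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (realization, seed, parameter, miri)."""
        rows = [
            {"realization": r, "seed": self.seeds[r], "parameter": p,
             "miri": self.mu_matrix[r, j]}
            for r in range(self.mu_matrix.shape[0])
            for j, p in enumerate(self.parameters)
        ]
        return pd.DataFrame(rows)

    def box_stats(self) -> pd.DataFrame:
        q1, med, q3 = np.percentile(self.mu_matrix, [25, 50, 75], axis=0)
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        rows = []
        for j, p in enumerate(self.parameters):
            col = self.mu_matrix[:, j]
            inside = col[(col >= lo_fence[j]) & (col <= hi_fence[j])]
            rows.append({
                "parameter": p, "median": med[j], "q1": q1[j], "q3": q3[j],
                "whisker_low": float(inside.min()),
                "whisker_high": float(inside.max()),
                "n_outliers": int(((col < lo_fence[j]) | (col > hi_fence[j])).sum()),
            })
        return pd.DataFrame(rows)

    def median_ranking(self) -> tuple[str, ...]:
        med = np.median(self.mu_matrix, axis=0)
        order = np.argsort(-med, kind="stable")
        return tuple(self.parameters[i] for i in order)


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_conditioning_set(
    densities: Mapping[str, Mapping[str, ConditionalDensity]],
    ranking: Sequence[str],
    k: int,
    direction: str,
    objective: str = "",
) -> ConditioningSet:
    """Fix the top-k ranked parameters at their conditional-density modes.

    The mode is taken from f_{P_i|U} when maximizing the objective and from
    f_{P_i|L} when minimizing; grid-argmax ties resolve to the smallest grid
    value.  ``k=0`` returns an empty (no-op) conditioning set.
    """
    if direction not in ("maximize", "minimize"):
        raise ValueError("direction must be 'maximize' or 'minimize'")
    source = "U" if direction == "maximize" else "L"
    entries = tuple(
        ConditioningEntry(parameter=name, value=densities[name][source].mode,
                          source=source, objective=objective)
        for name in list(ranking)[:k]
    )
    return ConditioningSet(entries=entries, direction=direction)


def multiobjective_select(
    tables: Sequence[tuple[str, MiriTable,
                           Mapping[str, Mapping[str, ConditionalDensity]], str]],
    priority: Sequence[str] | None = None,
) -> ConditioningSet:
    """One conditioning parameter per objective.

    ``tables`` holds (objective name, MiriTable, conditional densities,
    direction) per objective.  Objectives are served in priority order
    (default: declaration order); each takes its top-MIRI parameter not
    already claimed and fixes it at the mode appropriate to its own
    direction.
    """
    by_name = {t[0]: t for t in tables}
    order = list(priority) if priority is not None else [t[0] for t in tables]
    n_params = len(tables[0][1].parameters)
    if len(order) > n_params:
        raise ValueError("more objectives than parameters to condition")
    taken: set[str] = set()
    entries = []
    for obj_name in order:
        _, table, densities, direction = by_name[obj_name]
        chosen = next(p for p in table.ranking if p not in taken)
        taken.add(chosen)
        source = "U" if direction == "maximize" else "L"
        entries.append(ConditioningEntry(
            parameter=chosen, value=densities[chosen][source].mode,
            source=source, objective=obj_name))
    return ConditioningSet(entries=tuple(entries), direction="multiobjective")


# ---------------------------------------------------------------------------
# Conditional re-analysis
# ---------------------------------------------------------------------------

def density_stats(out: OutputSamples | np.ndarray, grid_size: int = 1024) -> DensityStats:
    """Mean, unbiased variance and KDE-grid mode of an output sample set."""
    values = out.valid_values if isinstance(out, OutputSamples) else np.asarray(out, float)
    if values.size < 10:
        raise ValueError("need at least 10 samples")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return DensityStats(mean=lo, variance=0.0, mode=lo)
    kde = estimate_density(values, (lo, hi), grid_size)
    return DensityStats(mean=float(values.mean()),
                        variance=float(values.var(ddof=1)),
                        mode=kde.mode)


def conditional_analysis(
    model,
    space: ParameterSpace,
    conditioning: ConditioningSet,
    fn: EvaluationFunction,
    n: int,
    seed: int,
    sim: SimulationConfig | None = None,
    n_workers: int = 1,
) -> tuple[OutputSamples, DensityStats]:
    """Re-run the sampling analysis with the conditioning set pinned.

    Draws a fresh Latin hypercube over the free parameters (the conditioned
    columns are exactly constant at their fixed values), evaluates the
    model, and returns the f_{Z|K} sample set with its summary statistics.
    """
    fixed = conditioning.as_mapping()
    for name, value in fixed.items():
        lo, hi = space.bounds(name)
        if not lo <= value <= hi:
            raise ValueError(f"fixed value {value} for {name!r} outside bounds")
    free = [name for name in space.names if name not in fixed]
    if free:
        free_draw = sample_l2hs(space.subspace(free), n, seed)
    matrix = np.empty((n, space.dim))
    for j, name in enumerate(space.names):
        if name in fixed:
            matrix[:, j] = fixed[name]
        else:
            matrix[:, j] = free_draw.matrix[:, free.index(name)]
    samples = SampleSet(space=space, matrix=matrix, seed=seed)
    out = evaluate_batch(model, samples, fn, sim=sim, n_workers=n_workers)
    return out, density_stats(out)


# ---------------------------------------------------------------------------
# Single realization and multi-realization MIRI statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RealizationResult:
    """Full single-realization pipeline products for one objective."""

    samples: SampleSet
    outputs: OutputSamples
    partition: Partition
    densities: dict
    miri: MiriTable


def run_realization(
    model,
    space: ParameterSpace,
    fns: Sequence[EvaluationFunction],
    n: int,
    alpha: float,
    seed: int,
    sim: SimulationConfig | None = None,
    n_workers: int = 1,
    grid_size: int = 1024,
) -> dict[str, RealizationResult]:
    """Sample once, simulate once, and run the partition/density/MIRI chain
    for every evaluation function on the shared trajectories."""
    samples = sample_l2hs(space, n, seed)
    outputs = evaluate_batch(model, samples, list(fns), sim=sim,
                             n_workers=n_workers)
    results = {}
    for fn in fns:
        out = outputs[fn.name]
        part = partition_output(out, alpha)
        dens = conditional_densities(samples, part, grid_size=grid_size)
        results[fn.name] = RealizationResult(
            samples=samples, outputs=out, partition=part, densities=dens,
            miri=miri_table(dens, alpha, seed=seed))
    return results


def repeat_realizations(
    model,
    space: ParameterSpace,
    fn: EvaluationFunction | Sequence[EvaluationFunction],
    n: int,
    alpha: float,
    base_seed: int,
    n_realizations: int,
    sim: SimulationConfig | None = None,
    n_workers: int = 1,
    seeds: Sequence[int] | None = None,
) -> RealizationSummary | dict[str, RealizationSummary]:
    """Repeat the MIRI pipeline across independent sample-set realizations.

    Realization r uses seed base_seed + r (or explicit ``seeds``); the
    per-parameter MIRI values are aggregated into box statistics.  Returns
    one summary per evaluation function (a bare summary for a single one).
    """
    if n_realizations < 2 and seeds is None:
        raise ValueError("need at least 2 realizations")
    single = isinstance(fn, EvaluationFunction)
    fns = [fn] if single else list(fn)
    seeds = tuple(seeds) if seeds is not None else tuple(
        realization_seed(base_seed, r) for r in range(n_realizations))
    mu = {f.name: [] for f in fns}
    for s in seeds:
        results = run_realization(model, space, fns, n, alpha, s, sim=sim,
                                  n_workers=n_workers)
        for f in fns:
            mu[f.name].append(results[f.name].miri.mu)
    summaries = {
        name: RealizationSummary(parameters=tuple(space.names),
                                 mu_matrix=np.vstack(rows), seeds=seeds)
        for name, rows in mu.items()
    }
    return summaries[fns[0].name] if single else summaries
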