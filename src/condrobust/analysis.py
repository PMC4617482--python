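"""High-level analysis object in the model/results idiom.

:class:`ConditionalRobustnessAnalysis` bundles a dynamical model, its
parameter space and one or more evaluation objectives; ``fit()`` runs the
sampling/simulation/partition/MIRI chain over one or more independent
realizations and returns a :class:`CRAResults` carrying the MIRI estimates
with their across-realization spread, the Kitano robustness estimate, the
conditional densities, and methods for conditioning-set selection and
conditional re-analysis.

Example
-------
>>> from condrobust import models, sampling
>>> from condrobust.analysis import ConditionalRobustnessAnalysis
>>> model = models.pulse_generator_model()
>>> space = sampling.build_parameter_space(model.nominal_parameters)
>>> fn = models.EvaluationFunction("area", "Y", "maximize")
>>> cra = ConditionalRobustnessAnalysis(model, space, fn, n_samples=2000)
>>> res = cra.fit(seed=0)
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import conditioning as _cond
from . import core as _core
from .conditioning import ConditioningSet, DensityStats, RealizationSummary
from .core import MiriTable, OutputSamples, Partition
from .models import DynamicalModel, EvaluationFunction, SimulationConfig
from .sampling import ParameterSpace, realization_seed

__all__ = ["ConditionalRobustnessAnalysis", "CRAResults"]


class ConditionalRobustnessAnalysis:
    """Conditional robustness analysis of a dynamical (or closed-form) model.

    Parameters
    ----------
    model : DynamicalModel or FixtureModel
        The system whose evaluation function is studied.
    space : ParameterSpace
        Sampling box over the perturbed parameters (optionally including
        initial-condition dimensions named ``<state>_0``).
    objectives : EvaluationFunction or sequence thereof
        The scalar trajectory summaries to analyze; each carries its own
        optimization direction.
    alpha : float
        Tail probability defining the lower/upper output sets (default 0.1).
    n_samples : int
        Latin hypercube sample count N per realization (default 10000).
        A warning is raised when N < 1000/alpha.
    conditioning_size : int
        Default number of parameters k in the conditioning set (default 3).
    sim : SimulationConfig, optional
        Integration horizon/grid/tolerances for ODE models.
    """

    def __init__(
        self,
        model,
        space: ParameterSpace,
        objectives: EvaluationFunction | Sequence[EvaluationFunction],
        alpha: float = 0.1,
        n_samples: int = 10000,
        conditioning_size: int = 3,
        sim: SimulationConfig | None = None,
    ):
        if not 0 < alpha <= 0.5:
            raise ValueError("alpha must lie in (0, 0.5]")
        if n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        objectives = ([objectives] if isinstance(objectives, EvaluationFunction)
                      else list(objectives))
        if not objectives:
            raise ValueError("at least one objective required")
        if conditioning_size > space.dim:
            raise ValueError("conditioning_size exceeds the space dimension")
        _core.validate_sample_budget(n_samples, alpha)
        self.model = model
        self.space = space
        self.objectives = objectives
        self.alpha = float(alpha)
        self.n_samples = int(n_samples)
        self.conditioning_size = int(conditioning_size)
        self.sim = sim

    def fit(self, seed: int = 0, n_realizations: int = 1,
            n_workers: int = 1) -> "CRAResults":
        """Run the full pipeline over ``n_realizations`` sample sets
        (realization r seeded with seed + r) and collect the results."""
        seeds = tuple(realization_seed(seed, r) for r in range(n_realizations))
        per_real = [
            _cond.run_realization(self.model, self.space, self.objectives,
                                  self.n_samples, self.alpha, s,
                                  sim=self.sim, n_workers=n_workers)
            for s in seeds
        ]
        summaries = {
            fn.name: RealizationSummary(
                parameters=tuple(self.space.names),
                mu_matrix=np.vstack([r[fn.name].miri.mu for r in per_real]),
                seeds=seeds)
            for fn in self.objectives
        }
        return CRAResults(analysis=self, realizations=per_real,
                          summaries=summaries, seeds=seeds,
                          n_workers=n_workers)


@dataclass
class CRAResults:
    """Fitted results: MIRI tables, rankings, densities and conditioning.

    The first realization provides the reference partition and conditional
    densities; ``summaries`` holds the across-realization MIRI spread.
    """

    analysis: ConditionalRobustnessAnalysis
    realizations: list[dict]
    summaries: dict[str, RealizationSummary]
    seeds: tuple[int, ...]
    n_workers: int = 1

    # -- accessors ---------------------------------------------------------

    def _objective(self, name: str | None) -> EvaluationFunction:
        objs = self.analysis.objectives
        if name is None:
            if len(objs) > 1:
                raise ValueError("several objectives fitted; name one")
            return objs[0]
        match = [f for f in objs if f.name == name]
        if not match:
            raise KeyError(f"objective {name!r} was not fitted")
        return match[0]

    def result(self, objective: str | None = None, realization: int = 0):
        return self.realizations[realization][self._objective(objective).name]

    def miri(self, objective: str | None = None, realization: int = 0) -> MiriTable:
        return self.result(objective, realization).miri

    def ranking(self, objective: str | None = None) -> tuple[str, ...]:
        """Parameters by descending median MIRI across realizations."""
        return self.summaries[self._objective(objective).name].median_ranking()

    def robustness(self, objective: str | None = None, realization: int = 0) -> float:
        """Monte-Carlo Kitano robustness estimate (mean evaluation value)."""
        return _core.kitano_robustness(self.result(objective, realization).outputs)

    def miri_frame(self) -> pd.DataFrame:
        """Long-format MIRI table over (objective, realization, parameter)."""
        frames = []
        for name, summary in self.summaries.items():
            frame = summary.to_frame()
            frame.insert(0, "objective", name)
            frames.append(frame)
        return pd.concat(frames, ignore_index=True)

    # -- conditioning ------------------------------------------------------

    def conditioning_set(self, objective: str | None = None,
                         k: int | None = None) -> ConditioningSet:
        """Top-k parameters (median-MIRI ranking) fixed at the modes of the
        first realization's conditional densities."""
        fn = self._objective(objective)
        k = self.analysis.conditioning_size if k is None else k
        return _cond.select_conditioning_set(
            self.result(fn.name).densities, self.ranking(fn.name), k,
            fn.direction, objective=fn.name)

    def multiobjective_set(self, priority: Sequence[str] | None = None) -> ConditioningSet:
        """One top-MIRI parameter per fitted objective (conflicts resolved
        by priority order)."""
        tables = [
            (fn.name, self.miri(fn.name), self.result(fn.name).densities,
             fn.direction)
            for fn in self.analysis.objectives
        ]
        return _cond.multiobjective_select(tables, priority=priority)

    def conditional(
        self,
        conditioning: ConditioningSet | None = None,
        objective: str | None = None,
        seed: int | None = None,
        n_samples: int | None = None,
    ) -> tuple[OutputSamples, DensityStats]:
        """Re-run the analysis with a conditioning set pinned (fresh Latin
        hypercube over the free parameters) and summarize f_{Z|K}."""
        fn = self._objective(objective)
        if conditioning is None:
            conditioning = self.conditioning_set(fn.name)
        return _cond.conditional_analysis(
            self.analysis.model, self.analysis.space, conditioning, fn,
            n_samples or self.analysis.n_samples,
            self.seeds[0] if seed is None else seed,
            sim=self.analysis.sim, n_workers=self.n_workers)

    def unconditional_stats(self, objective: str | None = None) -> DensityStats:
        return _cond.density_stats(self.result(objective).outputs)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Human-readable report of the fitted analysis."""
        a = self.analysis
        lines = [
            "Conditional Robustness Analysis",
            "=" * 48,
            f"model: {getattr(a.model, 'name', '?')}    "
            f"dimensions: {a.space.dim}",
            f"N = {a.n_samples}   alpha = {a.alpha}   "
            f"realizations = {len(self.seeds)}   seeds = {list(self.seeds)}",
            "",
        ]
        for fn in a.objectives:
            summary = self.summaries[fn.name]
            med = np.median(summary.mu_matrix, axis=0)
            order = np.argsort(-med, kind="stable")
            lines.append(f"objective: {fn.name}({fn.target_state}), {fn.direction}")
            lines.append(f"  robustness (mean z): {self.robustness(fn.name):.6g}")
            lines.append("  parameter    median MIRI")
            for i in order:
                lines.append(f"  {summary.parameters[i]:<12s} {med[i]:.4f}")
            cset = self.conditioning_set(fn.name)
            pins = ", ".join(f"{e.parameter}={e.value:.4g}" for e in cset.entries)
            lines.append(f"  conditioning set (k={a.conditioning_size}, "
                         f"{cset.direction}, source {cset.entries[0].source if cset.entries else '-'}): {pins}")
            lines.append("")
        return "\n".join(lines)
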