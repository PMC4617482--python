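"""Run configuration, model registry, parameter tables and result bundles.

A run is described by a flat YAML config (model name, objectives with
directions, N, alpha, realization count, conditioning-set size, base seed,
solver settings, output directory).  ``run_cra`` executes the whole
pipeline — sample, simulate, partition, estimate densities, rank by MIRI,
select and apply the conditioning set — and writes plain CSV/JSON artifacts
plus a manifest with seeds and software versions.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import ConditionalRobustnessAnalysis
from .conditioning import density_stats
from .fixtures import make_identity_fixture, make_linear_fixture
from .models import (
    EGFR_INPUT_NAMES,
    EGFR_PARAMETER_NAMES,
    EGFR_PLACEHOLDER_VALUES,
    EGFR_TOTAL_NAMES,
    EvaluationFunction,
    SimulationConfig,
    egfr_igf1r_model,
    pulse_generator_model,
)
from .sampling import build_parameter_space, extend_with_initial_conditions

logger = logging.getLogger(__name__)

__all__ = ["CraConfig", "load_config", "load_parameter_table", "run_cra",
           "build_model_and_space", "MODEL_REGISTRY"]

#: Default evaluation target per registered model.
_DEFAULT_TARGET = {
    "pulse_generator": "Y",
    "egfr_igf1r": "x7",
}


@dataclass
class CraConfig:
    """Configuration of a conditional robustness run."""

    model: str = "pulse_generator"
    objectives: tuple[str, ...] = ("area",)
    directions: tuple[str, ...] = ("maximize",)
    target_state: str | None = None
    n_samples: int = 10000
    alpha: float = 0.1
    n_realizations: int = 1
    conditioning_size: int = 3
    base_seed: int = 0
    lower_factor: float = 0.1
    upper_factor: float = 10.0
    log_scale: bool = False
    horizon: float = 500.0
    grid_size: int = 2001
    rtol: float = 1e-6
    atol: float = 1e-9
    n_workers: int = 1
    output_dir: str = "cra_results"
    parameter_table: str | None = None
    perturb_initial_conditions: bool = False
    ic_lower_factor: float = 0.1
    ic_upper_factor: float = 10.0

    def __post_init__(self):
        if not 0 < self.alpha <= 0.5:
            raise ValueError("alpha must lie in (0, 0.5]")
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if len(self.objectives) != len(self.directions):
            raise ValueError("one direction per objective required")

    @property
    def sim(self) -> SimulationConfig:
        return SimulationConfig(horizon=self.horizon, grid_size=self.grid_size,
                                rtol=self.rtol, atol=self.atol)


def load_config(path, **overrides) -> CraConfig:
    """Load a YAML config file; keyword overrides win over file keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key in ("objectives", "directions"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    data.update({k: v for k, v in overrides.items() if v is not None})
    return CraConfig(**data)


def load_parameter_table(path, required: Sequence[str] | None = None,
                         known: Sequence[str] | None = None) -> dict[str, float]:
    """Read a name,value CSV into a validated mapping.

    Rejects duplicate names, non-positive values, and (when ``known`` is
    given) unknown names; reports the full missing set when ``required``
    names are absent.
    """
    frame = pd.read_csv(path)
    if list(frame.columns[:2]) != ["name", "value"]:
        raise ValueError("parameter table must have columns name,value")
    names = frame["name"].astype(str).tolist()
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValueError(f"duplicate parameter names: {dupes}")
    table = dict(zip(names, frame["value"].astype(float)))
    bad = sorted(n for n, v in table.items() if not np.isfinite(v) or v <= 0)
    if bad:
        raise ValueError(f"non-positive or non-finite values for: {bad}")
    if known is not None:
        unknown = sorted(set(names) - set(known))
        if unknown:
            raise ValueError(f"unknown parameter names: {unknown}")
    if required is not None:
        missing = sorted(set(required) - set(names))
        if missing:
            raise ValueError(f"missing required parameters: {missing}")
    return table


# ---------------------------------------------------------------------------
# Model registry
# ---------------------------------------------------------------------------

def _build_pulse(config: CraConfig):
    model = pulse_generator_model()
    scale = "log" if config.log_scale else "linear"
    space = build_parameter_space(model.nominal_parameters,
                                 config.lower_factor, config.upper_factor,
                                 scale)
    return model, space


EGFR_TABLE_NAMES = (EGFR_PARAMETER_NAMES + EGFR_TOTAL_NAMES
                    + ("x1_0", "x2_0") + EGFR_INPUT_NAMES + ("x13",))


def _build_egfr(config: CraConfig):
    if config.parameter_table:
        values = dict(EGFR_PLACEHOLDER_VALUES)
        values.update(load_parameter_table(
            config.parameter_table, required=EGFR_PARAMETER_NAMES,
            known=EGFR_TABLE_NAMES))
    else:
        logger.warning(
            "EGFR-IGF1R model running with non-canonical placeholder "
            "parameter values; supply a parameter table for real analyses")
        values = dict(EGFR_PLACEHOLDER_VALUES)
    model = egfr_igf1r_model(
        parameter_values=[values[n] for n in EGFR_PARAMETER_NAMES],
        totals={n: values[n] for n in EGFR_TOTAL_NAMES},
        initial_receptors=(values["x1_0"], values["x2_0"]),
        inputs=[values[n] for n in EGFR_INPUT_NAMES],
        x13_constant=values.get("x13", 1.0),
        x5_recovery="x5",
    )
    scale = "log" if config.log_scale else "linear"
    space = build_parameter_space(model.nominal_parameters,
                                 config.lower_factor, config.upper_factor,
                                 scale)
    if config.perturb_initial_conditions:
        space = extend_with_initial_conditions(
            space, ("x1_0", "x2_0"), (values["x1_0"], values["x2_0"]),
            config.ic_lower_factor, config.ic_upper_factor, scale)
    return model, space


def _build_identity(config: CraConfig):
    model = make_identity_fixture(3, 1)
    return model, model.space


def _build_linear(config: CraConfig):
    model = make_linear_fixture([1.0, 0.5, 0.1])
    return model, model.space


MODEL_REGISTRY = {
    "pulse_generator": _build_pulse,
    "egfr_igf1r": _build_egfr,
    "identity3": _build_identity,
    "linear3": _build_linear,
}


def build_model_and_space(config: CraConfig):
    try:
        return MODEL_REGISTRY[config.model](config)
    except KeyError:
        raise ValueError(
            f"unknown model {config.model!r}; available: "
            f"{sorted(MODEL_REGISTRY)}") from None


def build_objectives(config: CraConfig, model) -> list[EvaluationFunction]:
    target = config.target_state or _DEFAULT_TARGET.get(config.model)
    if target is None:
        raise ValueError("target_state required for this model")
    return [EvaluationFunction(name, target, direction)
            for name, direction in zip(config.objectives, config.directions)]


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def run_cra(config: CraConfig) -> dict:
    """Execute the full pipeline for ``config`` and write the result bundle.

    Artifacts in the output directory: samples.csv (realization 1 draws),
    outputs.csv (aligned evaluation values), miri.csv (long format across
    realizations), conditioning.json, stats.json (unconditional vs
    conditional density statistics) and manifest.json.
    """
    model, space = build_model_and_space(config)
    is_fixture = hasattr(model, "evaluate_matrix")
    if is_fixture:
        # closed-form fixtures carry their own map; the objective here only
        # names the column and the optimization direction
        objectives = [EvaluationFunction("area", "z", d)
                      for d in config.directions]
    else:
        objectives = build_objectives(config, model)

    stage = "fit"
    try:
        cra = ConditionalRobustnessAnalysis(
            model, space, objectives, alpha=config.alpha,
            n_samples=config.n_samples,
            conditioning_size=min(config.conditioning_size, space.dim),
            sim=None if is_fixture else config.sim)
        results = cra.fit(seed=config.base_seed,
                          n_realizations=config.n_realizations,
                          n_workers=config.n_workers)
        stage = "conditioning"
        stats = {}
        conditioning = {}
        for fn in objectives:
            cset = results.conditioning_set(fn.name)
            conditioning[fn.name] = json.loads(cset.to_json())
            out, cond_stats = results.conditional(cset, fn.name,
                                                  seed=config.base_seed
                                                  + config.n_realizations)
            stats[fn.name] = {
                "unconditional": asdict(results.unconditional_stats(fn.name)),
                "conditional": asdict(cond_stats),
                "robustness": results.robustness(fn.name),
                "n_effective": out.n_effective,
            }
    except Exception as exc:
        raise RuntimeError(
            f"CRA stage {stage!r} failed (base_seed={config.base_seed}): {exc}"
        ) from exc

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    first = results.realizations[0][objectives[0].name]
    first.samples.to_csv(outdir / "samples.csv")
    pd.DataFrame({fn.name: results.realizations[0][fn.name].outputs.values
                  for fn in objectives}).to_csv(outdir / "outputs.csv",
                                                index=False)
    results.miri_frame().to_csv(outdir / "miri.csv", index=False)
    (outdir / "conditioning.json").write_text(
        json.dumps(conditioning, indent=2, sort_keys=True))
    (outdir / "stats.json").write_text(
        json.dumps(stats, indent=2, sort_keys=True))
    manifest = {
        "config": asdict(config),
        "seeds": list(results.seeds),
        "n_effective": {fn.name: results.realizations[0][fn.name].outputs.n_effective
                        for fn in objectives},
        "versions": {
            "condrobust": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return {"results": results, "stats": stats, "conditioning": conditioning,
            "output_dir": outdir}
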