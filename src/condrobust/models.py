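"""Dynamical-model abstraction, built-in networks and evaluation functions.

A model is a deterministic ODE system

    dx/dt = f(x, u, p),   x(0) = x0,

whose states are molecular concentrations (nM), driven by piecewise-constant
external inputs ``u`` and parameterized by a vector ``p`` of kinetic
constants.  A scalar *evaluation function* z = zeta(p) summarizes one
simulated trajectory (area under a trace, its peak, or the time of the peak)
and is the quantity whose distribution the conditional robustness analysis
studies.

Two networks ship with the package:

* a two-state incoherent-feedforward **pulse generator** (input S1 activates
  both the output Y and a repressor R2 of Y through Hill kinetics), and
* the ten-state **EGFR-IGF1R** signal-transduction cascade whose output is
  the active-ERK trace (state x7), with conservation totals for the
  non-receptor species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import odeint

__all__ = [
    "IntegrationError",
    "PiecewiseConstantInput",
    "DynamicalModel",
    "Trajectory",
    "EvaluationFunction",
    "SimulationConfig",
    "pulse_generator_model",
    "egfr_igf1r_model",
    "EGFR_PLACEHOLDER_VALUES",
    "integrate_model",
    "evaluate",
]


class IntegrationError(RuntimeError):
    """The ODE solver failed to produce a valid trajectory."""


@dataclass(frozen=True)
class PiecewiseConstantInput:
    """External stimuli held constant on consecutive time segments.

    ``times[k]`` is the start of segment ``k`` (``times[0] == 0``);
    ``values[k]`` is the input vector on ``[times[k], times[k+1])``.
    """

    names: tuple[str, ...]
    times: tuple[float, ...]
    values: tuple[tuple[float, ...], ...]

    def __post_init__(self):
        if len(self.times) != len(self.values):
            raise ValueError("one value vector per segment required")
        if self.times and self.times[0] != 0.0:
            raise ValueError("first segment must start at t=0")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("segment times must be strictly increasing")

    @classmethod
    def constant(cls, names: Sequence[str], values: Sequence[float]) -> "PiecewiseConstantInput":
        return cls(tuple(names), (0.0,), (tuple(float(v) for v in values),))

    def value_at(self, t: float) -> np.ndarray:
        idx = 0
        for k, tk in enumerate(self.times):
            if t >= tk:
                idx = k
        return np.asarray(self.values[idx], dtype=float)

    @property
    def switch_times(self) -> tuple[float, ...]:
        return self.times[1:]


@dataclass(frozen=True)
class DynamicalModel:
    """An ODE model dx/dt = f(x, u, p) with named states, parameters, inputs.

    ``rhs(x, t, p, u)`` must be deterministic and return a derivative vector
    of the same length as ``x``.  ``conserved_totals`` optionally records the
    total pools x_i^T that bound states of activation/deactivation cycles.
    """

    name: str
    state_names: tuple[str, ...]
    parameter_names: tuple[str, ...]
    rhs: Callable[[np.ndarray, float, np.ndarray, np.ndarray], Sequence[float]]
    initial_state: tuple[float, ...]
    inputs: PiecewiseConstantInput
    nominal_parameters: Mapping[str, float] = field(default_factory=dict)
    conserved_totals: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.initial_state) != len(self.state_names):
            raise ValueError("initial_state length must match state_names")
        if any(not math.isfinite(v) or v < 0 for v in self.initial_state):
            raise ValueError("initial states must be finite and non-negative")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    def state_index(self, name: str) -> int:
        return self.state_names.index(name)

    def build_initial_state(self, overrides: Mapping[str, float] | None = None) -> np.ndarray:
        """Initial-state vector with per-state overrides (used when initial
        conditions are sampled jointly with the parameters)."""
        x0 = np.asarray(self.initial_state, dtype=float).copy()
        for key, value in (overrides or {}).items():
            x0[self.state_index(key)] = value
        return x0

    def with_inputs(self, inputs: PiecewiseConstantInput) -> "DynamicalModel":
        return replace(self, inputs=inputs)


@dataclass(frozen=True)
class Trajectory:
    """A simulated realization x(t) on a uniform time grid (minutes, nM)."""

    times: np.ndarray
    states: np.ndarray
    state_names: tuple[str, ...]

    def trace(self, state: str) -> np.ndarray:
        return self.states[:, self.state_names.index(state)]


@dataclass(frozen=True)
class EvaluationFunction:
    """Scalar summary zeta of one trajectory: the quantity under study.

    ``name`` is one of ``area`` (trapezoidal integral of the target trace),
    ``maximum`` (its peak value), ``time_to_maximum`` (grid time of the first
    peak) or ``custom`` with a user-supplied ``func(times, trace) -> float``.
    ``direction`` states which extreme of z the downstream conditioning seeks.
    """

    name: str
    target_state: str
    direction: str = "maximize"
    func: Callable[[np.ndarray, np.ndarray], float] | None = None

    def __post_init__(self):
        if self.name not in ("area", "maximum", "time_to_maximum", "custom"):
            raise ValueError(f"unknown evaluation function {self.name!r}")
        if self.direction not in ("maximize", "minimize"):
            raise ValueError("direction must be 'maximize' or 'minimize'")
        if self.name == "custom" and self.func is None:
            raise ValueError("custom evaluation requires func")


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical integration settings.

    States dipping below ``-clamp_tol`` abort the sample (flagged as failed
    downstream); shallower negative excursions are clipped to zero.
    """

    horizon: float = 500.0
    grid_size: int = 2001
    rtol: float = 1e-6
    atol: float = 1e-9
    clamp_tol: float = 1e-6

    def __post_init__(self):
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.grid_size < 2:
            raise ValueError("grid_size must be at least 2")


# ---------------------------------------------------------------------------
# Built-in model: pulse generator (incoherent feedforward loop)
# ---------------------------------------------------------------------------

_PULSE_HILL_N1 = 3.0
_PULSE_HILL_N2 = 3.0

PULSE_NOMINAL = {
    "k1": 5.0,       # nM/min, R2 production rate
    "K1": 1.0,       # nM, input activation threshold
    "k12": 20.0,     # nM/min, Y production rate
    "K2": 100.0,     # nM, repression threshold of R2 on Y
    "lambda2": 0.01, # 1/min, R2 degradation
    "lambda": 0.04,  # 1/min, Y degradation
}


def _pulse_rhs(x, t, p, u):
    k1, K1, k12, K2, lam2, lam = p
    s1 = u[0]
    if s1 > 0.0:
        hn = (s1 / K1) ** _PULSE_HILL_N1
        h = hn / (1.0 + hn)
    else:
        h = 0.0
    r2, y = x
    r2 = max(r2, 0.0)
    return (
        k1 * h - lam2 * r2,
        k12 / (1.0 + (r2 / K2) ** _PULSE_HILL_N2) * h - lam * y,
    )


def pulse_generator_model(
    amplitude: float = 470.0, duration: float = 50.0
) -> DynamicalModel:
    """Two-state pulse generator driven by a rectangular input S1.

    S1 activates both the repressor R2 and the output Y via a Hill function
    (exponent 3); R2 represses Y production.  The default input is 470 nM for
    50 min, then 0.  The six kinetic parameters {k1, K1, k12, K2, lambda2,
    lambda} are the sampled ones; the Hill exponents are structural constants.
    """
    if duration > 0:
        inputs = PiecewiseConstantInput(
            ("S1",), (0.0, float(duration)), ((float(amplitude),), (0.0,))
        )
    else:
        inputs = PiecewiseConstantInput.constant(("S1",), (0.0,))
    return DynamicalModel(
        name="pulse_generator",
        state_names=("R2", "Y"),
        parameter_names=tuple(PULSE_NOMINAL),
        rhs=_pulse_rhs,
        initial_state=(0.0, 0.0),
        inputs=inputs,
        nominal_parameters=dict(PULSE_NOMINAL),
    )


# ---------------------------------------------------------------------------
# Built-in model: EGFR-IGF1R signal transduction network
# ---------------------------------------------------------------------------

EGFR_STATE_NAMES = tuple(f"x{i}" for i in range(1, 11))
EGFR_PARAMETER_NAMES = tuple(f"p{i}" for i in range(1, 40))
EGFR_TOTAL_NAMES = tuple(f"x{i}T" for i in range(3, 11))
EGFR_INPUT_NAMES = ("u1", "u2", "u3")

#: Placeholder numeric values for the EGFR-IGF1R network.  These are NOT the
#: published nominal values (those live in the original study's supplementary
#: tables and must be supplied by the user via a parameter table); they merely
#: make the model runnable for structural and methodological checks.  They
#: are chosen so the wild-type cascade is responsive but not saturated:
#: unit kinetic rates, conserved pools and receptor levels of the same
#: magnitude (10 nM), and deactivation inputs strong enough that active
#: fractions are graded rather than pinned at their conservation ceilings.
EGFR_PLACEHOLDER_VALUES: dict[str, float] = (
    {name: 1.0 for name in EGFR_PARAMETER_NAMES}
    | {name: 10.0 for name in EGFR_TOTAL_NAMES}
    | {"x1_0": 10.0, "x2_0": 10.0, "u1": 3.0, "u2": 3.0, "u3": 3.0}
)


def _mm(rate, enzyme, substrate, km):
    """Michaelis-Menten flux rate*enzyme*substrate/(km+substrate).

    Left unclipped on purpose: a slightly negative substrate (solver noise
    past a conservation boundary) makes the flux change sign and restore
    the state into [0, x^T]."""
    return rate * enzyme * substrate / (km + substrate)


def _make_egfr_rhs(totals, x13_constant, x5_recovery):
    xT = [totals[n] for n in EGFR_TOTAL_NAMES]  # x3T..x10T
    x3T, x4T, x5T, x6T, x7T, x8T, x9T, x10T = xT
    verbatim_x5 = x5_recovery == "verbatim"

    def rhs(x, t, p, u):
        x1, x2, x3, x4, x5, x6, x7, x8, x9, x10 = x
        u1, u2, u3 = u
        dx1 = -p[0] * x1
        dx2 = -p[1] * x2
        dx3 = (
            _mm(p[5], x1, x3T - x3, p[6])
            + _mm(p[13], x2, x3T - x3, p[14])
            - _mm(p[11], x13_constant, x3, p[12])
        )
        dx4 = _mm(p[7], x3, x4T - x4, p[8]) - _mm(p[32], u3, x4, p[33])
        recovery_species = x7 if verbatim_x5 else x5
        dx5 = (
            _mm(p[26], x4, x5T - x5, p[27])
            - _mm(p[36], u1, recovery_species, p[37])
            - _mm(p[30], x10, x5, p[31])
        )
        dx6 = _mm(p[28], x5, x6T - x6, p[29]) - _mm(p[34], u2, x6, p[35])
        dx7 = _mm(p[9], x6, x7T - x7, p[10]) - _mm(p[22], u2, x7, p[23])
        dx8 = _mm(p[3], x7, x8T - x8, p[4]) - p[38] * x8
        dx9 = (
            _mm(p[24], x4, x9T - x9, p[25])
            + _mm(p[15], x2, x9T - x9, p[16])
            + _mm(p[17], x1, x9T - x9, p[18])
            - p[2] * x9
        )
        dx10 = _mm(p[19], x9, x10T - x10, p[20]) - p[21] * x10
        return (dx1, dx2, dx3, dx4, dx5, dx6, dx7, dx8, dx9, dx10)

    return rhs


def egfr_igf1r_model(
    parameter_values: Sequence[float] | None = None,
    totals: Mapping[str, float] | None = None,
    initial_receptors: Sequence[float] | None = None,
    inputs: Sequence[float] | None = None,
    x13_constant: float = 1.0,
    x5_recovery: str = "verbatim",
) -> DynamicalModel:
    """Ten-state EGFR-IGF1R cascade with active ERK as state ``x7``.

    Receptor states x1 (EGFR) and x2 (IGF1R) decay after ligand binding and
    trigger the downstream activation cascade; states x3..x10 are active
    protein forms bounded by conservation totals x_i^T and start at 0
    (inactive).  Three constant inputs u1..u3 drive recovery/deactivation
    fluxes.

    ``x13_constant`` stands for a literal factor in the x3 deactivation flux
    whose species is not resolvable from the network description; it is kept
    as a named constant rather than silently remapped.  ``x5_recovery``
    selects the species appearing in the x5 recovery flux: ``"verbatim"``
    keeps the as-published form (driven by x7, which is not mass-conserving
    and can push x5 negative) while ``"x5"`` substitutes the dimensionally
    consistent form used for quantitative runs.

    When any of the numeric arguments is omitted, clearly non-canonical
    placeholder values (:data:`EGFR_PLACEHOLDER_VALUES`) are used.
    """
    if x5_recovery not in ("verbatim", "x5"):
        raise ValueError("x5_recovery must be 'verbatim' or 'x5'")
    ph = EGFR_PLACEHOLDER_VALUES
    if parameter_values is None:
        parameter_values = [ph[n] for n in EGFR_PARAMETER_NAMES]
    parameter_values = np.asarray(parameter_values, dtype=float)
    if parameter_values.shape != (39,):
        raise ValueError("parameter_values must have 39 entries p1..p39")
    if np.any(parameter_values <= 0):
        raise ValueError("all parameters must be positive")
    if totals is None:
        totals = {n: ph[n] for n in EGFR_TOTAL_NAMES}
    missing = [n for n in EGFR_TOTAL_NAMES if n not in totals]
    if missing:
        raise ValueError(f"missing conservation totals: {missing}")
    if any(totals[n] < 0 for n in EGFR_TOTAL_NAMES):
        raise ValueError("conservation totals must be non-negative")
    if initial_receptors is None:
        initial_receptors = (ph["x1_0"], ph["x2_0"])
    x1_0, x2_0 = (float(v) for v in initial_receptors)
    if x1_0 < 0 or x2_0 < 0:
        raise ValueError("initial receptor values must be non-negative")
    if inputs is None:
        inputs = (ph["u1"], ph["u2"], ph["u3"])
    u = tuple(float(v) for v in inputs)
    if len(u) != 3 or any(v < 0 for v in u):
        raise ValueError("inputs must be three non-negative values u1..u3")

    return DynamicalModel(
        name="egfr_igf1r",
        state_names=EGFR_STATE_NAMES,
        parameter_names=EGFR_PARAMETER_NAMES,
        rhs=_make_egfr_rhs(dict(totals), float(x13_constant), x5_recovery),
        initial_state=(x1_0, x2_0) + (0.0,) * 8,
        inputs=PiecewiseConstantInput.constant(EGFR_INPUT_NAMES, u),
        nominal_parameters=dict(zip(EGFR_PARAMETER_NAMES, parameter_values)),
        conserved_totals={n: float(totals[n]) for n in EGFR_TOTAL_NAMES},
    )


EGFR_SIM = SimulationConfig(horizon=30.0, grid_size=1000)


# ---------------------------------------------------------------------------
# Numerical integration and trajectory evaluation
# ---------------------------------------------------------------------------

def integrate_model(
    model: DynamicalModel,
    params: Sequence[float] | Mapping[str, float],
    horizon: float = 500.0,
    grid_size: int = 2001,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    clamp_tol: float = 1e-6,
    initial_state: Mapping[str, float] | None = None,
) -> Trajectory:
    """Integrate ``model`` on a uniform grid with LSODA (stiff-capable).

    The integration is split at every input switch time so the solver never
    steps across a discontinuity.  Raises :class:`IntegrationError` on solver
    failure, non-finite output, or states below ``-clamp_tol``; negative
    values above that tolerance are clipped to zero.
    """
    if isinstance(params, Mapping):
        p = np.array([params[n] for n in model.parameter_names], dtype=float)
    else:
        p = np.asarray(params, dtype=float)
    if p.shape != (model.n_parameters,):
        raise ValueError("parameter vector length mismatch")
    if np.any(p <= 0) or not np.all(np.isfinite(p)):
        raise ValueError("parameters must be finite and positive")

    grid = np.linspace(0.0, float(horizon), int(grid_size))
    switches = [t for t in model.inputs.switch_times if 0.0 < t < horizon]
    boundaries = [0.0] + switches + [float(horizon)]

    x = model.build_initial_state(initial_state)
    states = np.empty((grid.size, model.n_states))
    states[0] = x
    for a, b in zip(boundaries, boundaries[1:]):
        u = model.inputs.value_at(a)
        inner_mask = (grid > a) & (grid < b)
        seg_times = np.concatenate(([a], grid[inner_mask], [b]))
        sol, info = odeint(
            model.rhs, x, seg_times, args=(p, u),
            rtol=rtol, atol=atol, full_output=True, mxstep=10000,
        )
        if info["message"] != "Integration successful." or not np.all(np.isfinite(sol)):
            raise IntegrationError(
                f"LSODA failed on [{a}, {b}] for model {model.name!r}: "
                f"{info['message']}"
            )
        x = sol[-1]
        states[inner_mask] = sol[1:-1]
        states[grid == b] = sol[-1]

    if states.min() < -clamp_tol:
        raise IntegrationError(
            f"state fell below -{clamp_tol:g} (min {states.min():.3e}) "
            f"for model {model.name!r}"
        )
    np.clip(states, 0.0, None, out=states)
    return Trajectory(times=grid, states=states, state_names=model.state_names)


def evaluate(traj: Trajectory, fn: EvaluationFunction) -> float:
    """Apply an evaluation function to a trajectory, returning the scalar z."""
    trace = traj.trace(fn.target_state)
    if fn.name == "area":
        return float(np.trapezoid(trace, traj.times))
    if fn.name == "maximum":
        return float(trace.max())
    if fn.name == "time_to_maximum":
        return float(traj.times[int(np.argmax(trace))])
    return float(fn.func(traj.times, trace))
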