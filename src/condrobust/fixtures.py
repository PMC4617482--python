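"""Closed-form fixture models and analytic density pairs.

Fixtures expose the same evaluation surface as ODE models (an evaluation
map from parameter rows to scalars) but skip numerical integration, so
every pipeline stage can be exercised quickly against known answers: which
parameters drive the output, in which direction, and what MIRI ordering to
expect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import norm

from .core import ConditionalDensity
from .sampling import ParameterSpace, build_parameter_space

__all__ = [
    "FixtureModel",
    "make_identity_fixture",
    "make_linear_fixture",
    "gaussian_density_pair",
]


@dataclass(frozen=True)
class FixtureModel:
    """A model whose evaluation map z = g(p) is a known closed form.

    ``evaluate_matrix`` maps an (N, q) sample matrix to N evaluation values;
    ``driving_parameters`` documents which parameters influence z (in
    expected descending MIRI order).
    """

    name: str
    space: ParameterSpace
    map_fn: Callable[[np.ndarray], np.ndarray]
    driving_parameters: tuple[str, ...] = ()

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return self.space.names

    def evaluate_matrix(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
        return np.asarray(self.map_fn(matrix), dtype=float).reshape(matrix.shape[0])


def _unit_box(q: int) -> ParameterSpace:
    # essentially the [0, 1] box, with a strictly positive lower bound
    return ParameterSpace(
        names=tuple(f"p{i+1}" for i in range(q)),
        nominal=np.full(q, 0.5),
        lower=np.full(q, 1e-9),
        upper=np.full(q, 1.0),
        scale=("linear",) * q,
    )


def make_identity_fixture(q: int, driving_index: int = 1) -> FixtureModel:
    """z = p_j on the unit box; every other parameter is inert.

    The driving parameter's upper/lower conditional marginals are the top
    and bottom alpha-slices of its range (MIRI near 2), while inert
    parameters stay uniform under both conditionings (MIRI near 0).
    """
    if not 1 <= driving_index <= q:
        raise ValueError("driving_index must lie in 1..q")
    j = driving_index - 1
    space = _unit_box(q)
    return FixtureModel(
        name=f"identity{q}",
        space=space,
        map_fn=lambda m: m[:, j],
        driving_parameters=(space.names[j],),
    )


def make_linear_fixture(weights) -> FixtureModel:
    """z = sum_i w_i p_i on the unit box.

    A larger |w_i| produces a larger shift between the conditional marginals
    of p_i, hence a larger MIRI; a negative weight swaps which tail of p_i
    the upper output set favors.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0 or not np.any(w != 0):
        raise ValueError("weights must be a 1-D vector with a nonzero entry")
    space = _unit_box(w.size)
    order = np.argsort(-np.abs(w), kind="stable")
    driving = tuple(space.names[i] for i in order if w[i] != 0)
    return FixtureModel(
        name=f"linear{w.size}",
        space=space,
        map_fn=lambda m: m @ w,
        driving_parameters=driving,
    )


def gaussian_density_pair(
    mu1: float, mu2: float, sigma: float, grid_size: int = 4096,
    half_width: float = 8.0,
) -> tuple[ConditionalDensity, ConditionalDensity]:
    """Exact normal pdfs N(mu1, sigma^2) and N(mu2, sigma^2) on a shared
    grid — an analytic oracle for the MIRI quadrature (bypasses the KDE).

    The closed-form L1 distance is 2 * (2 * Phi(|mu2 - mu1| / (2 sigma)) - 1).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    lo = min(mu1, mu2) - half_width * sigma
    hi = max(mu1, mu2) + half_width * sigma
    grid = np.linspace(lo, hi, grid_size)
    make = lambda mu, src: ConditionalDensity(
        grid=grid, density=norm.pdf(grid, loc=mu, scale=sigma),
        bandwidth=sigma, parameter="analytic", source=src)
    return make(mu1, "U"), make(mu2, "L")
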