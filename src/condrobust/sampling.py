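"""Parameter spaces with multiplicative bounds and Latin hypercube sampling.

The parameter space is the axis-aligned box obtained by scaling each nominal
(wild-type) value by a lower and an upper multiplicative factor; the implied
prior over the box is uniform.  Sampling uses Latin hypercube draws with
linearly spaced strata (one equal-width stratum per sample and dimension,
a uniform draw inside each stratum, independent stratum permutations per
dimension); an optional log scale stratifies equally in log space instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

__all__ = [
    "ParameterSpace",
    "SampleSet",
    "build_parameter_space",
    "sample_l2hs",
    "extend_with_initial_conditions",
    "realization_seed",
]


@dataclass(frozen=True)
class ParameterSpace:
    """Box of admissible parameter values with a uniform prior.

    Bounds are multiplicative: ``lower[i] = lower_factor[i] * nominal[i]``
    and ``upper[i] = upper_factor[i] * nominal[i]``.
    """

    names: tuple[str, ...]
    nominal: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    scale: tuple[str, ...]

    def __post_init__(self):
        q = len(self.names)
        for arr in (self.nominal, self.lower, self.upper):
            if arr.shape != (q,):
                raise ValueError("space arrays must all have length q")
        if np.any(self.nominal <= 0):
            raise ValueError("nominal values must be positive")
        if np.any(self.lower <= 0):
            raise ValueError("lower bounds must be positive")
        if np.any(self.lower >= self.upper):
            raise ValueError("degenerate box: lower bound must be < upper bound")
        if any(s not in ("linear", "log") for s in self.scale):
            raise ValueError("scale entries must be 'linear' or 'log'")
        if len(set(self.names)) != q:
            raise ValueError("parameter names must be unique")

    @property
    def dim(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def bounds(self, name: str) -> tuple[float, float]:
        i = self.index(name)
        return float(self.lower[i]), float(self.upper[i])

    def subspace(self, names: Sequence[str]) -> "ParameterSpace":
        idx = [self.index(n) for n in names]
        return ParameterSpace(
            names=tuple(names),
            nominal=self.nominal[idx],
            lower=self.lower[idx],
            upper=self.upper[idx],
            scale=tuple(self.scale[i] for i in idx),
        )


@dataclass(frozen=True)
class SampleSet:
    """An N x q matrix of parameter draws aligned with a ParameterSpace."""

    space: ParameterSpace
    matrix: np.ndarray
    seed: int
    method: str = "l2hs"

    def __post_init__(self):
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.space.dim:
            raise ValueError("matrix must be N x q for the given space")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.space.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(self.space.names))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def with_fixed_columns(self, fixed: Mapping[str, float]) -> "SampleSet":
        """Copy with the named columns pinned to constant values."""
        matrix = self.matrix.copy()
        for name, value in fixed.items():
            lo, hi = self.space.bounds(name)
            if not lo <= value <= hi:
                raise ValueError(f"fixed value {value} for {name!r} outside [{lo}, {hi}]")
            matrix[:, self.space.index(name)] = value
        return SampleSet(space=self.space, matrix=matrix, seed=self.seed,
                         method=self.method)


def build_parameter_space(
    nominal: Mapping[str, float] | Sequence[float],
    lower_factor: float | Sequence[float] = 0.1,
    upper_factor: float | Sequence[float] = 10.0,
    scale: str | Sequence[str] = "linear",
    names: Sequence[str] | None = None,
) -> ParameterSpace:
    """Build a multiplicative-bounds box around nominal values.

    Defaults follow the factor-10 convention (bounds one decade below and
    above the wild-type value).  ``nominal`` may be a mapping name -> value
    or a plain sequence with ``names`` given separately.
    """
    if isinstance(nominal, Mapping):
        names = tuple(nominal)
        values = np.array([nominal[n] for n in names], dtype=float)
    else:
        values = np.asarray(nominal, dtype=float)
        names = tuple(names) if names is not None else tuple(
            f"p{i+1}" for i in range(values.size))
    q = values.size
    lf = np.broadcast_to(np.asarray(lower_factor, dtype=float), (q,))
    uf = np.broadcast_to(np.asarray(upper_factor, dtype=float), (q,))
    if np.any(lf <= 0) or np.any(lf >= uf):
        raise ValueError("factors must satisfy 0 < lower_factor < upper_factor")
    if isinstance(scale, str):
        scale = (scale,) * q
    return ParameterSpace(
        names=names,
        nominal=values,
        lower=lf * values,
        upper=uf * values,
        scale=tuple(scale),
    )


def sample_l2hs(
    space: ParameterSpace, n: int, seed: int, midpoint: bool = False
) -> SampleSet:
    """Latin hypercube draw with linearly spaced strata (L2HS).

    Each column gets exactly one point in each of the ``n`` equal-width
    strata of its bounds (equal width in log space for log-scaled
    parameters), placed uniformly at random within the stratum (stratum
    midpoints when ``midpoint`` is set, for debugging).  Reproducible from
    ``seed``.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    sampler = qmc.LatinHypercube(
        d=space.dim, scramble=not midpoint, rng=np.random.default_rng(seed)
    )
    unit = sampler.random(n=n)
    lo, hi = space.lower.copy(), space.upper.copy()
    log_mask = np.array([s == "log" for s in space.scale])
    lo[log_mask] = np.log(lo[log_mask])
    hi[log_mask] = np.log(hi[log_mask])
    matrix = qmc.scale(unit, lo, hi)
    matrix[:, log_mask] = np.exp(matrix[:, log_mask])
    return SampleSet(space=space, matrix=matrix, seed=seed)


def extend_with_initial_conditions(
    space: ParameterSpace,
    ic_names: Sequence[str],
    ic_nominal: Sequence[float],
    lower_factor: float | Sequence[float] = 0.1,
    upper_factor: float | Sequence[float] = 10.0,
    scale: str | Sequence[str] = "linear",
) -> ParameterSpace:
    """Append initial-condition dimensions so they are sampled jointly with
    the kinetic parameters (e.g. the receptor space over x1_0, x2_0)."""
    dupes = set(ic_names) & set(space.names)
    if dupes:
        raise ValueError(f"initial-condition names already in space: {sorted(dupes)}")
    extra = build_parameter_space(
        np.asarray(ic_nominal, dtype=float), lower_factor, upper_factor,
        scale, names=ic_names,
    )
    return ParameterSpace(
        names=space.names + extra.names,
        nominal=np.concatenate([space.nominal, extra.nominal]),
        lower=np.concatenate([space.lower, extra.lower]),
        upper=np.concatenate([space.upper, extra.upper]),
        scale=space.scale + extra.scale,
    )


def realization_seed(base_seed: int, realization: int) -> int:
    """Seed for realization ``r``: base_seed + r (auditable, replayable)."""
    return int(base_seed) + int(realization)
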