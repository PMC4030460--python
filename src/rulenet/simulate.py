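"""Simulated binary datasets with correlated and interacting features.

Each dataset has a binary decision ``DEC`` drawn uniformly, a block of
features *correlated* with the decision, and a block of feature *pairs*
that are jointly predictive of the decision while each member is
marginally uncorrelated with it — the epistasis-like situation where an
interaction effect exists without marginal effects.

With ``n_correlated = 5`` correlated features and ``n_pairs = 5`` pairs
(the defaults), feature ``C_i`` has expected phi correlation
``c = X * i / 4`` with the decision, and pair ``(R_i, S_i)`` is
informative with probability ``p = Y * i / 4``: with probability ``p``
the pair is set so that equal values mean ``DEC = 1`` and opposite
values mean ``DEC = 0``; otherwise ``S_i`` is random.  Feature names
carry the level as a rounded integer percent (half-up), e.g. ``C3_11``
for c = 11.25% and ``R4_10`` for p = 10%.

The per-object generative algorithm, with ``Random()`` a fair 0/1 draw
and ``Probability(q)`` a Bernoulli(q) event:

* ``DEC = Random()``
* for each correlated feature at level c:
  ``value = DEC if Probability(c) else Random()``
  (so ``P(value = DEC) = c + (1 - c)/2`` and the phi correlation is c)
* for each pair at level p: ``R = Random()``; if ``Probability(p)``
  then ``S = R`` when ``DEC = 1`` and ``S = 1 - R`` when ``DEC = 0``,
  else ``S = Random()``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .rules import DecisionTable

__all__ = [
    "SimulationParams",
    "SimulatedDataset",
    "generate_dataset",
    "generate_grid",
]

DECISION_NAME = "DEC"


def _percent(level: float) -> int:
    # round half-up to integer percent: 11.25 -> 11, 3.75 -> 4, 2.5 -> 3
    return int(math.floor(level * 100 + 0.5))


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulated dataset.

    ``X`` is the maximal correlation level and ``Y`` the maximal pair
    predictivity; feature ``i`` (0-based) gets level ``max * i / (m-1)``
    where ``m`` is the number of correlated features or pairs.
    """

    X: float
    Y: float
    n_objects: int = 1000
    n_correlated: int = 5
    n_pairs: int = 5
    seed: int | tuple[int, ...] = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.X <= 1.0 or not 0.0 <= self.Y <= 1.0:
            raise ValueError("X and Y must lie in [0, 1]")
        if self.n_objects < 1:
            raise ValueError("n_objects must be positive")
        if self.n_correlated < 1 or self.n_pairs < 1:
            raise ValueError("n_correlated and n_pairs must be positive")

    @property
    def correlation_levels(self) -> tuple[float, ...]:
        m = self.n_correlated
        return tuple(self.X * i / (m - 1) if m > 1 else self.X for i in range(m))

    @property
    def predictivity_levels(self) -> tuple[float, ...]:
        m = self.n_pairs
        return tuple(self.Y * i / (m - 1) if m > 1 else self.Y for i in range(m))


@dataclass
class SimulatedDataset:
    """A generated binary decision table plus its generating parameters."""

    table: DecisionTable
    params: SimulationParams
    replicate: int = 0

    @property
    def correlated_features(self) -> list[str]:
        return self.table.features[: self.params.n_correlated]

    @property
    def pair_features(self) -> list[tuple[str, str]]:
        rest = self.table.features[self.params.n_correlated :]
        return [(rest[2 * i], rest[2 * i + 1]) for i in range(self.params.n_pairs)]


def generate_dataset(params: SimulationParams) -> SimulatedDataset:
    """Generate one dataset; deterministic for a given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n = params.n_objects
    dec = rng.integers(0, 2, n)
    cols: dict[str, np.ndarray] = {}
    for i, c in enumerate(params.correlation_levels):
        informed = rng.random(n) < c
        cols[f"C{i}_{_percent(c)}"] = np.where(informed, dec, rng.integers(0, 2, n))
    for i, p in enumerate(params.predictivity_levels):
        r = rng.integers(0, 2, n)
        informed = rng.random(n) < p
        s = np.where(informed, np.where(dec == 1, r, 1 - r), rng.integers(0, 2, n))
        cols[f"R{i}_{_percent(p)}"] = r
        cols[f"S{i}_{_percent(p)}"] = s
    cols[DECISION_NAME] = dec
    df = pd.DataFrame(cols).astype(str)
    return SimulatedDataset(DecisionTable(df, DECISION_NAME), params)


def generate_grid(
    X_values: Sequence[float],
    Y_values: Sequence[float],
    replicates: int = 1,
    n_objects: int = 1000,
    base_seed: int = 0,
) -> Iterator[SimulatedDataset]:
    """Yield datasets over the (X, Y) grid with replicates.

    Produces ``len(X_values) * len(Y_values) * replicates`` datasets.
    Replicate ``r`` of grid cell ``(xi, yi)`` uses the seed sequence
    ``(base_seed, xi, yi, r)``, so every cell is independently and
    reproducibly seeded.
    """
    if not len(X_values) or not len(Y_values):
        raise ValueError("X_values and Y_values must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be positive")
    for xi, x in enumerate(X_values):
        for yi, y in enumerate(Y_values):
            for r in range(replicates):
                params = SimulationParams(
                    X=x, Y=y, n_objects=n_objects, seed=(base_seed, xi, yi, r)
                )
                ds = generate_dataset(params)
                ds.replicate = r
                yield ds
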