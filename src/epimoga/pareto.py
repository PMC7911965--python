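"""Pareto dominance, nondominated-set extraction and fitness assignment.

Both objectives are minimised. Solution a dominates b when a is no worse
than b on both objectives and strictly better on at least one; ties on both
objectives leave the pair mutually nondominated.

Fitness for roulette selection: dominated members get 1; each nondominated
member gets 2 + 2*d, where d is the number of members it dominates. This is
order-independent while preserving the intended selection pressure (a
nondominated solution is credited for every solution it beats).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .objectives import ObjectivePair


@dataclass
class FitnessVector:
    """Per-member selection weights; 1 marks a dominated solution."""

    values: list[int]

    def __post_init__(self) -> None:
        if any(v < 1 for v in self.values):
            raise ValueError("fitness values must be >= 1")

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def dominates(a: ObjectivePair, b: ObjectivePair) -> bool:
    """True iff a Pareto-dominates b (minimisation on both objectives)."""
    return (a.k2 <= b.k2 and a.gini <= b.gini) and (a.k2 < b.k2 or a.gini < b.gini)


def _objective_matrix(pairs: Sequence[ObjectivePair]) -> np.ndarray:
    return np.asarray([(p.k2, p.gini) for p in pairs], dtype=float).reshape(-1, 2)


def dominance_matrix(f: np.ndarray) -> np.ndarray:
    """Boolean matrix D with D[i, j] = row i dominates row j."""
    le = (f[:, None, :] <= f[None, :, :]).all(axis=-1)
    lt = (f[:, None, :] < f[None, :, :]).any(axis=-1)
    return le & lt


def nondominated_mask(f: np.ndarray) -> np.ndarray:
    """Boolean mask of rows not dominated by any other row."""
    if len(f) == 0:
        return np.zeros(0, dtype=bool)
    return ~dominance_matrix(f).any(axis=0)


def nondominated_set(pairs: Sequence[ObjectivePair]) -> set[int]:
    """Indices of the Pareto-maximal (nondominated) objective points."""
    return set(np.nonzero(nondominated_mask(_objective_matrix(pairs)))[0].tolist())


def assign_fitness(pairs: Sequence[ObjectivePair]) -> FitnessVector:
    """Domination-count fitness: 1 if dominated, else 2 + 2*(number dominated)."""
    f = _objective_matrix(pairs)
    if len(f) == 0:
        return FitnessVector([])
    d = dominance_matrix(f)
    dominated = d.any(axis=0)
    values = np.where(dominated, 1, 2 + 2 * d.sum(axis=1))
    return FitnessVector(values.astype(int).tolist())
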