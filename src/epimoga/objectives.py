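"""Genotype-combination contingency tables and the two search objectives.

For a K-SNP combination the 3^K joint genotypes are cross-tabulated against
the binary phenotype once; both objectives are then read off that table:

* the K2 score, a Bayesian-network scoring criterion reported here in
  negative natural-log form,

      S = sum_i [ ln((n_i + J - 1)!) - ln((J - 1)!) - sum_j ln(n_ij!) ],

  computed via log-gamma so large counts never overflow; and

* the Gini impurity of the phenotype split induced by the genotype cells,

      G = sum_i (n_i / n) * (1 - sum_j (n_ij / n_i)^2).

Lower is stronger for both: a combination that separates cases from
controls well concentrates each cell on one phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.special import gammaln

from .io import MISSING, GenotypeDataset


class ObjectivePair(NamedTuple):
    """The (K2, Gini) objective point for one SNP combination."""

    k2: float
    gini: float


@dataclass
class ContingencyTable:
    """3^K genotype-combination x 2 phenotype count table.

    ``counts[i, j]`` is the number of samples with mixed-radix base-3 cell
    index i (locus order = combination order) and phenotype j
    (column 0 = control, column 1 = case). Samples missing any of the K
    genotypes are excluded.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 2:
            raise ValueError("counts must have shape (I, 2)")
        if np.any(self.counts < 0):
            raise ValueError("contingency counts must be non-negative")

    @property
    def n_i(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        k = int(round(np.log(self.counts.shape[0]) / np.log(3)))
        if 3**k != self.counts.shape[0]:
            raise ValueError(f"row count {self.counts.shape[0]} is not a power of 3")
        return k


def tabulate(ds: GenotypeDataset, combo: Sequence[int]) -> ContingencyTable:
    """Cross-tabulate the K loci of ``combo`` (1-based indices) vs phenotype.

    The cell index encodes the genotype vector in mixed-radix base 3, with
    the first locus of the combination as the most significant digit.
    """
    loci = tuple(int(i) for i in combo)
    if len(loci) == 0:
        raise ValueError("combination must contain at least one locus")
    if len(set(loci)) != len(loci):
        raise ValueError(f"duplicate locus in combination {loci}")
    if min(loci) < 1 or max(loci) > ds.n_snps:
        raise ValueError(f"locus out of range 1..{ds.n_snps} in {loci}")

    cols = ds.genotypes[:, [i - 1 for i in loci]].astype(np.int64)
    keep = ~(cols == MISSING).any(axis=1)
    cols = cols[keep]
    y = ds.phenotype[keep].astype(np.int64)

    k = len(loci)
    cell = np.zeros(len(cols), dtype=np.int64)
    for t in range(k):
        cell = cell * 3 + cols[:, t]
    counts = np.bincount(cell * 2 + y, minlength=2 * 3**k).reshape(3**k, 2)
    return ContingencyTable(counts)


def k2_score(t: ContingencyTable) -> float:
    """Negative-log K2 score of a table; 0 exactly when the table is empty."""
    counts = t.counts
    n_i = counts.sum(axis=1)
    # J=2: ln((n_i+1)!) - ln(1!) - ln(n_i0!) - ln(n_i1!)
    return float(
        np.sum(gammaln(n_i + 2) - gammaln(counts[:, 0] + 1) - gammaln(counts[:, 1] + 1))
    )


def gini_score(t: ContingencyTable) -> float:
    """Cell-frequency-weighted Gini impurity of the phenotype split, in [0, 0.5]."""
    counts = t.counts
    n_i = counts.sum(axis=1)
    n = n_i.sum()
    if n == 0:
        raise ValueError("Gini impurity is undefined for an empty table")
    nz = n_i > 0
    purity = (counts[nz].astype(float) ** 2).sum(axis=1) / n_i[nz].astype(float) ** 2
    return float(np.sum(n_i[nz] / n * (1.0 - purity)))


def evaluate_objectives(
    ds: GenotypeDataset, combos: Iterable[Sequence[int]]
) -> list[ObjectivePair]:
    """Score each combination with a single tabulation pass per combination."""
    engine = ObjectiveEngine(ds)
    return [engine.score(tuple(int(i) for i in c)) for c in combos]


class ObjectiveEngine:
    """Memoising scorer used by the genetic-algorithm search.

    Scores are cached per canonical (sorted-loci) combination, so the many
    re-visits of a GA cost one dict lookup each. For the common
    no-missing-data case tabulation is a single vectorised bincount.
    """

    def __init__(self, ds: GenotypeDataset):
        self.ds = ds
        self._G = ds.genotypes.astype(np.int64)
        self._y = ds.phenotype.astype(np.int64)
        self._missing = bool(np.any(ds.genotypes == MISSING))
        # ln(k!) lookup for all counts that can occur, incl. n_i + 1
        self._lgfact = gammaln(np.arange(ds.n_samples + 3, dtype=float) + 1.0)
        self._cache: dict[tuple[int, ...], ObjectivePair] = {}

    @property
    def visited(self) -> frozenset[tuple[int, ...]]:
        """Canonical combinations scored so far."""
        return frozenset(self._cache)

    def score(self, loci: tuple[int, ...]) -> ObjectivePair:
        key = tuple(sorted(loci))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        pair = self._score_uncached(key)
        self._cache[key] = pair
        return pair

    def _score_uncached(self, loci: tuple[int, ...]) -> ObjectivePair:
        cols = self._G[:, [i - 1 for i in loci]]
        y = self._y
        if self._missing:
            keep = ~(cols == MISSING).any(axis=1)
            cols = cols[keep]
            y = y[keep]
        k = len(loci)
        cell = cols[:, 0].copy()
        for t in range(1, k):
            cell = cell * 3 + cols[:, t]
        counts = np.bincount(cell * 2 + y, minlength=2 * 3**k).reshape(3**k, 2)

        n_i = counts.sum(axis=1)
        lg = self._lgfact
        k2 = float(np.sum(lg[n_i + 1] - lg[counts[:, 0]] - lg[counts[:, 1]]))
        n = n_i.sum()
        if n == 0:
            raise ValueError("no samples with complete genotypes at these loci")
        nz = n_i > 0
        purity = (counts[nz].astype(float) ** 2).sum(axis=1) / n_i[nz].astype(float) ** 2
        gini = float(np.sum(n_i[nz] / n * (1.0 - purity)))
        return ObjectivePair(k2, gini)
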