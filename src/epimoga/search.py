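"""The multi-objective genetic-algorithm epistasis detector.

A candidate K-order epistasis model is a chromosome of K distinct SNP
indices. Each of ``num`` independent searches evolves a population of
``ps`` chromosomes for ``maxtimes`` generations with roulette selection on
domination-count fitness, one-point crossover, simple mutation, and
validity repair (no duplicate loci within a chromosome, no duplicate
chromosomes within a population). Every generation's nondominated members
are archived; the archives of all searches are merged and reduced to their
Pareto-nondominated subset — the elite set, the detector's output.

The statsmodels-flavoured entry point is :class:`EpiMOGA`::

    model = EpiMOGA(dataset, k=2, seed=7)
    res = model.fit()
    print(res.summary())

with :func:`detect` kept as the equivalent functional API.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeDataset
from .objectives import ObjectiveEngine, ObjectivePair
from .pareto import FitnessVector, dominance_matrix, nondominated_mask


@dataclass(frozen=True)
class SNPCombination:
    """An ordered tuple of K distinct 1-based SNP indices (a GA chromosome)."""

    loci: tuple[int, ...]

    def __post_init__(self) -> None:
        loci = tuple(int(i) for i in self.loci)
        object.__setattr__(self, "loci", loci)
        if len(loci) == 0:
            raise ValueError("a combination needs at least one locus")
        if len(set(loci)) != len(loci):
            raise ValueError(f"duplicate loci in combination {loci}")
        if min(loci) < 1:
            raise ValueError(f"loci are 1-based, got {loci}")

    @property
    def k(self) -> int:
        return len(self.loci)

    @property
    def canonical(self) -> tuple[int, ...]:
        """Sorted loci — a SNP set is unordered and both objectives agree."""
        return tuple(sorted(self.loci))


@dataclass
class GAConfig:
    """Search hyper-parameters.

    Defaults follow the published setting: population size 50, crossover
    probability 0.6, mutation probability 0.01, 60 independent searches;
    100 generations per search.
    """

    k: int = 2
    ps: int = 50
    pc: float = 0.6
    pm: float = 0.01
    num: int = 60
    maxtimes: int = 100
    seed: int = 0
    retry_budget: int = 10

    def __post_init__(self) -> None:
        if not (0.0 <= self.pc <= 1.0 and 0.0 <= self.pm <= 1.0):
            raise ValueError("pc and pm must lie in [0, 1]")
        if self.ps < 2 or self.num < 1 or self.maxtimes < 1 or self.k < 1:
            raise ValueError("require ps >= 2, num >= 1, maxtimes >= 1, k >= 1")
        if self.retry_budget < 0:
            raise ValueError("retry_budget must be >= 0")


@dataclass
class EliteSet:
    """Mutually nondominated, duplicate-free combinations with their scores."""

    combinations: list[SNPCombination]
    objectives: list[ObjectivePair]

    def __len__(self) -> int:
        return len(self.combinations)

    def __iter__(self):
        return iter(zip(self.combinations, self.objectives))

    def contains(self, combo: SNPCombination | Sequence[int]) -> bool:
        if not isinstance(combo, SNPCombination):
            combo = SNPCombination(tuple(combo))
        target = combo.canonical
        return any(c.canonical == target for c in self.combinations)


@dataclass
class Population:
    """A generation of the GA: ``ps`` canonically distinct chromosomes."""

    members: list[SNPCombination]
    objectives: list[ObjectivePair] | None = None

    def __post_init__(self) -> None:
        canon = [m.canonical for m in self.members]
        if len(set(canon)) != len(canon):
            raise ValueError("duplicate chromosomes (canonical form) in population")


# ---------------------------------------------------------------------------
# low-level operators on plain tuples (1-based loci); the public API wraps
# them in SNPCombination for per-call use, the search loop calls them directly
# ---------------------------------------------------------------------------

def _draw_chromosome(n: int, k: int, rng: np.random.Generator) -> tuple[int, ...]:
    return tuple(int(v) + 1 for v in rng.choice(n, size=k, replace=False))


def _crossover_tuples(p1, p2, pc, retry_budget, rng):
    k = len(p1)
    if rng.random() >= pc:
        return p1, p2
    for _ in range(retry_budget + 1):
        cpoint = int(np.round(rng.random() * k))
        c1 = p1[:cpoint] + p2[cpoint:]
        c2 = p2[:cpoint] + p1[cpoint:]
        if len(set(c1)) == k and len(set(c2)) == k:
            return c1, c2
    return p1, p2  # repair exhausted: parents pass through


def _mutate_tuple(x, n, pm, retry_budget, rng):
    k = len(x)
    if rng.random() >= pm:
        return x
    # u open at 0 so ceil(u*K) lands in 1..K and ceil(v*N) in 1..N
    mpoint = math.ceil((1.0 - rng.random()) * k) - 1
    others = set(x) - {x[mpoint]}
    for _ in range(retry_budget + 1):
        val = math.ceil((1.0 - rng.random()) * n)
        if val not in others:
            return x[:mpoint] + (val,) + x[mpoint + 1:]
    return x


def initialize_population(
    n: int, cfg: GAConfig, rng: np.random.Generator
) -> Population:
    """Draw ``ps`` valid, canonically distinct random chromosomes over 1..n."""
    k, ps = cfg.k, cfg.ps
    if n <= k:
        raise ValueError(f"need more SNPs ({n}) than the combination order ({k})")
    total = math.comb(n, k)
    if ps > total:
        raise ValueError(f"population size {ps} exceeds the {total} distinct {k}-subsets")
    members = [SNPCombination(t) for t in _init_tuples(n, k, ps, rng)]
    return Population(members)


def _init_tuples(n, k, ps, rng) -> list[tuple[int, ...]]:
    total = math.comb(n, k)
    if total <= 4 * ps:
        # near-exhaustion: enumerate, shuffle, take ps
        from itertools import combinations

        allc = list(combinations(range(1, n + 1), k))
        idx = rng.permutation(total)[:ps]
        return [allc[i] for i in idx]
    out: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    while len(out) < ps:
        t = _draw_chromosome(n, k, rng)
        key = tuple(sorted(t))
        if key not in seen:
            seen.add(key)
            out.append(t)
    return out


def roulette_select(fitness: FitnessVector, rng: np.random.Generator) -> int:
    """Sample one member index with probability proportional to its fitness."""
    if len(fitness) == 0:
        raise ValueError("cannot select from an empty fitness vector")
    w = fitness.as_array()
    return int(rng.choice(len(w), p=w / w.sum()))


def one_point_crossover(
    x1: SNPCombination,
    x2: SNPCombination,
    cfg: GAConfig,
    rng: np.random.Generator,
) -> tuple[SNPCombination, SNPCombination]:
    """With probability pc, swap the suffixes after a random cut point.

    The cut point is round(u*K), u ~ U(0,1), so an empty swap (0 or K) is
    possible. Offspring with duplicated loci trigger a redraw of the cut
    point, up to ``retry_budget`` times, after which the parents pass
    through unchanged.
    """
    if x1.k != x2.k:
        raise ValueError(f"mismatched combination orders {x1.k} vs {x2.k}")
    c1, c2 = _crossover_tuples(x1.loci, x2.loci, cfg.pc, cfg.retry_budget, rng)
    return SNPCombination(c1), SNPCombination(c2)


def simple_mutation(
    x: SNPCombination, n: int, cfg: GAConfig, rng: np.random.Generator
) -> SNPCombination:
    """With probability pm, replace the locus at position ceil(u*K) by
    ceil(v*N), redrawing v while it would duplicate another locus."""
    return SNPCombination(_mutate_tuple(x.loci, n, cfg.pm, cfg.retry_budget, rng))


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

def _run_search_tuples(
    engine: ObjectiveEngine,
    cfg: GAConfig,
    rng: np.random.Generator,
) -> dict[tuple[int, ...], ObjectivePair]:
    """One GA run; returns its candidate archive keyed by canonical loci."""
    n = engine.ds.n_snps
    k, ps = cfg.k, cfg.ps
    pop = _init_tuples(n, k, ps, rng)
    canon = [tuple(sorted(t)) for t in pop]
    archive: dict[tuple[int, ...], ObjectivePair] = {}

    for gen in range(cfg.maxtimes):
        scores = [engine.score(c) for c in canon]
        f = np.asarray(scores, dtype=float)
        dom = dominance_matrix(f)
        dominated = dom.any(axis=0)
        for i in np.nonzero(~dominated)[0]:
            archive[canon[i]] = scores[i]
        if gen == cfg.maxtimes - 1:
            break

        fitness = np.where(dominated, 1, 2 + 2 * dom.sum(axis=1)).astype(float)
        parents_idx = rng.choice(ps, size=ps, p=fitness / fitness.sum())

        children: list[tuple[int, ...]] = []
        i = 0
        while i + 1 < ps:
            c1, c2 = _crossover_tuples(
                pop[parents_idx[i]], pop[parents_idx[i + 1]],
                cfg.pc, cfg.retry_budget, rng,
            )
            children.append(c1)
            children.append(c2)
            i += 2
        if i < ps:  # odd remainder passes through
            children.append(pop[parents_idx[i]])

        children = [
            _mutate_tuple(c, n, cfg.pm, cfg.retry_budget, rng) for c in children
        ]

        # uniqueness sweep: residual duplicates replaced by fresh chromosomes
        seen: set[tuple[int, ...]] = set()
        next_pop: list[tuple[int, ...]] = []
        next_canon: list[tuple[int, ...]] = []
        for c in children:
            key = tuple(sorted(c))
            while key in seen:
                c = _draw_chromosome(n, k, rng)
                key = tuple(sorted(c))
            seen.add(key)
            next_pop.append(c)
            next_canon.append(key)
        pop, canon = next_pop, next_canon

    # reduce the run archive to its nondominated subset
    return _nondominated_dict(archive)


def _nondominated_dict(
    archive: dict[tuple[int, ...], ObjectivePair]
) -> dict[tuple[int, ...], ObjectivePair]:
    if not archive:
        return {}
    keys = list(archive)
    f = np.asarray([archive[key] for key in keys], dtype=float)
    mask = nondominated_mask(f)
    return {keys[i]: archive[keys[i]] for i in np.nonzero(mask)[0]}


def run_search(
    ds: GenotypeDataset,
    cfg: GAConfig,
    rng: np.random.Generator,
    engine: ObjectiveEngine | None = None,
) -> list[tuple[SNPCombination, ObjectivePair]]:
    """Run one independent GA search and return its candidate archive.

    The archive is the union over generations of each generation's
    nondominated members, reduced to its own nondominated subset.
    """
    _check_two_classes(ds)
    if engine is None:
        engine = ObjectiveEngine(ds)
    archive = _run_search_tuples(engine, cfg, rng)
    items = sorted(archive.items(), key=lambda kv: (kv[1].k2, kv[1].gini, kv[0]))
    return [(SNPCombination(key), pair) for key, pair in items]


def _check_two_classes(ds: GenotypeDataset) -> None:
    if ds.n_cases == 0 or ds.n_controls == 0:
        raise ValueError("dataset must contain at least one case and one control")


def detect(ds: GenotypeDataset, cfg: GAConfig | None = None, **kwargs) -> EliteSet:
    """Full detector: ``num`` independent searches, merged and Pareto-screened."""
    return EpiMOGA(ds, cfg, **kwargs).fit().elite


class EpiMOGA:
    """Multi-objective GA epistasis model for a case-control dataset.

    Parameters
    ----------
    dataset : GenotypeDataset
    config : GAConfig, optional
        Full search configuration; individual fields may instead be given
        as keyword arguments (``k``, ``ps``, ``pc``, ``pm``, ``num``,
        ``maxtimes``, ``seed``, ``retry_budget``).

    Examples
    --------
    >>> model = EpiMOGA(dataset, k=2, num=60, seed=7)
    >>> res = model.fit()
    >>> res.to_frame().head()
    """

    def __init__(self, dataset: GenotypeDataset, config: GAConfig | None = None, **kwargs):
        _check_two_classes(dataset)
        if config is None:
            config = GAConfig(**kwargs)
        elif kwargs:
            config = replace(config, **kwargs)
        if dataset.n_snps <= config.k:
            raise ValueError("dataset has too few SNPs for the requested order")
        self.dataset = dataset
        self.config = config

    def fit(self, seed: int | None = None) -> "EpiMOGAResults":
        """Run the full search and return the fitted results.

        The master seed spawns ``num`` independent sub-streams, one per
        search; given (dataset, config) the result is deterministic.
        """
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        ss = np.random.SeedSequence(cfg.seed)
        streams = ss.spawn(cfg.num + 1)  # one per run + one for orchestration
        engine = ObjectiveEngine(self.dataset)

        merged: dict[tuple[int, ...], ObjectivePair] = {}
        archive_sizes: list[int] = []
        for child in streams[: cfg.num]:
            rng = np.random.Generator(np.random.PCG64(child))
            run_archive = _run_search_tuples(engine, cfg, rng)
            archive_sizes.append(len(run_archive))
            merged.update(run_archive)

        elite_dict = _nondominated_dict(merged)
        order = sorted(elite_dict, key=lambda key: (elite_dict[key].k2, elite_dict[key].gini, key))
        elite = EliteSet(
            combinations=[SNPCombination(key) for key in order],
            objectives=[elite_dict[key] for key in order],
        )
        return EpiMOGAResults(self, cfg, elite, engine.visited, archive_sizes)


@dataclass
class EpiMOGAResults:
    """Results of a fitted :class:`EpiMOGA` search.

    Attributes
    ----------
    elite : EliteSet
        The Pareto-nondominated candidate combinations — the detection result.
    visited : frozenset of tuple
        Every canonical combination the search scored (the explored part of
        the search space).
    archive_sizes : list of int
        Candidate-archive size of each independent search.
    """

    model: EpiMOGA
    config: GAConfig
    elite: EliteSet
    visited: frozenset
    archive_sizes: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Elite set as a DataFrame: 1-based indices, SNP names, K2, Gini."""
        names = self.model.dataset.snp_names
        k = self.config.k
        rows = []
        for combo, pair in self.elite:
            loci = combo.canonical
            row = {f"locus{t + 1}": loci[t] for t in range(k)}
            row.update({f"snp{t + 1}": names[loci[t] - 1] for t in range(k)})
            row["k2"] = pair.k2
            row["gini"] = pair.gini
            rows.append(row)
        cols = (
            [f"locus{t + 1}" for t in range(k)]
            + [f"snp{t + 1}" for t in range(k)]
            + ["k2", "gini"]
        )
        return pd.DataFrame(rows, columns=cols)

    def save_elite(self, path) -> None:
        """Write the elite set as a deterministic TSV (round-trippable)."""
        df = self.to_frame()
        df["k2"] = df["k2"].map(lambda v: f"{v:.12g}")
        df["gini"] = df["gini"].map(lambda v: f"{v:.12g}")
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")

    def posthoc(self, alpha: float = 0.001) -> pd.DataFrame:
        """Chi-square screen of the elite set (see :func:`epimoga.qc.posthoc_filter`)."""
        from .qc import posthoc_filter

        return posthoc_filter(self.elite, self.model.dataset, alpha=alpha)

    def summary(self) -> str:
        """Plain-text summary table of the fitted search."""
        cfg = self.config
        ds = self.model.dataset
        head = (
            f"EpiMOGA epistasis search (order K={cfg.k})\n"
            f"{'=' * 60}\n"
            f"Samples: {ds.n_samples} ({ds.n_cases} cases / {ds.n_controls} controls)"
            f"    SNPs: {ds.n_snps}\n"
            f"Searches: {cfg.num} x {cfg.maxtimes} generations, "
            f"Ps={cfg.ps}, Pc={cfg.pc}, Pm={cfg.pm}, seed={cfg.seed}\n"
            f"Combinations scored: {len(self.visited)}"
            f"    Elite set size: {len(self.elite)}\n"
            f"{'-' * 60}\n"
        )
        df = self.to_frame()
        with pd.option_context("display.width", 120, "display.max_rows", 50):
            body = df.to_string(index=False, float_format=lambda v: f"{v:.6g}")
        return head + body
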