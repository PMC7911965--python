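"""Scoring detector output against simulation ground truth.

Across a collection of replicate datasets, each with one embedded
functional combination:

* Power = DT / D, the fraction of datasets whose elite set contains the
  truth (exact canonical match; a near-miss sharing one SNP counts as a
  miss).
* recall / precision / F_measure are micro-averaged over the pooled
  per-dataset counts: TP (elite members equal to the truth, 0 or 1 per
  dataset), FP (all other elite members), FN (1 - TP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .search import EliteSet, GAConfig, SNPCombination


def n_combinations(n_snps: int, k: int) -> int:
    """Size of the K-order candidate universe, C(n_snps, k)."""
    return math.comb(n_snps, k)


@dataclass
class EvaluationResult:
    """Pooled detection metrics over a dataset collection.

    Ratios with a zero denominator are ``None`` (undefined), never 0.
    """

    d: int
    dt: int
    tp: int
    fp: int
    fn: int
    power: float
    recall: float | None
    precision: float | None
    f_measure: float | None


def match_truth(elite: EliteSet, truth: SNPCombination | Sequence[int]) -> bool:
    """True iff some elite member equals the truth as an unordered SNP set."""
    return elite.contains(truth)


def evaluate_collection(
    results: Iterable[tuple[EliteSet, SNPCombination]]
) -> EvaluationResult:
    """Micro-averaged Power/recall/precision/F over (elite, truth) pairs."""
    results = list(results)
    if not results:
        raise ValueError("cannot evaluate an empty collection")
    d = len(results)
    dt = tp = fp = fn = 0
    for elite, truth in results:
        hit = match_truth(elite, truth)
        dt += int(hit)
        tp += int(hit)
        fp += len(elite) - int(hit)
        fn += 1 - int(hit)

    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    if recall and precision:
        f_measure = 2.0 / (1.0 / precision + 1.0 / recall)
    elif recall == 0.0 or precision == 0.0:
        f_measure = 0.0 if (recall is not None and precision is not None) else None
    else:
        f_measure = None
    return EvaluationResult(
        d=d, dt=dt, tp=tp, fp=fp, fn=fn,
        power=dt / d, recall=recall, precision=precision, f_measure=f_measure,
    )


def power_experiment(
    model_id: str = "DME2",
    maf: float = 0.1,
    h2: float = 0.05,
    prevalence: float = 0.2,
    n_cases: int = 400,
    n_controls: int = 400,
    n_snps: int = 100,
    replicates: int = 30,
    cfg: GAConfig | None = None,
    master_seed: int = 0,
) -> EvaluationResult:
    """Full simulation study for one setting: simulate, detect, evaluate.

    Generates ``replicates`` independent datasets embedding one calibrated
    2-locus model, runs the detector on each, and pools the detection
    metrics. Each replicate derives its data stream and its search seed
    from ``master_seed`` so the whole experiment is reproducible.
    """
    from .search import EpiMOGA
    from .simulate import build_dme_model, build_dnme_model, simulate_dataset

    if cfg is None:
        cfg = GAConfig()
    results = []
    for rep in range(replicates):
        ss = np.random.SeedSequence([master_seed, rep])
        rng = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))
        if model_id.upper() == "DNME":
            model = build_dnme_model(maf, h2, prevalence, rng)
        else:
            model = build_dme_model(model_id.upper(), maf, h2, prevalence)
        ds, truth = simulate_dataset(model, n_cases, n_controls, n_snps, rng)
        search_seed = int(ss.generate_state(1)[0] % (2**31))
        res = EpiMOGA(ds, cfg, seed=search_seed).fit()
        results.append((res.elite, truth))
    return evaluate_collection(results)
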