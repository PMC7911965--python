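"""Case-control simulator embedding a K-locus epistatic penetrance model.

A penetrance model assigns to each joint genotype g (3^K cells) the disease
probability f_g. Under Hardy-Weinberg equilibrium with per-locus minor
allele frequency m, genotype probabilities are ((1-m)^2, 2m(1-m), m^2);
the model's population summaries are

    prevalence   K* = sum_g p(g) f_g
    heritability h2 = sum_g p(g) (f_g - K*)^2 / (K* (1 - K*))

Four two-locus disease architectures are provided, all calibrated exactly
(by bisection / linear projection) to a requested (MAF, h2, prevalence):

* DME1 -- multiplicative: f = alpha * (1 + theta)^(g1 * g2)
* DME2 -- threshold:      f = alpha * (1 + theta)^[g1 >= 1 and g2 >= 1]
* DME3 -- "concrete":     a fixed XOR-checkerboard, f = alpha * (1 + theta)^((g1 + g2) mod 2)
* DNME -- purely epistatic: a random table whose single-locus marginal
  penetrances all equal the prevalence (no marginal effects), scaled to h2.

Datasets draw case genotypes at the functional loci from p(g) f_g (controls
from p(g) (1 - f_g)); all remaining SNPs are independent HWE noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .io import GenotypeDataset
from .search import SNPCombination

_DME_IDS = ("DME1", "DME2", "DME3")


class InfeasibleModelError(ValueError):
    """No penetrance table in [0, 1] satisfies the requested constraints."""


def hwe_genotype_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities ((1-m)^2, 2m(1-m), m^2)."""
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"minor allele frequency must lie in (0, 0.5], got {maf}")
    q = float(maf)
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def _joint_probs(mafs) -> np.ndarray:
    """Joint HWE genotype probability tensor of shape (3,)*K."""
    probs = hwe_genotype_probs(mafs[0])
    for m in mafs[1:]:
        probs = np.multiply.outer(probs, hwe_genotype_probs(m))
    return probs


@dataclass
class PenetranceModel:
    """K-locus penetrance table with its generative parameters.

    ``table`` has shape (3,)*K; ``table[g1, ..., gK]`` is P(disease | g).
    """

    table: np.ndarray
    mafs: tuple[float, ...]
    prevalence: float
    heritability: float
    model_id: str

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        self.mafs = tuple(float(m) for m in self.mafs)
        if self.table.shape != (3,) * len(self.mafs):
            raise ValueError(
                f"table shape {self.table.shape} does not match {len(self.mafs)} loci"
            )
        if np.any(self.table < 0) or np.any(self.table > 1):
            raise ValueError("penetrances must lie in [0, 1]")

    @property
    def k(self) -> int:
        return len(self.mafs)


def table_statistics(m: PenetranceModel):
    """Realised (prevalence, heritability, per-locus marginal penetrances).

    The marginal penetrance of genotype a at locus t is the conditional
    mean penetrance E[f | g_t = a]; marginals shape is (K, 3).
    """
    p = _joint_probs(m.mafs)
    f = m.table
    prevalence = float(np.sum(p * f))
    if prevalence <= 0.0 or prevalence >= 1.0:
        raise ValueError(
            f"heritability undefined at prevalence {prevalence} (must be in (0,1))"
        )
    h2 = float(np.sum(p * (f - prevalence) ** 2) / (prevalence * (1 - prevalence)))
    k = m.k
    marginals = np.empty((k, 3))
    for t in range(k):
        axes = tuple(a for a in range(k) if a != t)
        num = np.apply_over_axes(np.sum, p * f, axes).reshape(3)
        den = np.apply_over_axes(np.sum, p, axes).reshape(3)
        marginals[t] = num / den
    return prevalence, h2, marginals


def _dme_exponents(model_id: str) -> np.ndarray:
    g = np.arange(3)
    g1, g2 = np.meshgrid(g, g, indexing="ij")
    if model_id == "DME1":
        return (g1 * g2).astype(float)
    if model_id == "DME2":
        return ((g1 >= 1) & (g2 >= 1)).astype(float)
    if model_id == "DME3":
        return ((g1 + g2) % 2).astype(float)
    raise ValueError(f"unknown DME model {model_id!r}; expected one of {_DME_IDS}")


def build_dme_model(
    model_id: str,
    maf: float,
    h2: float,
    prevalence: float,
    tol: float = 1e-12,
) -> PenetranceModel:
    """Calibrate a marginal-effect disease model to (MAF, h2, prevalence).

    Each architecture scales disease odds multiplicatively,
    odds(g) = alpha * (1 + theta)^x(g) with penetrance f = odds/(1 + odds)
    (the standard two-locus interaction parameterisation), so penetrances
    stay inside (0, 1) for any effect size. For a given theta, alpha is
    solved from the prevalence constraint (the prevalence is strictly
    increasing in alpha); theta is then solved by bisection so the realised
    heritability matches h2. Raises :class:`InfeasibleModelError` when the
    requested heritability exceeds what the architecture can express at
    this MAF and prevalence.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("heritability must lie in [0, 1]")
    x = _dme_exponents(model_id)
    p = _joint_probs((maf, maf))

    def table_for(theta: float) -> np.ndarray:
        mult = (1.0 + theta) ** x

        def prev_of(log_alpha: float) -> float:
            odds = np.exp(log_alpha) * mult
            return float(np.sum(p * odds / (1.0 + odds))) - prevalence

        lo, hi = -40.0, 40.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if prev_of(mid) < 0.0:
                lo = mid
            else:
                hi = mid
        odds = np.exp(0.5 * (lo + hi)) * mult
        return odds / (1.0 + odds)

    def h2_of(theta: float) -> float:
        f = table_for(theta)
        return float(np.sum(p * (f - prevalence) ** 2) / (prevalence * (1 - prevalence)))

    if h2 == 0.0:
        return PenetranceModel(table_for(0.0), (maf, maf), prevalence, h2, model_id)

    hi_b = 1.0
    while h2_of(hi_b) < h2:
        hi_b *= 2.0
        if hi_b > 1e9:
            raise InfeasibleModelError(
                f"{model_id}: heritability {h2} unreachable at MAF {maf}, "
                f"prevalence {prevalence}; the architecture saturates at "
                f"h2 = {h2_of(1e9):.6g}"
            )
    lo, hi = 0.0, hi_b
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if h2_of(mid) < h2:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    theta = 0.5 * (lo + hi)
    return PenetranceModel(table_for(theta), (maf, maf), prevalence, h2, model_id)


def build_dnme_model(
    maf: float,
    h2: float,
    prevalence: float,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> PenetranceModel:
    """Random purely epistatic two-locus table with no marginal effects.

    Random deviations are projected onto the linear subspace where every
    HWE-weighted row and column mean is zero (so each single-locus marginal
    penetrance equals the prevalence exactly), then scaled to realise the
    requested heritability; tables leaving [0, 1] are rejected and redrawn.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    p1 = hwe_genotype_probs(maf)
    p2 = hwe_genotype_probs(maf)
    p = np.multiply.outer(p1, p2)

    # constraint matrix: weighted row sums and column sums of the deviation are 0
    a = np.zeros((6, 9))
    for i in range(3):
        a[i, 3 * i : 3 * i + 3] = p2
    for j in range(3):
        a[3 + j, j::3] = p1
    proj = np.eye(9) - np.linalg.pinv(a) @ a

    target_var = h2 * prevalence * (1 - prevalence)
    for _ in range(max_attempts):
        d = proj @ rng.standard_normal(9)
        d = d.reshape(3, 3)
        var = float(np.sum(p * d**2))
        if var < 1e-12:
            continue
        if h2 == 0.0:
            f = np.full((3, 3), prevalence)
        else:
            f = prevalence + np.sqrt(target_var / var) * d
        if np.all(f >= 0.0) and np.all(f <= 1.0):
            return PenetranceModel(f, (maf, maf), prevalence, h2, "DNME")
    raise InfeasibleModelError(
        f"DNME: no table in [0,1] found for MAF {maf}, h2 {h2}, prevalence "
        f"{prevalence} within {max_attempts} attempts"
    )


def simulate_dataset(
    m: PenetranceModel,
    n_cases: int,
    n_controls: int,
    n_snps: int,
    rng: np.random.Generator,
    noise_maf_range: tuple[float, float] = (0.05, 0.5),
) -> tuple[GenotypeDataset, SNPCombination]:
    """Draw a balanced-or-not case-control dataset with one embedded model.

    The K functional loci are placed at random positions (returned as the
    ground truth, canonical order). Case genotypes at those loci follow
    p(g) f_g (controls p(g) (1 - f_g)); the other SNPs are independent HWE
    draws with MAFs uniform over ``noise_maf_range``. No missingness.
    """
    k = m.k
    if n_snps <= k:
        raise ValueError(f"need n_snps > {k}")
    p = _joint_probs(m.mafs).ravel()
    f = m.table.ravel()
    w_case = p * f
    w_ctrl = p * (1.0 - f)
    if n_cases > 0 and w_case.sum() <= 0:
        raise ValueError("penetrance model admits no cases")
    if n_controls > 0 and w_ctrl.sum() <= 0:
        raise ValueError("penetrance model admits no controls")

    truth_loci = np.sort(rng.choice(n_snps, size=k, replace=False)) + 1
    truth = SNPCombination(tuple(int(v) for v in truth_loci))

    cells = list(product(range(3), repeat=k))
    cell_idx = np.concatenate(
        [
            rng.choice(len(cells), size=n_cases, p=w_case / w_case.sum())
            if n_cases
            else np.empty(0, dtype=int),
            rng.choice(len(cells), size=n_controls, p=w_ctrl / w_ctrl.sum())
            if n_controls
            else np.empty(0, dtype=int),
        ]
    ).astype(int)
    functional = np.array([cells[i] for i in cell_idx], dtype=np.int8)

    L = n_cases + n_controls
    lo, hi = noise_maf_range
    noise_mafs = rng.uniform(lo, hi, size=n_snps - k)
    geno = np.empty((L, n_snps), dtype=np.int8)
    noise = rng.binomial(2, noise_mafs, size=(L, n_snps - k)).astype(np.int8)
    mask = np.zeros(n_snps, dtype=bool)
    mask[truth_loci - 1] = True
    geno[:, mask] = functional
    geno[:, ~mask] = noise

    phenotype = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    snp_names = [f"SNP{j + 1}" for j in range(n_snps)]
    ds = GenotypeDataset(geno, phenotype, snp_names)
    return ds, truth
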