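"""Quality control for real genotype data and post-hoc analysis of hits.

Pre-search QC mirrors common GWAS practice: samples are dropped first on
call rate, then SNPs on call rate, MAF, a Hardy-Weinberg goodness-of-fit
test in controls, and a single-SNP association chi-square. The association
rule is direction-configurable (``keep_below`` retains the SNPs with
association p below the threshold — useful to pre-enrich a search panel;
``drop_below`` removes them).

Post-hoc, detected combinations are screened by a chi-square test of
independence on their genotype-combination x phenotype table and exported
as a Cytoscape-readable SIF edge list with an attribute table.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeDataset
from .objectives import tabulate
from .search import EliteSet, SNPCombination


@dataclass
class QCThresholds:
    """Filter thresholds; defaults follow routine array-genotyping QC."""

    snp_call_rate_min: float = 0.95
    maf_min: float = 0.05
    hwe_p_min: float = 0.05
    assoc_p_threshold: float = 0.05
    assoc_filter_mode: str = "keep_below"
    sample_call_rate_min: float = 0.95

    def __post_init__(self) -> None:
        for name in (
            "snp_call_rate_min",
            "maf_min",
            "hwe_p_min",
            "assoc_p_threshold",
            "sample_call_rate_min",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.assoc_filter_mode not in ("keep_below", "drop_below"):
            raise ValueError("assoc_filter_mode must be 'keep_below' or 'drop_below'")


def _chisq_of_table(table: np.ndarray) -> float:
    """Pearson chi-square p on a count table after dropping empty rows/cols.

    No continuity correction. Returns NaN when fewer than two non-empty
    rows or columns remain (the test is undefined).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.size == 0:
        return float("nan")
    t = t[t.sum(axis=1) > 0]
    if t.shape[0]:
        t = t[:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return float("nan")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(p)


def snp_statistics(ds: GenotypeDataset) -> pd.DataFrame:
    """Per-SNP call rate, MAF, HWE p (controls) and association p.

    Returns a DataFrame indexed by SNP name. SNPs with zero non-missing
    calls get call_rate 0 and NaN for the undefined statistics.
    """
    if ds.n_samples < 1:
        raise ValueError("dataset has no samples")
    G = ds.genotypes
    y = ds.phenotype
    L, N = G.shape
    obs = G != MISSING
    call_rate = obs.mean(axis=0)

    mafs = np.full(N, np.nan)
    hwe_p = np.full(N, np.nan)
    assoc_p = np.full(N, np.nan)
    controls = y == 0
    for j in range(N):
        col = G[obs[:, j], j].astype(int)
        if len(col) == 0:
            continue
        freq = col.mean() / 2.0
        mafs[j] = min(freq, 1.0 - freq)
        # HWE goodness-of-fit in controls, 1 df
        cc = G[controls & obs[:, j], j].astype(int)
        hwe_p[j] = _hwe_gof_p(cc)
        # genotype x phenotype 3x2 association
        tab = np.zeros((3, 2))
        colfull = G[obs[:, j], j].astype(int)
        yy = y[obs[:, j]].astype(int)
        np.add.at(tab, (colfull, yy), 1)
        assoc_p[j] = _chisq_of_table(tab)
    return pd.DataFrame(
        {"call_rate": call_rate, "maf": mafs, "hwe_p": hwe_p, "assoc_p": assoc_p},
        index=pd.Index(ds.snp_names, name="snp"),
    )


def _hwe_gof_p(genos: np.ndarray) -> float:
    n = len(genos)
    if n == 0:
        return float("nan")
    counts = np.bincount(genos, minlength=3).astype(float)
    p_hat = (counts[1] + 2 * counts[2]) / (2 * n)
    if p_hat <= 0.0 or p_hat >= 1.0:
        return 1.0  # monomorphic: fits HWE trivially
    expected = n * np.array(
        [(1 - p_hat) ** 2, 2 * p_hat * (1 - p_hat), p_hat**2]
    )
    stat = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(stat, df=1))


def apply_qc(
    ds: GenotypeDataset, th: QCThresholds | None = None
) -> tuple[GenotypeDataset, dict[str, int]]:
    """Filter samples then SNPs; returns the reduced dataset and a report.

    Order: samples below ``sample_call_rate_min`` first, then SNPs failing
    call rate, MAF, HWE, or the association rule. The report counts
    removals per criterion in application order (a SNP is charged to the
    first criterion it fails).
    """
    if th is None:
        th = QCThresholds()
    obs = ds.genotypes != MISSING
    sample_cr = obs.mean(axis=1)
    keep_samples = sample_cr >= th.sample_call_rate_min
    report = {"samples_call_rate": int(np.sum(~keep_samples))}
    if not keep_samples.any():
        raise ValueError("QC removed every sample")

    sub = GenotypeDataset(
        ds.genotypes[keep_samples],
        ds.phenotype[keep_samples],
        ds.snp_names,
        [s for s, k in zip(ds.sample_names, keep_samples) if k],
    )
    st = snp_statistics(sub)
    fail_cr = st["call_rate"] < th.snp_call_rate_min
    fail_maf = st["maf"].isna() | (st["maf"] < th.maf_min)
    fail_hwe = st["hwe_p"].isna() | (st["hwe_p"] < th.hwe_p_min)
    if th.assoc_filter_mode == "keep_below":
        fail_assoc = st["assoc_p"].isna() | (st["assoc_p"] >= th.assoc_p_threshold)
    else:
        fail_assoc = st["assoc_p"] < th.assoc_p_threshold

    charged = pd.Series("pass", index=st.index)
    for crit, mask in [
        ("snp_call_rate", fail_cr),
        ("snp_maf", fail_maf),
        ("snp_hwe", fail_hwe),
        ("snp_assoc", fail_assoc),
    ]:
        newly = mask & (charged == "pass")
        charged[newly] = crit
        report[crit] = int(newly.sum())

    keep_snps = (charged == "pass").to_numpy()
    if not keep_snps.any():
        raise ValueError("QC removed every SNP")
    out = GenotypeDataset(
        sub.genotypes[:, keep_snps],
        sub.phenotype,
        [s for s, k in zip(sub.snp_names, keep_snps) if k],
        sub.sample_names,
    )
    return out, report


def pair_chisq(ds: GenotypeDataset, combo: SNPCombination) -> float:
    """Chi-square independence p of the 3^K x 2 table for a combination.

    Empty genotype rows are dropped so the degrees of freedom adapt to the
    observed support. Raises when fewer than two non-empty rows remain.
    """
    if not isinstance(combo, SNPCombination):
        combo = SNPCombination(tuple(combo))
    t = tabulate(ds, combo.loci)
    p = _chisq_of_table(t.counts)
    if np.isnan(p):
        raise ValueError(
            f"chi-square undefined for combination {combo.loci}: "
            "fewer than two supported genotype rows or one phenotype class"
        )
    return p


def posthoc_filter(
    elite: EliteSet, ds: GenotypeDataset, alpha: float = 0.001
) -> pd.DataFrame:
    """Retain elite combinations whose joint chi-square p is below alpha.

    Each retained row carries the per-SNP single-locus p-values and the
    joint p-value (the P1, P2, ..., P columns of a hit table).
    """
    if len(elite) == 0:
        raise ValueError("elite set is empty")
    single_p_cache: dict[int, float] = {}

    def single_p(locus: int) -> float:
        if locus not in single_p_cache:
            single_p_cache[locus] = pair_chisq(ds, SNPCombination((locus,)))
        return single_p_cache[locus]

    rows = []
    for combo, pair in elite:
        p_joint = pair_chisq(ds, combo)
        if p_joint < alpha:
            loci = combo.canonical
            row = {f"locus{t + 1}": loci[t] for t in range(len(loci))}
            row.update(
                {f"snp{t + 1}": ds.snp_names[loci[t] - 1] for t in range(len(loci))}
            )
            row.update(
                {f"p{t + 1}": single_p(loci[t]) for t in range(len(loci))}
            )
            row["p_joint"] = p_joint
            row["k2"] = pair.k2
            row["gini"] = pair.gini
            rows.append(row)
    return pd.DataFrame(rows).sort_values("p_joint", ignore_index=True) if rows else pd.DataFrame(rows)


def export_network(pairs: pd.DataFrame, path) -> str:
    """Write a SIF edge list plus an attribute TSV for retained 2-SNP hits.

    ``pairs`` is the output of :func:`posthoc_filter` (order 2). The SIF
    uses the ``pp`` interaction type; the companion ``<stem>_attributes.tsv``
    holds per-edge -log10 joint p and per-node degree.
    """
    if pairs is None or len(pairs) == 0:
        raise ValueError("no pairs to export")
    if "snp2" not in pairs.columns:
        raise ValueError("network export expects 2-SNP combinations")
    path = str(path)
    with open(path, "w") as fh:
        for _, row in pairs.iterrows():
            fh.write(f"{row['snp1']}\tpp\t{row['snp2']}\n")

    degree: dict[str, int] = {}
    for _, row in pairs.iterrows():
        for node in (row["snp1"], row["snp2"]):
            degree[node] = degree.get(node, 0) + 1
    stem, _ = os.path.splitext(path)
    attr_path = stem + "_attributes.tsv"
    with open(attr_path, "w") as fh:
        fh.write("type\tname\tvalue\n")
        for _, row in pairs.iterrows():
            w = -np.log10(max(row["p_joint"], 1e-300))
            fh.write(f"edge\t{row['snp1']} (pp) {row['snp2']}\t{w:.6g}\n")
        for node in sorted(degree):
            fh.write(f"node\t{node}\t{degree[node]}\n")
    return path
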