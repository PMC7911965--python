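import numpy as np
import pytest
from scipy import stats

from epimoga import (
    MISSING,
    EliteSet,
    GenotypeDataset,
    ObjectivePair,
    QCThresholds,
    SNPCombination,
    apply_qc,
    build_dme_model,
    evaluate_objectives,
    export_network,
    pair_chisq,
    posthoc_filter,
    simulate_dataset,
    snp_statistics,
)


def rng_of(seed):
    return np.random.Generator(np.random.PCG64(seed))


def null_dataset(n_samples=200, n_snps=8, seed=0, maf=0.3):
    """Genotypes independent of phenotype, common alleles, HWE draws."""
    rng = rng_of(seed)
    geno = rng.binomial(2, maf, size=(n_samples, n_snps)).astype(np.int8)
    pheno = np.concatenate(
        [np.ones(n_samples // 2, np.int8), np.zeros(n_samples - n_samples // 2, np.int8)]
    )
    return GenotypeDataset(geno, pheno, [f"rs{i}" for i in range(n_snps)])


class TestSnpStatistics:
    def test_maf_from_allele_counts(self):
        ds = GenotypeDataset(
            np.array([[0], [0], [1], [1]], dtype=np.int8),
            np.array([1, 1, 0, 0]),
            ["rsA"],
        )
        assert snp_statistics(ds).loc["rsA", "maf"] == pytest.approx(0.25)

    def test_call_rate_counts_missing(self):
        geno = np.zeros((20, 1), dtype=np.int8)
        geno[0, 0] = MISSING
        geno[1:11, 0] = 1  # keep the SNP polymorphic
        ds = GenotypeDataset(geno, np.tile([0, 1], 10), ["rsA"])
        assert snp_statistics(ds).loc["rsA", "call_rate"] == pytest.approx(0.95)

    def test_exact_hwe_counts_fit_perfectly(self):
        # controls with genotype counts (81, 18, 1): the HWE expectation at maf 0.1
        geno = np.repeat([0, 1, 2], [81, 18, 1]).reshape(-1, 1).astype(np.int8)
        geno = np.vstack([geno, np.repeat([0, 1], [5, 5]).reshape(-1, 1)])
        pheno = np.concatenate([np.zeros(100, np.int8), np.ones(10, np.int8)])
        ds = GenotypeDataset(geno, pheno, ["rsA"])
        assert snp_statistics(ds).loc["rsA", "hwe_p"] == pytest.approx(1.0)

    def test_all_missing_snp_flagged_undefined(self):
        geno = np.zeros((10, 2), dtype=np.int8)
        geno[:5, 0] = 1
        geno[:, 1] = MISSING
        ds = GenotypeDataset(geno, np.tile([0, 1], 5), ["rsA", "rsB"])
        st = snp_statistics(ds)
        assert st.loc["rsB", "call_rate"] == 0.0
        assert np.isnan(st.loc["rsB", "maf"])


class TestApplyQC:
    def test_clean_null_dataset_unchanged_under_drop_below(self):
        # fixture chosen so every SNP genuinely passes all filters
        ds = null_dataset(seed=4)
        th = QCThresholds(assoc_filter_mode="drop_below")
        out, report = apply_qc(ds, th)
        assert out.n_snps == ds.n_snps and out.n_samples == ds.n_samples
        assert all(v == 0 for v in report.values())

    def test_rare_snp_removed_by_maf_rule(self):
        ds = null_dataset(seed=6)
        geno = ds.genotypes.copy()
        geno[:, 0] = 0
        geno[0, 0] = 1  # maf = 1/400
        ds2 = GenotypeDataset(geno, ds.phenotype, ds.snp_names)
        out, report = apply_qc(ds2, QCThresholds(assoc_filter_mode="drop_below"))
        assert report["snp_maf"] == 1
        assert "rs0" not in out.snp_names

    def test_low_call_rate_sample_removed(self):
        ds = null_dataset(seed=7)
        geno = ds.genotypes.copy()
        geno[3, :] = MISSING  # call rate 0 for sample 4
        ds2 = GenotypeDataset(geno, ds.phenotype, ds.snp_names)
        out, report = apply_qc(ds2, QCThresholds(assoc_filter_mode="drop_below"))
        assert report["samples_call_rate"] == 1
        assert out.n_samples == ds.n_samples - 1

    def test_keep_below_retains_only_associated_snps(self):
        ds = null_dataset(seed=8, n_snps=4)
        geno = ds.genotypes.copy()
        geno[:, 0] = np.where(ds.phenotype == 1, 2, 0)  # perfectly associated
        ds2 = GenotypeDataset(geno, ds.phenotype, ds.snp_names)
        out, _ = apply_qc(ds2, QCThresholds(assoc_filter_mode="keep_below"))
        assert out.snp_names == ["rs0"]

    def test_idempotent(self):
        ds = null_dataset(seed=9)
        th = QCThresholds(assoc_filter_mode="drop_below")
        once, _ = apply_qc(ds, th)
        twice, report = apply_qc(once, th)
        np.testing.assert_array_equal(once.genotypes, twice.genotypes)
        assert all(v == 0 for v in report.values())

    def test_everything_removed_is_an_error(self):
        geno = np.zeros((10, 1), dtype=np.int8)  # monomorphic: fails MAF
        ds = GenotypeDataset(geno, np.tile([0, 1], 5), ["rsA"])
        with pytest.raises(ValueError):
            apply_qc(ds, QCThresholds(assoc_filter_mode="drop_below"))


class TestPairChisq:
    def test_balanced_table_has_unit_p(self):
        geno = np.tile([[0], [1]], (10, 1)).astype(np.int8)
        pheno = np.tile([0, 0, 1, 1], 5)
        ds = GenotypeDataset(geno, pheno, ["rsA"])
        assert pair_chisq(ds, SNPCombination((1,))) == pytest.approx(1.0)

    def test_order_one_matches_single_snp_association(self):
        ds = null_dataset(seed=10, n_snps=3)
        st = snp_statistics(ds)
        for j, name in enumerate(ds.snp_names):
            assert pair_chisq(ds, SNPCombination((j + 1,))) == pytest.approx(
                st.loc[name, "assoc_p"], rel=1e-10
            )

    def test_perfect_separation_toy_table(self):
        # genotype 0 -> all cases (10), genotype 1 -> all controls (10)
        geno = np.repeat([0, 1], 10).reshape(-1, 1).astype(np.int8)
        pheno = np.repeat([1, 0], 10).astype(np.int8)
        ds = GenotypeDataset(geno, pheno, ["rsA"])
        p = pair_chisq(ds, SNPCombination((1,)))
        assert p == pytest.approx(stats.chi2.sf(20.0, 1), rel=1e-10)
        assert p < 0.001

    def test_textbook_oracle_on_small_random_tables(self):
        rng = rng_of(12)
        for _ in range(100):
            geno = rng.integers(0, 3, size=(30, 2)).astype(np.int8)
            pheno = rng.integers(0, 2, size=30).astype(np.int8)
            ds = GenotypeDataset(geno, pheno, ["a", "b"])
            if len(np.unique(pheno)) < 2:
                continue
            combo = SNPCombination((1, 2))
            from epimoga.objectives import tabulate

            t = tabulate(ds, combo.loci).counts.astype(float)
            t = t[t.sum(axis=1) > 0]
            if t.shape[0] < 2 or (t.sum(axis=0) > 0).sum() < 2:
                continue
            t = t[:, t.sum(axis=0) > 0]
            row, col, n = t.sum(axis=1), t.sum(axis=0), t.sum()
            expected = np.outer(row, col) / n
            stat = np.sum((t - expected) ** 2 / expected)
            df = (t.shape[0] - 1) * (t.shape[1] - 1)
            assert pair_chisq(ds, combo) == pytest.approx(
                stats.chi2.sf(stat, df), abs=1e-10
            )


@pytest.fixture(scope="module")
def strong_elite():
    model = build_dme_model("DME2", 0.2, 0.1, 0.2)
    ds, truth = simulate_dataset(model, 400, 400, 30, rng_of(44))
    decoy = (1, 2) if truth.canonical != (1, 2) else (3, 4)
    combos = [SNPCombination(truth.canonical), SNPCombination(decoy)]
    pairs = evaluate_objectives(ds, [c.loci for c in combos])
    return EliteSet(combos, pairs), ds, truth


class TestPosthoc:
    def test_weak_pair_dropped_strict_alpha(self, strong_elite):
        elite, ds, truth = strong_elite
        kept = posthoc_filter(elite, ds, alpha=1e-12)
        weak_p = pair_chisq(ds, elite.combinations[1])
        if weak_p > 1e-12:
            assert len(kept) < len(elite)

    def test_vacuous_alpha_retains_all(self, strong_elite):
        elite, ds, _ = strong_elite
        assert len(posthoc_filter(elite, ds, alpha=1.0)) == len(elite)

    def test_truth_pair_retained_on_strong_signal(self, strong_elite):
        elite, ds, truth = strong_elite
        kept = posthoc_filter(elite, ds, alpha=0.001)
        kept_loci = set(zip(kept["locus1"], kept["locus2"]))
        assert truth.canonical in kept_loci

    def test_single_pair_network(self, strong_elite, tmp_path):
        elite, ds, _ = strong_elite
        kept = posthoc_filter(elite, ds, alpha=1.0)
        sif = tmp_path / "net.sif"
        export_network(kept.head(1), sif)
        lines = sif.read_text().strip().split("\n")
        assert len(lines) == 1
        parts = lines[0].split("\t")
        assert parts[1] == "pp" and len(set(parts) - {"pp"}) == 2

    def test_node_degree_matches_reparsed_edges(self, strong_elite, tmp_path):
        elite, ds, _ = strong_elite
        kept = posthoc_filter(elite, ds, alpha=1.0)
        sif = tmp_path / "net.sif"
        export_network(kept, sif)
        degree: dict[str, int] = {}
        for line in sif.read_text().strip().split("\n"):
            a, _, b = line.split("\t")
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        attrs = (tmp_path / "net_attributes.tsv").read_text().strip().split("\n")[1:]
        node_rows = [r.split("\t") for r in attrs if r.startswith("node")]
        assert {r[1]: int(r[2]) for r in node_rows} == degree
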