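"""Allelic association, BH-FDR, and random-gene resampling validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from rankset.data_model import GenotypeTable
from rankset.snp_association import (
    allelic_test,
    allelic_tests_all,
    bh_fdr,
    gene_assoc,
    random_gene_resampling,
)
from rankset.synthetic_data import synthesize_genotypes

from conftest import make_genotypes


def table_from_counts(minor_case, major_case, minor_control, major_control):
    """GenotypeTable for one SNP realising the given allele counts.

    Uses het/hom-minor combinations so every allele count pair with
    minor+major even is representable.
    """

    def dosages(minor, major):
        n = (minor + major) // 2
        hom = minor // 2
        het = minor % 2
        return [2] * hom + [1] * het + [0] * (n - hom - het)

    case_d = dosages(minor_case, major_case)
    ctrl_d = dosages(minor_control, major_control)
    dosage = np.array(case_d + ctrl_d, dtype=np.int8)[:, None]
    return make_genotypes(
        dosage, ["case"] * len(case_d) + ["control"] * len(ctrl_d)
    )


class TestAllelicTest:
    def test_homogeneous_table(self):
        gt = table_from_counts(10, 90, 20, 180)
        res = allelic_test(gt, "rs1")
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(1.0)

    def test_textbook_table_matches_scipy_oracle(self):
        gt = table_from_counts(10, 990, 50, 950)
        res = allelic_test(gt, "rs1")
        assert res.odds_ratio == pytest.approx((10 * 950) / (990 * 50))
        chi2, p, _, _ = sps.chi2_contingency(
            [[10, 990], [50, 950]], correction=False
        )
        assert res.chi2 == pytest.approx(chi2, abs=1e-10)
        assert res.p_raw == pytest.approx(p, abs=1e-10)
        assert res.test == "chi2"

    def test_label_swap_inverts_or_keeps_chi2(self):
        fwd = allelic_test(table_from_counts(10, 990, 50, 950), "rs1")
        rev = allelic_test(table_from_counts(50, 950, 10, 990), "rs1")
        assert rev.odds_ratio == pytest.approx(1 / fwd.odds_ratio)
        assert rev.chi2 == pytest.approx(fwd.chi2, abs=1e-10)

    def test_zero_cell_uses_haldane_and_fisher(self):
        gt = table_from_counts(0, 100, 10, 90)
        res = allelic_test(gt, "rs1")
        assert res.test == "fisher"
        assert res.odds_ratio == pytest.approx(
            (0.5 * 90.5) / (100.5 * 10.5)
        )
        _, p = sps.fisher_exact([[0, 100], [10, 90]])
        assert res.p_raw == pytest.approx(p, abs=1e-12)

    def test_all_missing_group_is_an_error(self):
        gt = make_genotypes(
            [[-1], [-1], [1], [0]], ["case", "case", "control", "control"]
        )
        with pytest.raises(ValueError, match="all genotypes missing"):
            allelic_test(gt, "rs1")

    def test_vectorised_path_agrees_with_single_snp_path(self):
        sim = synthesize_genotypes(
            n_cases=300, n_controls=300, n_genes=3, snps_per_gene=4, seed=21
        )
        all_res = allelic_tests_all(sim.table).set_index("snp")
        for snp in sim.table.snp_ids:
            one = allelic_test(sim.table, snp)
            row = all_res.loc[snp]
            assert row["chi2"] == pytest.approx(one.chi2, abs=1e-10)
            assert row["p_raw"] == pytest.approx(one.p_raw, abs=1e-10)
            assert row["odds_ratio"] == pytest.approx(one.odds_ratio, rel=1e-10)


def bh_stepup_oracle(p):
    """Hand step-up: sort, adjust m*p/i, enforce monotonicity from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        adj[i] = min(adj[i], adj[i + 1])
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 5), [0.2] * 5, atol=1e-12)

    def test_single_p_identity(self):
        assert bh_fdr([0.123])[0] == pytest.approx(0.123)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_matches_hand_stepup_and_dominates_raw(self, p):
        adj = bh_fdr(p)
        np.testing.assert_allclose(adj, bh_stepup_oracle(p), atol=1e-12)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(size=25)
        base = bh_fdr(p)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_fdr(p[perm]), base[perm], atol=1e-12)

    @pytest.mark.parametrize("bad", [[-0.1], [1.5], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_fdr(bad)


class TestGeneAssoc:
    def test_single_snp_gene_fdr_equals_raw(self):
        sim = synthesize_genotypes(
            n_cases=200, n_controls=200, n_genes=2, snps_per_gene=1, seed=3
        )
        res = gene_assoc(sim.table, sim.target_gene)
        assert len(res) == 1
        assert res["p_fdr"].iloc[0] == pytest.approx(res["p_raw"].iloc[0])

    def test_unknown_gene_rejected(self):
        sim = synthesize_genotypes(n_cases=50, n_controls=50, n_genes=2, seed=4)
        with pytest.raises(KeyError, match="NOPE"):
            gene_assoc(sim.table, "NOPE")

    def test_null_p_values_approximately_uniform(self):
        # fully null panel (freq_ratio = 1): raw allelic p ~ Uniform(0,1).
        # Sample sizes are large enough that the discrete allele counts make
        # the chi-square p effectively continuous, so a plain KS test applies.
        sim = synthesize_genotypes(
            n_cases=2000,
            n_controls=2000,
            n_genes=500,
            snps_per_gene=20,
            freq_ratio=1.0,
            target_control_maf=0.2,
            seed=29,
        )
        res = allelic_tests_all(sim.table)
        assert len(res) == 10_000
        ks = sps.kstest(res["p_raw"], "uniform")
        assert ks.pvalue > 0.001


class TestResampling:
    def test_forced_no_hit_null_gives_one_over_n_plus_one(self):
        # non-target SNPs are constant dosage 1 in everyone -> homogeneous
        # tables, p = 1 -> no resampled family can produce an FDR hit
        n_genes, k = 61, 3
        snp_ids, gene_of = [], {}
        for g in range(n_genes):
            gname = "PTEN" if g == 0 else f"g{g:03d}"
            for j in range(k):
                sid = f"{gname}_s{j}"
                snp_ids.append(sid)
                gene_of[sid] = gname
        n_case = n_ctrl = 40
        dosage = np.ones((n_case + n_ctrl, len(snp_ids)), dtype=np.int8)
        dosage[:n_case, 0] = 0  # strong case/control differential at target
        dosage[n_case:, 0] = 2
        gt = GenotypeTable(
            snp_ids=tuple(snp_ids),
            gene_of=gene_of,
            sample_ids=tuple(f"s{i}" for i in range(n_case + n_ctrl)),
            phenotype=tuple(["case"] * n_case + ["control"] * n_ctrl),
            dosage=dosage,
        )
        res = random_gene_resampling(gt, "PTEN", n_genes=60, seed=8)
        assert res.n_hits == 0
        assert res.empirical_p == pytest.approx(1 / 61)
        assert res.significant

    def test_all_genes_copies_of_target_gives_p_one(self):
        # every gene carries the same strong differential SNP -> every draw hits
        n_genes, k = 30, 2
        snp_ids, gene_of = [], {}
        for g in range(n_genes):
            gname = "PTEN" if g == 0 else f"g{g:03d}"
            for j in range(k):
                sid = f"{gname}_s{j}"
                snp_ids.append(sid)
                gene_of[sid] = gname
        n_case = n_ctrl = 50
        dosage = np.zeros((n_case + n_ctrl, len(snp_ids)), dtype=np.int8)
        dosage[n_case:, :] = 2  # all SNPs: minor allele only in controls
        gt = GenotypeTable(
            snp_ids=tuple(snp_ids),
            gene_of=gene_of,
            sample_ids=tuple(f"s{i}" for i in range(n_case + n_ctrl)),
            phenotype=tuple(["case"] * n_case + ["control"] * n_ctrl),
            dosage=dosage,
        )
        res = random_gene_resampling(gt, "PTEN", n_genes=20, seed=9)
        assert res.n_hits == 20
        assert res.empirical_p == 1.0

    def test_determinism_and_distinct_gene_draws(self):
        sim = synthesize_genotypes(
            n_cases=150, n_controls=150, n_genes=40, snps_per_gene=4, seed=13
        )
        r1 = random_gene_resampling(sim.table, sim.target_gene, n_genes=25, seed=2)
        r2 = random_gene_resampling(sim.table, sim.target_gene, n_genes=25, seed=2)
        assert r1 == r2
        assert len(set(r1.drawn_genes)) == 25
        assert sim.target_gene not in r1.drawn_genes

    def test_too_few_candidate_genes_rejected(self):
        sim = synthesize_genotypes(
            n_cases=50, n_controls=50, n_genes=5, snps_per_gene=2, seed=1
        )
        with pytest.raises(ValueError, match="candidate genes"):
            random_gene_resampling(sim.table, sim.target_gene, n_genes=10, seed=0)
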