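"""Bayesian variable selection, BF conversion, pruning, windows, cis mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from fibronet.containers import ExpressionMatrix, GenomicInterval, GenotypeMatrix
from fibronet.crossspecies import OrthologMap
from fibronet.neteqtl import (
    SpikeSlabRegression,
    cis_isoform_eqtl,
    exact_mppi_enumeration,
    kruskal_by_genotype,
    mppi_to_bf,
    network_eqtl_map,
    prior_inclusion,
    prune_ld_blocks,
    restrict_to_window,
    spike_slab_mppi,
    syntenic_window,
)
from fibronet.syndata import generate_genotypes, generate_panel_expression


class TestPriorAndBf:
    def test_published_prior_arithmetic(self):
        assert prior_inclusion(2.0, 1384) == pytest.approx(1.4e-3, rel=0.05)

    def test_bf_identity_at_prior(self):
        pi = 2 / 1384
        assert mppi_to_bf(pi, pi) == pytest.approx(1.0)

    def test_bf_direct_arithmetic(self):
        assert mppi_to_bf(0.5, 2 / 1384) == pytest.approx(691.0, rel=1e-3)

    def test_bf_strictly_increasing_in_mppi(self):
        pi = 0.02
        grid = np.linspace(0, 0.99, 50)
        bfs = [mppi_to_bf(m, pi) for m in grid]
        assert (np.diff(bfs) > 0).all()

    @pytest.mark.parametrize("mppi,pi", [(1.0, 0.5), (-0.1, 0.5), (0.5, 0.0), (0.5, 1.0)])
    def test_domain_checks(self, mppi, pi):
        with pytest.raises(ValueError):
            mppi_to_bf(mppi, pi)


class TestEnumeration:
    def test_single_predictor_null_pulls_toward_prior(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(40)
        X = rng.standard_normal((40, 1))
        m = exact_mppi_enumeration(y, X, e_pg=0.5)
        # null data: posterior stays the same order of magnitude as pi=0.5
        assert 0.05 < m[0] < 0.95

    def test_duplicated_predictor_splits_inclusion(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(60)
        y = 0.9 * x + 0.3 * rng.standard_normal(60)
        single = exact_mppi_enumeration(y, x[:, None], e_pg=0.5)[0]
        dup = exact_mppi_enumeration(y, np.column_stack([x, x]), e_pg=0.5)
        assert dup[0] == pytest.approx(dup[1], abs=1e-10)
        # either-included probability comparable to the single-column run
        either = dup.sum() - 0  # overlap of both-included counted twice is small
        assert either > 0.8 * single

    def test_null_shrinkage_band(self):
        # independent response: every mppi within an order of magnitude of
        # the prior (the g-prior penalty shrinks below pi itself)
        pi = 2.0 / 6
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            y = rng.standard_normal(50)
            X = rng.standard_normal((50, 6))
            m = exact_mppi_enumeration(y, X)
            assert ((m > pi / 10) & (m < 10 * pi)).all()

    def test_guard_at_p_15(self):
        with pytest.raises(ValueError):
            exact_mppi_enumeration(np.zeros(20), np.zeros((20, 16)))


class TestSampler:
    def test_exact_recovery_of_single_true_predictor(self):
        rng = np.random.default_rng(2)
        X = np.linalg.qr(rng.standard_normal((60, 6)))[0]  # orthogonal columns
        y = X[:, 3].copy()  # noise-free
        m = spike_slab_mppi(y, X, e_pg=0.5, n_iter=20_000, seed=0)
        assert m[3] > 0.99
        assert (np.delete(m, 3) < 0.05).all()
        # and the sampler agrees with the exact posterior
        exact = exact_mppi_enumeration(y, X, e_pg=0.5)
        assert np.abs(m - exact).max() < 0.02

    def test_matches_enumeration_within_tolerance(self):
        for seed in range(3):
            rng = np.random.default_rng(200 + seed)
            X = rng.standard_normal((50, 6))
            beta = np.zeros(6)
            beta[1] = 0.7
            y = X @ beta + 0.8 * rng.standard_normal(50)
            exact = exact_mppi_enumeration(y, X)
            approx = spike_slab_mppi(y, X, n_iter=50_000, seed=seed)
            assert np.abs(exact - approx).max() < 0.02

    def test_column_scaling_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 5))
        y = X[:, 0] + rng.standard_normal(40)
        m1 = spike_slab_mppi(y, X, n_iter=5_000, seed=9)
        X2 = X.copy()
        X2[:, 0] *= 37.0
        m2 = spike_slab_mppi(y, X2, n_iter=5_000, seed=9)
        assert np.allclose(m1, m2)

    def test_zero_variance_column_gets_prior(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 4))
        X[:, 2] = 1.0
        y = rng.standard_normal(30)
        with pytest.warns(UserWarning, match="zero-variance"):
            m = spike_slab_mppi(y, X, n_iter=2_000, seed=0)
        assert m[2] == pytest.approx(2.0 / 4)

    def test_input_checks(self):
        with pytest.raises(ValueError):
            spike_slab_mppi(np.ones(30), np.zeros((30, 0)))
        with pytest.raises(ValueError):
            spike_slab_mppi(np.full(30, np.nan), np.zeros((30, 2)))
        with pytest.raises(ValueError):
            spike_slab_mppi(np.ones(5), np.ones((5, 2)))

    def test_estimator_api(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 5))
        y = X[:, 1] + 0.3 * rng.standard_normal(40)
        est = SpikeSlabRegression(n_iter=10_000, random_state=1).fit(X, y)
        assert est.prior_pi_ == pytest.approx(2.0 / 5)
        assert est.mppi_.shape == (5,)
        assert est.get_support()[1]
        assert est.bf_[1] > 1.0
        params = est.get_params()
        assert params["n_iter"] == 10_000


class TestPruning:
    def test_singleton_block_kept(self):
        geno = generate_genotypes(20, 5, 1, seed=6)
        pruned = prune_ld_blocks(geno)
        assert pruned.n_snps == 5
        assert pruned.snp_ids == geno.snp_ids

    def test_identical_block_members_first_kept(self):
        geno = generate_genotypes(20, 4, 3, seed=7)
        pruned = prune_ld_blocks(geno)
        assert pruned.n_snps == 4
        assert all(s.endswith("_1") for s in pruned.snp_ids)

    def test_representative_has_highest_mean_spearman_with_tie_rule(self):
        # 3 SNPs: s1==s2 perfectly, s3 half-correlated -> means (s1,s2) tie,
        # input order picks s1
        dosage = pd.DataFrame(
            [[0, 0, 1, 1, 0, 1], [0, 0, 1, 1, 0, 1], [0, 1, 1, 0, 0, 1]],
            index=pd.Index(["s1", "s2", "s3"], name="snp_id"),
            columns=[f"i{j}" for j in range(6)],
        )
        idx = dosage.index
        geno = GenotypeMatrix(
            dosage=dosage,
            chrom=pd.Series(["chr1"] * 3, index=idx),
            pos=pd.Series([1, 2, 3], index=idx),
            block_id=pd.Series(["b1"] * 3, index=idx),
        )
        rho12 = spearmanr(dosage.loc["s1"], dosage.loc["s2"]).statistic
        rho13 = spearmanr(dosage.loc["s1"], dosage.loc["s3"]).statistic
        assert rho12 == pytest.approx(1.0) and rho13 < 1.0
        pruned = prune_ld_blocks(geno)
        assert pruned.snp_ids == ["s1"]

    def test_output_size_blocks_plus_blockless(self):
        geno = generate_genotypes(25, 8, 2, seed=8)
        block = geno.block_id.copy()
        block.iloc[-2:] = ""  # detach the last block's SNPs
        geno2 = GenotypeMatrix(geno.dosage, geno.chrom, geno.pos, block, ploidy=1)
        pruned = prune_ld_blocks(geno2)
        assert pruned.n_snps == 7 + 2


class TestNetworkMap:
    def test_planted_hotspot_called_null_not(self, ri_panel):
        geno, expr, truth = ri_panel
        pruned = prune_ld_blocks(geno)
        posterior, summary = network_eqtl_map(
            expr, truth.module_genes("M1"), pruned, n_iter=4_000, seed=5
        )
        called = set(summary.index[summary["called"]])
        assert called == {truth.hotspot_snp}
        assert summary.loc[truth.hotspot_snp, "median_bf"] > 100
        assert posterior.prior_pi == pytest.approx(2.0 / 100)

    def test_null_effect_calls_nothing(self):
        geno = generate_genotypes(30, 50, 1, seed=9)
        expr, truth = generate_panel_expression(
            geno, 60, [25], ("block5", 0.0), noise_sd=0.5, seed=9
        )
        _, summary = network_eqtl_map(
            expr, truth.module_genes("M1"), geno, n_iter=2_000, seed=9
        )
        assert not summary["called"].any()

    def test_single_gene_module_median_is_its_bf(self, ri_panel):
        geno, expr, truth = ri_panel
        pruned = prune_ld_blocks(geno)
        gene = truth.module_genes("M1")[0]
        posterior, summary = network_eqtl_map(expr, [gene], pruned, n_iter=2_000, seed=1)
        assert np.allclose(summary["median_bf"].to_numpy(),
                           posterior.bf.loc[gene].to_numpy())


class TestSyntenicWindow:
    def _tables(self):
        rat = pd.DataFrame(
            {
                "gene_id": ["rg1", "rg2", "rg3"],
                "chrom": ["chr19", "chr19", "chr19"],
                "start": [1_000_000, 5_000_000, 9_000_000],
                "end": [1_010_000, 5_020_000, 9_050_000],
            }
        )
        human = pd.DataFrame(
            {
                "gene_id": ["hg1", "hg2", "hg3"],
                "chrom": ["chr16", "chr16", "chr16"],
                # hg2 centered at 69,415,969
                "start": [100_000, 69_395_969, 80_000_000],
                "end": [120_000, 69_435_969, 80_010_000],
            }
        )
        return rat, human

    def test_reproduces_published_window(self):
        rat, human = self._tables()
        ortho = OrthologMap([("rg1", "hg1"), ("rg2", "hg2"), ("rg3", "hg3")])
        block = GenomicInterval("chr19", 4_000_000, 6_000_000)  # nearest: rg2
        win = syntenic_window(block, rat, ortho, human, window_mb=10.0)
        assert (win.chrom, win.start, win.end) == ("chr16", 64_415_969, 74_415_969)
        assert win.span == 10_000_000

    def test_zero_window_degenerates_to_center(self):
        rat, human = self._tables()
        ortho = OrthologMap([("rg2", "hg2")])
        block = GenomicInterval("chr19", 4_000_000, 6_000_000)
        win = syntenic_window(block, rat, ortho, human, window_mb=0.0)
        assert win.start == win.end == 69_415_969

    def test_walks_outward_to_gene_with_ortholog(self):
        rat, human = self._tables()
        ortho = OrthologMap([("rg3", "hg3")])  # rg2 (nearest) has no ortholog
        block = GenomicInterval("chr19", 4_000_000, 6_000_000)
        win = syntenic_window(block, rat, ortho, human, window_mb=2.0)
        assert win.chrom == "chr16" and win.center() == 80_005_000

    def test_equidistant_tie_prefers_smaller_start(self):
        rat = pd.DataFrame(
            {
                "gene_id": ["left", "right"],
                "chrom": ["chr1", "chr1"],
                "start": [900, 1100],  # midpoints 950 and 1150, center 1050
                "end": [1000, 1200],
            }
        )
        human = pd.DataFrame(
            {"gene_id": ["hl", "hr"], "chrom": ["chr2", "chr2"],
             "start": [10_000, 50_000], "end": [11_000, 51_000]}
        )
        ortho = OrthologMap([("left", "hl"), ("right", "hr")])
        block = GenomicInterval("chr1", 1000, 1100)
        win = syntenic_window(block, rat, ortho, human, window_mb=0.001)
        assert win.center() == 10_500  # "left" wins the tie

    def test_no_mappable_gene_rejected(self):
        rat, human = self._tables()
        ortho = OrthologMap([("rg1", "hg1")])
        block = GenomicInterval("chr5", 1, 2)
        with pytest.raises(ValueError):
            syntenic_window(block, rat, ortho, human)


class TestCisIsoform:
    def test_kruskal_hand_value_two_groups(self):
        values = np.array([1.0, 2, 3, 4, 5, 6])
        dose = np.array([0, 0, 0, 1, 1, 1])
        h, p = kruskal_by_genotype(values, dose)
        # complete separation of two groups of 3: H = 12/(6*7)*(3*(2-3.5)^2
        # + 3*(5-3.5)^2) = 3.857
        assert h == pytest.approx(3.857, abs=1e-3)

    def test_constant_isoform_h_zero_p_one(self):
        h, p = kruskal_by_genotype(np.ones(8), np.array([0, 0, 0, 0, 1, 1, 1, 1]))
        assert h == 0.0 and p == 1.0

    def test_small_groups_dropped(self):
        values = np.arange(6.0)
        dose = np.array([0, 0, 0, 0, 0, 2])  # dosage-2 group has 1 sample
        with pytest.warns(UserWarning, match="dropped|fewer"):
            h, p = kruskal_by_genotype(values, dose)
        assert p == 1.0

    def test_planted_isoform_recovered(self):
        # the planted isoform must dominate; null isoforms are KW-tested at
        # their best-of-window SNP, a post-selection test that is mildly
        # anti-conservative, so they are held to a looser bar
        hits = 0
        null_strong_flags = 0
        for seed in range(10):
            geno = generate_genotypes(60, 10, 1, seed=300 + seed)
            window = GenomicInterval("chr1", 1, 500_000)
            windowed = restrict_to_window(geno, window)
            dose = geno.dosage.loc["snp_b3_1"].to_numpy(dtype=float)
            rng = np.random.default_rng(400 + seed)
            iso = np.vstack([
                1.5 * dose + 0.5 * rng.standard_normal(60),  # loaded isoform
                rng.standard_normal((3, 60)),
            ])
            expr = ExpressionMatrix(
                pd.DataFrame(iso, index=[f"iso{k}" for k in range(4)],
                             columns=geno.sample_ids),
                unit="log2",
            )
            posterior, kw = cis_isoform_eqtl(expr, geno, window, n_iter=3_000, seed=seed)
            kw = kw.set_index("isoform")
            planted = kw.loc["iso0"]
            if planted["fdr"] < 0.01 and planted["lead_snp"] == "snp_b3_1":
                hits += 1
            assert planted["fdr"] <= kw["fdr"].min() + 1e-12
            null_strong_flags += int((kw.drop("iso0")["fdr"] < 0.01).sum())
        assert hits >= 9
        assert null_strong_flags <= 3  # 30 null isoform tests in total

    def test_window_restriction(self):
        geno = generate_genotypes(20, 10, 1, seed=10)
        win = GenomicInterval("chr1", 1, 100_001)
        sub = restrict_to_window(geno, win)
        assert sub.n_snps == 3  # blocks at 1, 50,001, 100,001
        with pytest.raises(ValueError):
            restrict_to_window(geno, GenomicInterval("chr9", 1, 10))
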