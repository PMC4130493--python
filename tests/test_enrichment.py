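"""Class-enrichment chi-square and the matched-sentinel permutation test."""

import numpy as np
import pandas as pd
import pytest

from varstrat.enrichment import (
    af_class_depletion,
    class_enrichment,
    count_stratified_near_sentinels,
    draw_matched_set,
    matched_pool_indices,
    permutation_enrichment,
)
from varstrat.simulate import (
    CohortSpec,
    simulate_gene_bed,
    simulate_genotypes,
    simulate_sentinels,
    variant_pool,
)
from varstrat.types import SentinelCatalog


def brute_force_window_count(stratified, sentinels, window_bp):
    """All-pairs distance scan (oracle for <= 1e3 SNPs)."""
    count = 0
    for _, s in stratified.iterrows():
        hit = any(s["chrom"] == t["chrom"] and abs(s["pos"] - t["pos"]) <= window_bp
                  for _, t in sentinels.iterrows())
        count += hit
    return count


class TestClassEnrichment:
    def test_hand_contingency_fold(self):
        labels = np.array(["coding"] * 1000 + ["other"] * 9000, dtype=object)
        mask = np.zeros(10_000, dtype=bool)
        mask[:20] = True          # 20 coding in stratum...
        mask[1000:1080] = True    # ...plus 80 non-coding = stratum of 100
        res = class_enrichment(labels, mask, "coding")
        assert res.fold == pytest.approx((20 / 100) / (1000 / 10_000))
        assert res.fold == pytest.approx(2.0)
        assert res.method == "chi2"
        assert res.p_value < 0.05

    def test_null_identity_fold_one(self):
        labels = np.array((["coding"] * 10 + ["other"] * 90) * 10, dtype=object)
        mask = np.zeros(1000, dtype=bool)
        mask[:100] = True  # same 10% class rate inside and out
        res = class_enrichment(labels, mask, "coding")
        assert res.fold == pytest.approx(1.0)
        assert res.p_value > 0.5

    def test_empty_class_in_stratum_fold_zero(self):
        labels = np.array(["coding"] * 50 + ["other"] * 950, dtype=object)
        mask = np.zeros(1000, dtype=bool)
        mask[500:600] = True
        res = class_enrichment(labels, mask, "coding")
        assert res.fold == 0.0

    def test_absent_background_class_flagged(self):
        labels = np.array(["other"] * 100, dtype=object)
        mask = np.zeros(100, dtype=bool)
        mask[:10] = True
        assert np.isnan(class_enrichment(labels, mask, "coding").fold)

    def test_small_counts_use_resampling_fallback(self):
        labels = np.array(["coding"] * 4 + ["other"] * 30, dtype=object)
        mask = np.zeros(34, dtype=bool)
        mask[[0, 1, 4, 5]] = True
        res = class_enrichment(labels, mask, "coding",
                               rng=np.random.default_rng(0))
        assert res.method == "resampling"
        assert 0.0 < res.p_value <= 1.0

    def test_chi2_matches_classic_identity(self):
        labels = np.array(["coding"] * 300 + ["other"] * 2700, dtype=object)
        rng = np.random.default_rng(5)
        mask = rng.random(3000) < 0.2
        res = class_enrichment(labels, mask, "coding")
        a = int((mask & (labels == "coding")).sum())
        n, ns, nc = 3000, int(mask.sum()), 300
        b, c, d = ns - a, nc - a, (n - ns) - (nc - a)
        expected = n * (a * d - b * c) ** 2 / (ns * (n - ns) * nc * (n - nc))
        assert res.chi2 == pytest.approx(expected)


class TestAfClassDepletion:
    def test_single_bin_reduces_to_class_enrichment(self):
        rng = np.random.default_rng(2)
        n = 2000
        labels = np.where(rng.random(n) < 0.1, "nonsynonymous", "intergenic").astype(object)
        novel = rng.random(n) < 0.3
        afs = np.full(n, 0.2)  # everything lands in the common bin
        out = af_class_depletion(afs, novel, labels, "nonsynonymous")
        assert len(out) == 1
        ref = class_enrichment(labels, novel, "nonsynonymous")
        assert out["fold"].iloc[0] == pytest.approx(ref.fold)
        assert out["chi2"].iloc[0] == pytest.approx(ref.chi2)


class TestWindowCounting:
    def _frames(self, strat, sent):
        return (pd.DataFrame(strat, columns=["chrom", "pos"]),
                pd.DataFrame(sent, columns=["chrom", "pos"]))

    def test_interval_arithmetic_oracle(self):
        strat, sent = self._frames(
            [("1", 600_000), ("1", 1_400_000), ("1", 2_200_000), ("1", 3_600_000)],
            [("1", 1_000_000), ("1", 3_000_000)])
        expected = brute_force_window_count(strat, sent, 500_000)
        assert expected == 2  # 0.6 and 1.4 Mb; 2.2 and 3.6 Mb are > 0.5 Mb away
        assert count_stratified_near_sentinels(strat, sent, 500_000) == expected

    def test_union_semantics_counts_each_snp_once(self):
        strat, sent = self._frames([("1", 1_500_000)],
                                   [("1", 1_200_000), ("1", 1_800_000)])
        assert count_stratified_near_sentinels(strat, sent, 500_000) == 1

    def test_boundary_inclusive(self):
        strat, sent = self._frames([("1", 1_500_000)], [("1", 1_000_000)])
        assert count_stratified_near_sentinels(strat, sent, 500_000) == 1
        assert count_stratified_near_sentinels(strat, sent, 499_999) == 0

    def test_no_stratified_and_chromosome_separation(self):
        strat, sent = self._frames([], [("1", 1000)])
        assert count_stratified_near_sentinels(strat, sent, 500_000) == 0
        strat, sent = self._frames([("2", 1000)], [("1", 1000)])
        assert count_stratified_near_sentinels(strat, sent, 500_000) == 0

    def test_empty_sentinels_error(self):
        strat, sent = self._frames([("1", 1000)], [])
        with pytest.raises(ValueError):
            count_stratified_near_sentinels(strat, sent)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            strat = pd.DataFrame({
                "chrom": rng.choice(["1", "2"], 200),
                "pos": rng.integers(1, 50_000_000, 200)})
            sent = pd.DataFrame({
                "chrom": rng.choice(["1", "2"], 12),
                "pos": rng.integers(1, 50_000_000, 12)})
            assert (count_stratified_near_sentinels(strat, sent, 500_000)
                    == brute_force_window_count(strat, sent, 500_000))


def _pool_from(truth, genes):
    return variant_pool(truth, genes)


@pytest.fixture(scope="module")
def match_cohort():
    spec = CohortSpec(n_samples=(30, 30), n_variants=2500,
                      drift_f=(0.02, 0.02), rng_seed=19)
    truth = simulate_genotypes(spec)
    genes = simulate_gene_bed(spec, n_genes=1400, mean_len=40_000)
    return truth, genes


@pytest.fixture(scope="module")
def enrich_cohort():
    # gene density ~1 per 150 kb, as in the human genome, so matching
    # on distance-to-gene (+/-10 kb) has workable candidate pools
    spec = CohortSpec(n_samples=(30, 30), n_variants=4000,
                      drift_f=(0.08, 0.08), rng_seed=23)
    truth = simulate_genotypes(spec)
    genes = simulate_gene_bed(spec, n_genes=1400, mean_len=40_000)
    pool = variant_pool(truth, genes)
    return truth, genes, pool


class TestMatchedDraws:

    def test_pool_of_exact_copies_yields_permutation(self, match_cohort):
        truth, genes = match_cohort
        sent = simulate_sentinels(truth, genes, 8, rng=np.random.default_rng(1))
        # pool containing only the sentinels themselves, under fresh ids so
        # self-exclusion does not empty the eligibility sets
        pool = sent.entries.copy()
        pool["variant_id"] = [f"copy{i}" for i in range(len(pool))]
        matched = draw_matched_set(sent, pool, np.random.default_rng(2))
        assert sorted(matched["pos"]) == sorted(pool["pos"])

    def test_zero_tolerances_with_unique_covariates_error_path(self):
        entries = pd.DataFrame({
            "variant_id": ["s1"], "chrom": ["1"], "pos": [100],
            "af": [0.10], "dist_nearest_gene": [500], "n_genes_250kb": [1]})
        sent = SentinelCatalog("toy", entries)
        pool = pd.DataFrame({
            "variant_id": ["s1", "v2"], "chrom": ["1", "1"], "pos": [100, 900],
            "af": [0.10, 0.30], "dist_nearest_gene": [500, 9000],
            "n_genes_250kb": [1, 4]})
        elig = matched_pool_indices(sent, pool, af_tol=0.0, gene_prox_tol_bp=0,
                                    gene_count_tol=0)
        assert len(elig[0]) == 0  # own entry excluded; v2 outside tolerance
        with pytest.raises(ValueError):
            draw_matched_set(sent, pool, np.random.default_rng(0), af_tol=0.0,
                             gene_prox_tol_bp=0, gene_count_tol=0,
                             on_empty="error")
        # default policy drops the sentinel instead
        dropped = draw_matched_set(sent, pool, np.random.default_rng(0),
                                   af_tol=0.0, gene_prox_tol_bp=0,
                                   gene_count_tol=0)
        assert len(dropped) == 0

    def test_matched_covariates_within_tolerance(self, match_cohort):
        truth, genes = match_cohort
        sent = simulate_sentinels(truth, genes, 10, rng=np.random.default_rng(5))
        pool = _pool_from(truth, genes)
        rng = np.random.default_rng(6)
        for _ in range(50):
            matched = draw_matched_set(sent, pool, rng)
            if len(matched) < len(sent):
                continue  # unmatched sentinels dropped, logged by length
            assert (np.abs(matched["af"].to_numpy()
                           - sent.entries["af"].to_numpy()) <= 0.02 + 1e-12).all()
            assert (np.abs(matched["n_genes_250kb"].to_numpy()
                           - sent.entries["n_genes_250kb"].to_numpy()) <= 2).all()

    def test_no_replacement_within_one_set(self, match_cohort):
        truth, genes = match_cohort
        sent = simulate_sentinels(truth, genes, 15, rng=np.random.default_rng(7))
        pool = _pool_from(truth, genes)
        rng = np.random.default_rng(8)
        for _ in range(20):
            matched = draw_matched_set(sent, pool, rng)
            assert matched["variant_id"].is_unique


class TestPermutationEnrichment:

    def test_p_value_bounds_and_determinism(self, enrich_cohort):
        truth, genes, pool = enrich_cohort
        sent = simulate_sentinels(truth, genes, 10, rng=np.random.default_rng(1))
        strat = pool.nlargest(150, "divergence")[["chrom", "pos"]]
        res1 = permutation_enrichment(strat, sent, pool, n_perm=200,
                                      rng=np.random.default_rng(9))
        res2 = permutation_enrichment(strat, sent, pool, n_perm=200,
                                      rng=np.random.default_rng(9))
        assert 1 / 201 <= res1.p_exact <= 1.0
        assert res1.expected == res2.expected and res1.p_exact == res2.p_exact

    def test_observed_zero_gives_fold_zero_p_one(self, enrich_cohort):
        truth, genes, pool = enrich_cohort
        sent = simulate_sentinels(truth, genes, 5, rng=np.random.default_rng(2))
        strat = pd.DataFrame({"chrom": ["99"], "pos": [1]})  # off-genome
        res = permutation_enrichment(strat, sent, pool, n_perm=100,
                                     rng=np.random.default_rng(3))
        assert res.observed == 0
        assert res.fold == 0.0
        assert res.p_exact == 1.0

    def test_positive_control_detected(self, enrich_cohort):
        truth, genes, pool = enrich_cohort
        # sentinels seeded on elevated-divergence variants; stratified snps
        # also the high-divergence tail -> strong spatial coincidence
        sent = simulate_sentinels(truth, genes, 15, enrichment_strength=200.0,
                                  rng=np.random.default_rng(4))
        strat = pool.nlargest(150, "divergence")[["chrom", "pos"]]
        res = permutation_enrichment(strat, sent, pool, n_perm=400,
                                     rng=np.random.default_rng(5))
        assert res.fold > 1.5
        assert res.p_exact < 0.05

    def test_window_invariance_smoke(self, enrich_cohort):
        truth, genes, pool = enrich_cohort
        sent = simulate_sentinels(truth, genes, 15, enrichment_strength=200.0,
                                  rng=np.random.default_rng(4))
        strat = pool.nlargest(150, "divergence")[["chrom", "pos"]]
        res500 = permutation_enrichment(strat, sent, pool, n_perm=300,
                                        window_bp=500_000,
                                        rng=np.random.default_rng(6))
        res1m = permutation_enrichment(strat, sent, pool, n_perm=300,
                                       window_bp=1_000_000,
                                       rng=np.random.default_rng(7))
        assert res1m.fold > 1.0 and res500.fold > 1.0
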