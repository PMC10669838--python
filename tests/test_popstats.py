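import math

import numpy as np
import pytest
from scipy.stats import fisher_exact

from sweepscan import popstats
from sweepscan.popstats import (
    SiteCounts,
    apply_filters,
    bonferroni,
    fisher_allele_test,
    gene_diversity,
    genomewide_fst,
    hwe_exact_test,
    ibs_distance_matrix,
    observed_heterozygosity,
    site_counts,
    wc_fst_site,
)


def counts_from(*pops):
    """Build SiteCounts for a single site from (hom_ref, het, hom_alt) tuples."""
    hr = np.array([[p[0] for p in pops]])
    he = np.array([[p[1] for p in pops]])
    ha = np.array([[p[2] for p in pops]])
    return SiteCounts(
        pops=[f"p{i}" for i in range(len(pops))], n=hr + he + ha, hom_ref=hr, het=he, hom_alt=ha
    )


def wc_theta_reference(pop_counts):
    """Independent scalar transcription of the 1984 variance-component
    estimator, written from the published formulas (r populations)."""
    pops = [(hr, he, ha) for hr, he, ha in pop_counts if hr + he + ha > 0]
    r = len(pops)
    if r < 2:
        return float("nan")
    n = [hr + he + ha for hr, he, ha in pops]
    p = [(2 * ha + he) / (2 * ni) for (hr, he, ha), ni in zip(pops, n)]
    h = [he / ni for (hr, he, ha), ni in zip(pops, n)]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    ssq = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        ssq - (pbar * (1 - pbar) - (r - 1) / r * ssq - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * ssq - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    if a + b + c == 0:
        return float("nan")
    return a / (a + b + c)


class TestSiteCounts:
    def test_basic_tally(self):
        g = {"p1": np.array([[0]] * 10 + [[1]] * 10 + [[2]] * 10)}
        c = site_counts(g)
        assert c.alt_freq[0, 0] == 0.5
        assert c.het[0, 0] == 10 and c.n[0, 0] == 30

    def test_all_missing_population_flagged_unusable(self):
        g = {"p1": np.array([[0], [1]]), "p2": np.array([[-1], [-1]])}
        c = site_counts(g)
        assert c.n[0, 1] == 0
        assert not c.usable[0]

    def test_mixed_missing_matches_direct_tally(self):
        rng = np.random.default_rng(4)
        g = rng.integers(-1, 3, size=(20, 50))
        c = site_counts({"p1": g})
        for j in rng.integers(0, 50, size=10):
            col = g[:, j]
            assert c.hom_ref[j, 0] == (col == 0).sum()
            assert c.het[j, 0] == (col == 1).sum()
            assert c.hom_alt[j, 0] == (col == 2).sum()


class TestWcFst:
    def test_fixed_difference_is_one(self):
        c = counts_from((30, 0, 0), (0, 0, 30))
        assert wc_fst_site(c)[0] == pytest.approx(1.0)

    def test_shared_monomorphic_site_is_na(self):
        c = counts_from((30, 0, 0), (30, 0, 0))
        assert np.isnan(wc_fst_site(c)[0])

    def test_single_usable_population_is_na(self):
        c = counts_from((10, 10, 10), (0, 0, 0))
        assert np.isnan(wc_fst_site(c)[0])

    def test_matches_independent_transcription(self):
        pops = [(10, 10, 10), (25, 4, 1)]
        c = counts_from(*pops)
        assert wc_fst_site(c)[0] == pytest.approx(wc_theta_reference(pops), abs=1e-9)

    def test_genomewide_single_site_equals_site_value(self):
        c = counts_from((10, 10, 10), (25, 4, 1))
        assert genomewide_fst(c) == pytest.approx(wc_fst_site(c)[0], abs=1e-12)

    def test_genomewide_equals_naive_ratio_of_sums(self):
        rng = np.random.default_rng(5)
        g = {
            "p1": rng.integers(0, 3, size=(15, 1000)),
            "p2": rng.integers(0, 3, size=(12, 1000)),
        }
        c = site_counts(g)
        a, denom = popstats.wc_fst_components(c)
        use = np.isfinite(denom) & ~np.isclose(denom, 0)
        assert genomewide_fst(c) == pytest.approx(a[use].sum() / denom[use].sum(), abs=1e-12)

    def test_copied_population_gives_near_zero(self):
        from sweepscan import simdata

        # literal copies push theta to its finite-sample floor ~ -1/(2n-1),
        # so the |value| <= 0.01 contract needs n >= 51 diploids
        cfg = simdata.SimConfig(n_pops=1, samples_per_pop=60, n_snps=20_000, fst_matrix=0.0, seed=6)
        g1 = simdata.simulate_populations(cfg).haplotypes["pop1"].genotypes()
        c = site_counts({"p1": g1, "p2": g1.copy()})
        assert abs(genomewide_fst(c)) <= 0.01


class TestFisher:
    def test_identical_proportions_give_one(self):
        assert fisher_allele_test([10], [20], [10], [20])[0] == pytest.approx(1.0)

    def test_fixed_difference_small_table(self):
        # [[10,0],[0,10]]: enumeration gives 2/C(20,10)
        p = fisher_allele_test([0], [10], [10], [10])[0]
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-10)

    def test_zero_margin_is_one(self):
        assert fisher_allele_test([0], [10], [0], [10])[0] == 1.0

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n1, n2 = rng.integers(2, 40, size=2)
            a1, a2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            ours = fisher_allele_test([a1], [n1], [a2], [n2])[0]
            ref = fisher_exact([[n1 - a1, a1], [n2 - a2, a2]])[1]
            assert ours == pytest.approx(ref, rel=1e-8), (a1, n1, a2, n2)

    def test_transposition_invariance(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n1, n2 = rng.integers(2, 30, size=2)
            a1, a2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            p = fisher_allele_test([a1], [n1], [a2], [n2])[0]
            p_rows = fisher_allele_test([a2], [n2], [a1], [n1])[0]
            p_cols = fisher_allele_test([n1 - a1], [n1], [n2 - a2], [n2])[0]
            assert p == pytest.approx(p_rows, rel=1e-10)
            assert p == pytest.approx(p_cols, rel=1e-10)


class TestBonferroni:
    def test_caps_at_one(self):
        assert bonferroni(np.array([0.3]), 4)[0] == 1.0

    def test_genome_scale_arithmetic(self):
        assert bonferroni(np.array([1e-9]), 8_207_242)[0] == pytest.approx(8.207242e-3)

    def test_zero_p_stays_zero(self):
        assert bonferroni(np.array([0.0]), 10**7)[0] == 0.0

    def test_invalid_m(self):
        with pytest.raises(ValueError):
            bonferroni(np.array([0.5]), 0)


class TestHeterozygosity:
    def test_all_het_individual(self):
        rates, mean = observed_heterozygosity(np.ones((1, 50), dtype=int))
        assert rates[0] == 1.0 and mean == 1.0

    def test_all_hom_individual(self):
        rates, _ = observed_heterozygosity(np.full((1, 50), 2))
        assert rates[0] == 0.0

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(9)
        g = rng.integers(-1, 3, size=(25, 400))
        rates, mean = observed_heterozygosity(g)
        for i in range(25):
            row = g[i][g[i] >= 0]
            assert rates[i] == pytest.approx((row == 1).sum() / len(row))
        assert mean == pytest.approx(np.mean(rates))


class TestGeneDiversity:
    def test_half_frequency_limit(self):
        # p = 0.5 at a large sample: per-locus value -> 0.5
        g = np.array([[0]] * 500 + [[2]] * 500)
        assert gene_diversity(g, corrected=False) == pytest.approx(0.5)
        assert gene_diversity(g, corrected=True) == pytest.approx(0.5 * 2000 / 1999)

    def test_monomorphic_locus_contributes_zero(self):
        g = np.column_stack([np.zeros(10, dtype=int), np.repeat([0, 2], 5)])
        expected = (0.0 + (1 - 0.5**2 - 0.5**2) * 20 / 19) / 2
        assert gene_diversity(g) == pytest.approx(expected)

    def test_matches_per_locus_formula(self):
        rng = np.random.default_rng(10)
        g = rng.integers(0, 3, size=(30, 200))
        direct = []
        for j in range(200):
            p = g[:, j].sum() / 60
            direct.append((1 - p**2 - (1 - p) ** 2) * 60 / 59)
        assert gene_diversity(g) == pytest.approx(np.mean(direct), abs=1e-12)


class TestIbsDistance:
    def test_identical_individuals(self):
        g = np.tile(np.array([[0, 1, 2, 1]]), (2, 1))
        d = ibs_distance_matrix(g)
        assert d[0, 1] == 0.0

    def test_opposite_homozygotes(self):
        g = np.array([[0, 0, 0], [2, 2, 2]])
        assert ibs_distance_matrix(g)[0, 1] == 1.0

    def test_matches_brute_force_pair_loop(self):
        rng = np.random.default_rng(11)
        g = rng.integers(-1, 3, size=(8, 100))
        d = ibs_distance_matrix(g)
        for i in range(8):
            for j in range(8):
                if i == j:
                    assert d[i, j] == 0.0
                    continue
                shared, m = 0, 0
                for k in range(100):
                    if g[i, k] >= 0 and g[j, k] >= 0:
                        m += 1
                        shared += 2 - abs(g[i, k] - g[j, k])
                assert d[i, j] == pytest.approx(1 - shared / (2 * m))


class TestHwe:
    def test_empty_and_monomorphic_are_one(self):
        assert hwe_exact_test(0, 0, 0) == 1.0
        assert hwe_exact_test(25, 0, 0) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)

    def test_matches_exhaustive_enumeration(self):
        # integer-exact enumeration over all het counts with fixed allele counts
        def enumerate_p(hr, he, ha):
            n = hr + he + ha
            rare = min(2 * hr + he, 2 * ha + he)
            if n == 0 or rare == 0:
                return 1.0
            common = 2 * n - rare
            weights = {}
            for h in range(rare % 2, min(rare, common) + 1, 2):
                rr, cc = (rare - h) // 2, (common - h) // 2
                weights[h] = (
                    2**h * math.factorial(n)
                    // (math.factorial(rr) * math.factorial(cc) * math.factorial(h))
                )
            w_obs = weights[he]
            return sum(w for w in weights.values() if w <= w_obs) / sum(weights.values())

        assert hwe_exact_test(3, 5, 1) == pytest.approx(enumerate_p(3, 5, 1), abs=1e-12)
        rng = np.random.default_rng(12)
        for _ in range(100):
            hr, he, ha = rng.integers(0, 12, size=3)
            assert hwe_exact_test(hr, he, ha) == pytest.approx(
                enumerate_p(int(hr), int(he), int(ha)), abs=1e-10
            )


class TestApplyFilters:
    def test_maf_filter_counting(self):
        # 10 sites, 3 with MAF below 0.2 in 10 diploids
        rng = np.random.default_rng(13)
        g = np.ones((10, 10), dtype=int)  # MAF 0.5 everywhere (all het)
        g[:, :3] = 0
        g[0, :3] = 1  # 3 sites with alt freq 0.05
        keep, report = apply_filters(g, maf_min=0.2, hwe_alpha=0.0, missing_max=1.0)
        assert report["removed_maf"] == 3 and keep.sum() == 7

    def test_permissive_thresholds_are_identity(self):
        rng = np.random.default_rng(14)
        g = rng.integers(0, 3, size=(20, 50))
        keep, report = apply_filters(g, maf_min=0.0, hwe_alpha=0.0, missing_max=1.0)
        assert keep.all() and report["n_kept"] == 50

    def test_report_matches_per_site_recheck(self):
        rng = np.random.default_rng(15)
        g = rng.integers(-1, 3, size=(30, 300))
        maf_min, hwe_alpha, missing_max = 0.1, 0.05, 0.05
        keep, report = apply_filters(g, maf_min, hwe_alpha, missing_max)
        n_maf = n_hwe = n_miss = 0
        for j in range(300):
            col = g[:, j]
            called = col[col >= 0]
            p = called.sum() / (2 * len(called))
            maf = min(p, 1 - p)
            hwe_p = hwe_exact_test(
                int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
            )
            miss = 1 - len(called) / 30
            if maf < maf_min:
                n_maf += 1
            elif hwe_p < hwe_alpha:
                n_hwe += 1
            elif miss > missing_max:
                n_miss += 1
            else:
                assert keep[j]
        assert (report["removed_maf"], report["removed_hwe"], report["removed_missing"]) == (
            n_maf,
            n_hwe,
            n_miss,
        )
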