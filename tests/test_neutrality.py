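"""Neutrality statistics against exact enumerations and simulation oracles."""

from fractions import Fraction

import numpy as np
import pytest

from ivypop.coalescent import DemographyModel, drop_mutations, simulate_tree
from ivypop.neutrality import (
    coalescent_pvalue,
    ewens_log_pmf,
    fu_fs_from_parts,
    locus_stats_from_sim,
    multilocus_d_test,
    null_distribution,
    r2_from_parts,
    r2_statistic,
    tajima_d,
    tajima_d_from_parts,
)


def _brute_tajima_d(n, s, pi_total):
    """Independent re-derivation of the 1989 formula with Fractions."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = float(e1) * s + float(e2) * s * (s - 1)
    return (pi_total - s / float(a1)) / np.sqrt(var)


def _brute_stirling(n):
    """|s(n, k)| by exact integer recurrence."""
    row = [0, 1]
    for m in range(1, n):
        new = [0] * (m + 2)
        for k in range(1, m + 2):
            new[k] = m * row[k] + row[k - 1] if k <= m else row[k - 1]
        row = new
    return row


class TestTajimaD:
    def test_hand_example(self, four_hap_alignment):
        assert tajima_d(four_hap_alignment) == pytest.approx(1.893, abs=2e-3)

    def test_matches_exact_rational_oracle(self):
        for n, s, pi in [(4, 2, 4 / 3), (10, 7, 2.5), (50, 20, 4.0)]:
            assert tajima_d_from_parts(n, s, pi) == pytest.approx(
                _brute_tajima_d(n, s, pi), rel=1e-12)

    def test_singleton_excess_is_negative(self, rng):
        n, s = 10, 6
        # all mutations are singletons: pi_total = s * 2(n-1)/(n(n-1))
        pi = s * 2 * (n - 1) / (n * (n - 1))
        assert tajima_d_from_parts(n, s, pi) < 0

    def test_undefined_for_no_segregation(self):
        assert np.isnan(tajima_d_from_parts(10, 0, 0.0))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            tajima_d_from_parts(3, 1, 0.5)


class TestFuFs:
    def test_exact_small_cases(self):
        assert fu_fs_from_parts(4, 2, 1.0) == pytest.approx(np.log(3.0))
        assert fu_fs_from_parts(4, 4, 4 / 3) == pytest.approx(-2.5816, abs=1e-3)

    def test_single_haplotype_is_plus_infinity(self):
        with pytest.warns(UserWarning):
            assert fu_fs_from_parts(6, 1, 0.5) == np.inf

    def test_ewens_pmf_sums_to_one(self):
        for n in (2, 5, 12, 40):
            for theta in (0.5, 1.0, 3.7):
                logp = ewens_log_pmf(n, theta)[1:]
                assert np.exp(logp).sum() == pytest.approx(1.0, rel=1e-10)

    def test_stirling_against_integer_recurrence(self):
        from ivypop.neutrality import _log_stirling_row

        for n in (4, 7, 11):
            exact = _brute_stirling(n)
            ours = np.exp(_log_stirling_row(n)[1:])
            assert np.allclose(ours, exact[1:], rtol=1e-10)

    def test_invariant_to_site_and_row_order(self, rng):
        from ivypop.neutrality import fu_fs
        from ivypop.popdata import HaplotypeAlignment

        seqs = rng.choice(list("AT"), size=(8, 20))
        inds = [f"I{i // 2}" for i in range(8)]
        a = fu_fs(HaplotypeAlignment("x", seqs, inds))
        cols = rng.permutation(20)
        rows = rng.permutation(8)
        b = fu_fs(HaplotypeAlignment(
            "x", seqs[np.ix_(rows, cols)], [inds[i] for i in rows]))
        assert a == pytest.approx(b)


class TestR2:
    def test_hand_example(self, four_hap_alignment):
        assert r2_statistic(four_hap_alignment) == pytest.approx(1 / 3)

    def test_star_genealogy_gives_small_r2(self):
        # singletons spread evenly over sequences: U_i ~ pi/2 -> small R2
        n, s = 10, 10
        singles = np.ones(n)
        pi = s * 2 * (n - 1) / (n * (n - 1))
        spread = r2_from_parts(n, s, pi, singles)
        lopsided = r2_from_parts(n, s, pi, np.r_[np.full(1, s), np.zeros(n - 1)])
        assert spread < lopsided

    def test_undefined_without_segregation(self):
        assert np.isnan(r2_from_parts(5, 0, 0.0, np.zeros(5)))


class TestNullDistributions:
    def test_fixed_s_mean_d_slightly_negative(self, rng):
        """Fixed-S conditioning makes E[D] mildly negative (msprime-verified)."""
        null = null_distribution("tajima_d", 20, 17, 4000, seed=rng)
        assert -0.15 < null.mean() < -0.03

    def test_observed_at_median_gives_half_pvalues(self, rng):
        null = null_distribution("tajima_d", 12, 8, 2000, seed=rng)
        res = coalescent_pvalue(float(np.median(null)), "tajima_d", 12, 8,
                                reps=2000, seed=1)
        assert res.p_low == pytest.approx(0.5, abs=0.05)
        assert res.p_high == pytest.approx(0.5, abs=0.05)
        assert res.p_low + res.p_high >= 1.0  # ties count both sides

    def test_same_seed_bit_identical(self):
        a = coalescent_pvalue(-1.0, "tajima_d", 10, 5, reps=1000, seed=3)
        b = coalescent_pvalue(-1.0, "tajima_d", 10, 5, reps=1000, seed=3)
        assert np.array_equal(a.null_values, b.null_values)
        assert (a.p_low, a.p_high) == (b.p_low, b.p_high)

    def test_growth_data_rejected_against_constant_null(self, rng):
        """Power check: strong-expansion loci give low p_low for D.

        Settings (n = 50, theta = 100, alpha = 50) chosen where the
        single-locus D test has near-complete power; at small n and mild
        growth its power is known to be weak.
        """
        grow = DemographyModel(growth_rate=50.0)
        n = 50
        hits = 0
        trials = 12
        for _ in range(trials):
            locus = drop_mutations(simulate_tree(n, grow, rng), 100.0, rng)
            st = locus_stats_from_sim(locus)
            if st["s"] == 0:
                continue
            d = tajima_d_from_parts(n, st["s"], st["pi_total"])
            res = coalescent_pvalue(d, "tajima_d", n, st["s"], reps=1000,
                                    seed=rng)
            hits += res.p_low < 0.05
        assert hits >= 0.75 * trials

    def test_fs_and_r2_agree_with_d_on_growth(self, rng):
        """All three statistics signal expansion on the same data."""
        grow = DemographyModel(growth_rate=10.0)
        n = 25
        d_all, fs_all, r2_all = [], [], []
        fs_null, r2_null = [], []
        for _ in range(60):
            locus = drop_mutations(simulate_tree(n, grow, rng), 8.0, rng)
            st = locus_stats_from_sim(locus)
            if st["s"] < 2 or st["pi_total"] == 0:
                continue
            d_all.append(tajima_d_from_parts(n, st["s"], st["pi_total"]))
            fs_all.append(fu_fs_from_parts(n, st["k_obs"], st["pi_total"]))
            r2_all.append(r2_from_parts(n, st["s"], st["pi_total"],
                                        st["singletons"]))
            neutral = drop_mutations(simulate_tree(n, seed=rng), 8.0, rng)
            stn = locus_stats_from_sim(neutral)
            if stn["s"] >= 2 and stn["pi_total"] > 0:
                fs_null.append(fu_fs_from_parts(n, stn["k_obs"], stn["pi_total"]))
                r2_null.append(r2_from_parts(n, stn["s"], stn["pi_total"],
                                             stn["singletons"]))
        assert np.mean(d_all) < 0
        assert np.mean(fs_all) < np.mean(fs_null)
        assert np.mean(r2_all) < np.mean(r2_null)


class TestMultilocusD:
    def test_symmetric_null_gives_half_p(self, rng):
        per_locus = [((-0.09), 20, 10), ((-0.09), 20, 12), ((-0.09), 20, 8)]
        res = multilocus_d_test(per_locus, reps=2000, seed=rng)
        assert 0.2 < res.p_low < 0.8

    def test_growth_loci_fall_below_null(self, rng):
        grow = DemographyModel(growth_rate=10.0)
        per_locus = []
        n = 24
        while len(per_locus) < 7:
            locus = drop_mutations(simulate_tree(n, grow, rng), 6.0, rng)
            st = locus_stats_from_sim(locus)
            if st["s"] >= 2:
                per_locus.append(
                    (tajima_d_from_parts(n, st["s"], st["pi_total"]),
                     n, st["s"]))
        res = multilocus_d_test(per_locus, reps=1000, seed=rng)
        assert res.observed < res.sim_mean
        assert res.p_low < 0.1

    def test_reproducible_and_requires_two_loci(self):
        a = multilocus_d_test([(-0.5, 10, 5), (0.2, 10, 6)], reps=1000, seed=9)
        b = multilocus_d_test([(-0.5, 10, 5), (0.2, 10, 6)], reps=1000, seed=9)
        assert a.p_low == b.p_low
        with pytest.raises(ValueError):
            multilocus_d_test([(-0.5, 10, 5)], reps=1000, seed=0)
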