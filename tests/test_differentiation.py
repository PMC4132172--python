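"""F-statistics, AMOVA, distances, Mantel tests, LD and selfing rate."""

import numpy as np
import pandas as pd
import pytest

from ivypop.differentiation import (
    amova,
    geographic_distance,
    ld_r2_matrix,
    linearized_fst,
    mantel_test,
    multilocus_fst,
    nei_distance,
    outlier_percentile,
    pairwise_fst_matrix,
    prune_ld_and_recompute,
    selfing_rate_from_fis,
    snp_fst_distribution,
    weir_cockerham_fst,
)
from ivypop.popdata import SnpMatrix


def _snps(G, ids=None):
    G = np.asarray(G, dtype=np.int8)
    n, s = G.shape
    return SnpMatrix(
        snp_ids=[(f"L{j}", 0) for j in range(s)],
        genotypes=G,
        allele_labels=[("A", "T")] * s,
        individuals=ids or [f"I{i}" for i in range(n)],
    )


class TestWeirCockerham:
    def test_fixed_difference_gives_one(self):
        G = np.array([[2]] * 10 + [[0]] * 10)
        assert weir_cockerham_fst(G, ["a"] * 10 + ["b"] * 10) == 1.0

    def test_identical_hwe_pops_slightly_negative(self):
        g = [2] * 25 + [1] * 50 + [0] * 25
        G = np.array(g + g).reshape(-1, 1)
        theta = weir_cockerham_fst(G, ["a"] * 100 + ["b"] * 100)
        assert theta == pytest.approx(-0.00505, abs=1e-4)
        assert theta <= 0

    def test_random_split_of_one_population_averages_zero(self, rng):
        thetas = []
        for _ in range(500):
            G = rng.binomial(2, 0.3, size=60).reshape(-1, 1).astype(np.int8)
            labels = rng.permutation(["a"] * 30 + ["b"] * 30)
            t = weir_cockerham_fst(G, labels)
            if np.isfinite(t):
                thetas.append(t)
        assert np.mean(thetas) == pytest.approx(0.0, abs=0.01)

    def test_monomorphic_is_nan(self):
        G = np.zeros((20, 1), dtype=np.int8)
        assert np.isnan(weir_cockerham_fst(G, ["a"] * 10 + ["b"] * 10))

    def test_island_fst_increases_as_migration_drops(self, rng):
        """Monotonic multilocus FST over a 3-point migration grid."""
        from ivypop.coalescent import DemographyModel, diploidize, drop_mutations, simulate_tree

        means = []
        for M in (20.0, 5.0, 1.0):
            model = DemographyModel(n_demes=4, migration_rate=M)
            vals = []
            for _ in range(25):
                tree = simulate_tree(48, model, rng, sample_demes=[12] * 4)
                locus = drop_mutations(tree, 3.0, rng)
                if locus.n_segregating == 0:
                    continue
                G = np.zeros((24, locus.n_segregating), dtype=np.int8)
                labels = []
                for deme in range(4):
                    pool = np.flatnonzero(tree.leaf_deme == deme)
                    asn = diploidize(locus.haplotypes[pool], 0.0, rng,
                                     n_individuals=6)
                    G[deme * 6:(deme + 1) * 6] = asn.genotypes
                    labels += [f"d{deme}"] * 6
                t = multilocus_fst(G, np.asarray(labels))
                if np.isfinite(t):
                    vals.append(t)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestAmova:
    def test_clonal_fixed_populations(self):
        G = np.array([[2, 2, 2]] * 6 + [[0, 0, 0]] * 6)
        res = amova(_snps(G), ["a"] * 6 + ["b"] * 6, permutations=49, seed=0)
        assert res.f_statistics["FST"] == pytest.approx(1.0)
        assert res.percentages[0] == pytest.approx(100.0, abs=1e-6)

    def test_complete_selfing_puts_nothing_within_individuals(self, rng):
        # all homozygotes, same frequencies in both pops
        G = rng.choice([0, 2], size=(24, 10)).astype(np.int8)
        res = amova(_snps(G), ["a"] * 12 + ["b"] * 12, permutations=49, seed=0)
        assert res.variance_components[2] == 0.0  # no heterozygotes
        assert res.f_statistics["FIS"] == pytest.approx(1.0)

    def test_percentages_sum_and_fit_identity(self, rng):
        G = rng.integers(0, 3, size=(40, 15)).astype(np.int8)
        labels = ["a"] * 10 + ["b"] * 10 + ["c"] * 10 + ["d"] * 10
        res = amova(_snps(G), labels, permutations=49, seed=1)
        assert sum(res.percentages) == pytest.approx(100.0, abs=0.01)
        fst, fis, fit = (res.f_statistics[k] for k in ("FST", "FIS", "FIT"))
        assert fit == pytest.approx(fst + (1 - fst) * fis, abs=1e-9)

    def test_size_one_population_excluded_with_warning(self, rng):
        G = rng.integers(0, 3, size=(9, 5)).astype(np.int8)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"]
        with pytest.warns(UserWarning, match="size 1"):
            res = amova(_snps(G), labels, permutations=9, seed=0)
        assert res is not None

    def test_permutation_pvalues_reproducible(self, rng):
        G = rng.integers(0, 3, size=(20, 8)).astype(np.int8)
        labels = ["a"] * 10 + ["b"] * 10
        r1 = amova(_snps(G), labels, permutations=99, seed=5)
        r2 = amova(_snps(G), labels, permutations=99, seed=5)
        assert r1.p_values == r2.p_values


class TestNeiDistance:
    def test_identical_frequencies_give_zero(self):
        G = np.array([[1, 1], [1, 0], [0, 1], [1, 1], [1, 0], [0, 1]],
                     dtype=np.int8)
        D = nei_distance(G, ["a"] * 3 + ["b"] * 3)
        assert D.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_fixed_alleles_give_infinity(self):
        G = np.array([[2]] * 4 + [[0]] * 4, dtype=np.int8)
        D = nei_distance(G, ["a"] * 4 + ["b"] * 4)
        assert np.isinf(D.iloc[0, 1])

    def test_hand_value(self):
        G = np.array([[1]] * 10 + [[2]] * 8 + [[1]] * 2, dtype=np.int8)
        D = nei_distance(G, ["x"] * 10 + ["y"] * 10)
        assert D.iloc[0, 1] == pytest.approx(0.2473, abs=1e-3)


class TestMantelAndGeography:
    def _dist(self, rng, n=10):
        X = rng.random((n, 2)) * 10
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        return D

    def test_perfect_linear_relation(self, rng):
        A = self._dist(rng)
        res = mantel_test(A, 2 * A + 3, permutations=99, seed=0)
        assert res.r_xy == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_affine_invariance(self, rng):
        A, B = self._dist(rng), self._dist(rng)
        r1 = mantel_test(A, B, permutations=19, seed=0).r_xy
        r2 = mantel_test(5 * A + 1, 0.2 * B + 7, permutations=19, seed=0).r_xy
        assert r1 == pytest.approx(r2)

    def test_matches_skbio_oracle(self, rng):
        from skbio.stats.distance import mantel as skbio_mantel, DistanceMatrix

        A, B = self._dist(rng), self._dist(rng)
        ours = mantel_test(A, B, permutations=999, seed=1)
        r_sk, p_sk, _ = skbio_mantel(DistanceMatrix(A), DistanceMatrix(B),
                                     permutations=999, alternative="greater")
        assert ours.r_xy == pytest.approx(float(r_sk), abs=1e-12)
        assert ours.p_value == pytest.approx(float(p_sk), abs=0.05)

    def test_constant_matrix_rejected(self):
        A = np.zeros((4, 4))
        with pytest.raises(ValueError, match="constant"):
            mantel_test(A, A, permutations=9, seed=0)

    def test_geographic_distance_values(self):
        meta = pd.DataFrame({
            "population_id": ["a", "b", "c"],
            "latitude": [0.0, 0.0, 0.0],
            "longitude": [0.0, 180.0, 0.0],
        })
        d = geographic_distance(meta)
        assert d.loc["a", "b"] == pytest.approx(np.pi * 6371.0, rel=1e-4)
        assert d.loc["a", "c"] == 0.0
        assert np.allclose(d, d.T)

    def test_missing_coordinates_named(self):
        meta = pd.DataFrame({
            "population_id": ["a", "b"],
            "latitude": [1.0, np.nan], "longitude": [2.0, 3.0],
        })
        with pytest.raises(ValueError, match="b"):
            geographic_distance(meta)

    def test_stepping_stone_shows_isolation_by_distance(self, rng):
        """Linearized FST correlates with distance under stepping-stone."""
        from ivypop.simulate import ScenarioConfig, generate_dataset
        from ivypop.popdata import extract_snps

        cfg = ScenarioConfig(n_populations=8, lines_per_population=6,
                             n_loci=4, demography="stepping_stone",
                             migration_rate=4.0, theta_per_site=2e-4,
                             seed=77)
        ds = generate_dataset(cfg)
        snps = extract_snps(ds.alignments, ds.meta)
        geo = geographic_distance(ds.meta)
        fstm = pairwise_fst_matrix(snps, ds.meta).loc[geo.index, geo.index]
        lin = linearized_fst(fstm)
        res = mantel_test(lin, geo, permutations=499, seed=3)
        assert res.r_xy > 0
        assert res.p_value < 0.1


class TestLinearizedFst:
    def test_monotone_transform(self):
        f = pd.DataFrame([[0.0, 0.1, 0.4], [0.1, 0.0, 0.8], [0.4, 0.8, 0.0]])
        lin = linearized_fst(f)
        tri = np.triu_indices(3, 1)
        order_f = np.argsort(np.asarray(f)[tri])
        order_l = np.argsort(np.asarray(lin)[tri])
        assert np.array_equal(order_f, order_l)
        assert lin.iloc[0, 1] == pytest.approx(0.1 / 0.9)


class TestSelfingRate:
    @pytest.mark.parametrize("fis,expected", [
        (0.86, 92.47), (0.0, 0.0), (1.0, 100.0),
    ])
    def test_values(self, fis, expected):
        assert selfing_rate_from_fis(fis) == pytest.approx(expected, abs=0.01)

    def test_negative_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert selfing_rate_from_fis(-0.2) == 0.0

    def test_above_one_rejected(self):
        with pytest.raises(ValueError):
            selfing_rate_from_fis(1.2)


class TestLd:
    def test_identical_dosages_r2_one(self):
        G = np.tile(np.array([0, 1, 2, 0, 2, 1], dtype=np.int8), (2, 1)).T
        r2, sig = ld_r2_matrix(_snps(G))
        assert r2[0, 1] == pytest.approx(1.0)

    def test_orthogonal_dosages_r2_zero(self):
        a = np.array([0, 0, 2, 2], dtype=np.int8)
        b = np.array([0, 2, 0, 2], dtype=np.int8)
        r2, sig = ld_r2_matrix(_snps(np.c_[a, b]))
        assert r2[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert not sig[0, 1]

    def test_phased_homozygote_hand_value(self):
        # haplotype counts AB=40 ab=40 Ab=10 aB=10 -> 50 homozygous diploids
        dosA = np.array([2] * 20 + [0] * 20 + [2] * 5 + [0] * 5, dtype=np.int8)
        dosB = np.array([2] * 20 + [0] * 20 + [0] * 5 + [2] * 5, dtype=np.int8)
        r2, _ = ld_r2_matrix(_snps(np.c_[dosA, dosB]))
        assert r2[0, 1] == pytest.approx(0.36, abs=1e-9)


class TestFstDistribution:
    def test_prune_removes_linked_pair(self):
        base = np.repeat([0, 2], 20).astype(np.int8)  # duplicated pair
        alt = np.tile([0, 2], 20).astype(np.int8)  # exactly uncorrelated
        per4 = np.tile([0, 0, 2, 2], 10).astype(np.int8)
        G = np.c_[base, base, alt, per4]
        snps = _snps(G)
        labels = ["a"] * 20 + ["b"] * 20
        dist = snp_fst_distribution(snps, labels)
        assert dist.ld_flags[0] and dist.ld_flags[1]
        pruned = prune_ld_and_recompute(dist)
        assert len(pruned.per_snp_fst) <= 3
        assert not any(sid in (("L0", 0), ("L1", 0)) for sid in pruned.snp_ids)

    def test_no_ld_leaves_distribution_unchanged(self, rng):
        G = rng.binomial(2, 0.5, size=(60, 4)).astype(np.int8)
        dist = snp_fst_distribution(_snps(G), ["a"] * 30 + ["b"] * 30)
        if not dist.ld_flags.any():
            pruned = prune_ld_and_recompute(dist)
            assert np.array_equal(pruned.per_snp_fst, dist.per_snp_fst)

    def test_outlier_percentile_endpoints(self):
        vals = np.linspace(0, 0.5, 20)
        assert outlier_percentile(vals, 0.9) == 100.0
        assert outlier_percentile(vals, float(np.median(vals))) == pytest.approx(50.0, abs=3)
        with pytest.raises(ValueError):
            outlier_percentile(np.array([]), 0.5)
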