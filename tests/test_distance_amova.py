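"""Distances, clustering/Newick, AMOVA and IBS kinship."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster import hierarchy

from goatpop.io_formats import (
    DistanceMatrix,
    GenotypeMatrix,
    MISSING,
    SampleRecord,
    ValidationError,
)
from goatpop.distance_amova import (
    amova,
    cap_infinite,
    hierarchical_cluster,
    ibs_kinship,
    manhattan_distance_matrix,
    nei_distance,
    nei_distance_matrix,
    reynolds_distance,
    tree_to_newick,
)
from goatpop.synthetic_data import SimConfig, simulate


def _gm(dosages):
    d = np.asarray(dosages, dtype=np.int8)
    return GenotypeMatrix(
        [f"s{i}" for i in range(d.shape[0])],
        [f"l{j}" for j in range(d.shape[1])],
        d,
    )


def nei_oracle(x, y):
    """Scalar loop evaluation of Nei 1972 D for two frequency profiles."""
    jxy = jx = jy = 0.0
    for a, b in zip(x, y):
        jxy += a * b + (1 - a) * (1 - b)
        jx += a * a + (1 - a) * (1 - a)
        jy += b * b + (1 - b) * (1 - b)
    n = len(x)
    import math

    return -math.log((jxy / n) / math.sqrt((jx / n) * (jy / n)))


class TestNei:
    def test_identical_profiles_zero(self):
        assert nei_distance([0.5, 0.2, 0.9], [0.5, 0.2, 0.9]) == pytest.approx(0.0)

    def test_opposite_fixation_infinite(self):
        assert nei_distance([1.0, 1.0], [0.0, 0.0]) == float("inf")

    def test_scalar_oracle_agreement(self, rng):
        x = rng.uniform(0.05, 0.95, 5)
        y = rng.uniform(0.05, 0.95, 5)
        assert nei_distance(x, y) == pytest.approx(nei_oracle(x, y), abs=1e-12)

    def test_matrix_agrees_with_per_pair_oracle(self, rng):
        d = rng.integers(0, 3, size=(8, 120)).astype(np.int8)
        d[rng.random(d.shape) < 0.05] = MISSING
        gm = _gm(d)
        dm = nei_distance_matrix(gm)
        for i in range(8):
            for j in range(i + 1, 8):
                both = (d[i] != MISSING) & (d[j] != MISSING)
                expected = nei_oracle(d[i][both] / 2.0, d[j][both] / 2.0)
                assert dm.values[i, j] == pytest.approx(expected, abs=1e-10)


class TestReynolds:
    def test_identical_profiles_zero(self):
        # identical sample frequencies: the estimator is negative, floored to 0
        assert reynolds_distance([0.3, 0.6], [0.3, 0.6], 24, 24) == 0.0

    def test_fixed_difference_is_one(self):
        assert reynolds_distance([1.0] * 5, [0.0] * 5, 100, 100) == pytest.approx(1.0)

    def test_scalar_oracle_agreement(self, rng):
        p1 = rng.uniform(0.1, 0.9, 5)
        p2 = rng.uniform(0.1, 0.9, 5)
        n1, n2 = 20, 30
        num = den = 0.0
        for a, b in zip(p1, p2):
            num += (a - b) ** 2 - a * (1 - a) / (2 * n1 - 1) - b * (1 - b) / (
                2 * n2 - 1
            )
            den += a * (1 - b) + b * (1 - a)
        expected = max(num / den, 0.0)
        assert reynolds_distance(p1, p2, n1, n2) == pytest.approx(expected, abs=1e-12)

    def test_recovers_drift_level(self):
        data = simulate(
            SimConfig(pop_labels=("A", "B"), n_per_pop=(24, 24),
                      fst_per_pop=(0.02, 0.02), n_loci=10_000,
                      n_outlier_loci=0, missing_rate=0.0, seed=2)
        )
        d = data.genotypes.dosage
        p1 = d[:24].mean(axis=0) / 2.0
        p2 = d[24:].mean(axis=0) / 2.0
        assert reynolds_distance(p1, p2, 24, 24) == pytest.approx(0.02, rel=0.25)


class TestManhattan:
    def test_identical_zero_and_known_value(self):
        gm = _gm([[0, 0], [2, 2]])
        dm = manhattan_distance_matrix(gm)
        assert dm.values[0, 0] == 0.0
        assert dm.values[0, 1] == pytest.approx(2.0)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 2**30))
    def test_triangle_inequality(self, seed):
        r = np.random.default_rng(seed)
        gm = _gm(r.integers(0, 3, size=(3, 40)).astype(np.int8))
        d = manhattan_distance_matrix(gm).values
        assert d[0, 2] <= d[0, 1] + d[1, 2] + 1e-12


class TestClustering:
    def test_closest_pair_merges_first(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 1.0, 10.0], [1.0, 0, 10.0], [10.0, 10.0, 0]]),
        )
        tree = hierarchical_cluster(dm)
        assert sorted(tree.linkage[0, :2]) == [0, 1]
        assert tree.linkage[0, 2] == pytest.approx(1.0)

    def test_newick_preserves_leaves_and_heights(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0, 1.0, 10.0], [1.0, 0, 10.0], [10.0, 10.0, 0]]),
        )
        nwk = tree_to_newick(hierarchical_cluster(dm))
        assert nwk.endswith(";")
        for leaf in ("A", "B", "C"):
            assert leaf in nwk
        import skbio, io

        tree = skbio.TreeNode.read(io.StringIO(nwk))
        # cophenetic distance of the first merge = 2 × merge height
        assert tree.find("A").distance(tree.find("B")) == pytest.approx(2.0)

    def test_agrees_with_naive_agglomeration(self, rng):
        """Cophenetic matrix equals a brute-force complete-linkage
        agglomeration on random 6-leaf matrices."""
        for _ in range(10):
            a = rng.random((6, 6)) + 0.01
            values = (a + a.T) / 2
            np.fill_diagonal(values, 0)
            dm = DistanceMatrix([f"u{i}" for i in range(6)], values)

            # independent naive agglomeration producing cophenetic heights
            clusters = [{i} for i in range(6)]
            coph = np.zeros((6, 6))
            while len(clusters) > 1:
                best = None
                for i in range(len(clusters)):
                    for j in range(i + 1, len(clusters)):
                        d = max(
                            values[x, y] for x in clusters[i] for y in clusters[j]
                        )
                        if best is None or d < best[0]:
                            best = (d, i, j)
                d, i, j = best
                for x in clusters[i]:
                    for y in clusters[j]:
                        coph[x, y] = coph[y, x] = d
                clusters[i] = clusters[i] | clusters[j]
                del clusters[j]

            tree = hierarchical_cluster(dm, "complete")
            got = hierarchy.cophenet(tree.linkage)
            from scipy.spatial.distance import squareform

            np.testing.assert_allclose(squareform(got), coph, atol=1e-9)

    def test_nonfinite_distances_rejected_and_cappable(self):
        v = np.array([[0, np.inf], [np.inf, 0]])
        dm = DistanceMatrix(["a", "b"], v)
        with pytest.raises(ValidationError, match="non-finite"):
            hierarchical_cluster(dm)
        capped = cap_infinite(
            DistanceMatrix(["a", "b", "c"],
                           np.array([[0, np.inf, 1.0], [np.inf, 0, 1.0],
                                     [1.0, 1.0, 0]]))
        )
        assert capped.values[0, 1] == pytest.approx(2.0)


def amova_oracle(d2, groups):
    """Brute-force SS decomposition and variance components (explicit loops)."""
    all_idx = [i for g in groups for i in g]
    n = len(all_idx)
    ss_total = sum(d2[i, j] for i in all_idx for j in all_idx) / (2.0 * n)
    ss_within = 0.0
    for g in groups:
        ss_within += sum(d2[i, j] for i in g for j in g) / (2.0 * len(g))
    ss_among = ss_total - ss_within
    g_count = len(groups)
    ms_among = ss_among / (g_count - 1)
    ms_within = ss_within / (n - g_count)
    n0 = (n - sum(len(g) ** 2 for g in groups) / n) / (g_count - 1)
    s2w = ms_within
    s2a = (ms_among - ms_within) / n0
    return ss_among, ss_within, s2a, s2w


class TestAmova:
    def test_matches_brute_force_on_toy(self, rng):
        a = rng.random((6, 6))
        values = (a + a.T) / 2
        np.fill_diagonal(values, 0)
        labels = [f"i{k}" for k in range(6)]
        dm = DistanceMatrix(labels, values)
        samples = [SampleRecord(l, "G1" if k < 3 else "G2")
                   for k, l in enumerate(labels)]
        res = amova(dm, samples, permutations=0)
        ssa, ssw, s2a, s2w = amova_oracle(values**2, [[0, 1, 2], [3, 4, 5]])
        assert res.ss_among == pytest.approx(ssa, abs=1e-9)
        assert res.ss_within == pytest.approx(ssw, abs=1e-9)
        assert res.sigma2_among == pytest.approx(s2a, abs=1e-9)
        assert res.sigma2_within == pytest.approx(s2w, abs=1e-9)
        assert res.pct_among + res.pct_within == pytest.approx(100.0, abs=1e-9)
        assert res.p_value is None  # permutations = 0 → not computed

    def test_null_labels_give_no_structure(self):
        data = simulate(
            SimConfig(pop_labels=("P",), n_per_pop=(40,), fst_per_pop=(0.001,),
                      n_loci=1500, n_outlier_loci=0, seed=23)
        )
        samples = [
            SampleRecord(s, "A" if i % 2 else "B")
            for i, s in enumerate(data.genotypes.sample_ids)
        ]
        dm = nei_distance_matrix(data.genotypes)
        res = amova(dm, samples, permutations=500, seed=0)
        assert abs(res.pct_among) < 1.0
        assert res.p_value > 0.05

    def test_diverged_populations_dominant_share(self):
        gm = _gm(np.vstack([np.zeros((4, 30)), np.full((4, 30), 2)]))
        samples = [SampleRecord(s, "A" if i < 4 else "B")
                   for i, s in enumerate(gm.sample_ids)]
        dm = manhattan_distance_matrix(gm)
        res = amova(dm, samples, permutations=200, seed=0)
        assert res.pct_among > 90.0

    def test_phi_tracks_wc_theta_on_euclidean_distances(self):
        """Cross-module consistency: AMOVA Φ_ST on squared Euclidean dosage
        distances equals 2θ/(1+θ) for two equal-n populations — between-group
        dosage variance is 4·Var(p_k) against a within variance of 2pq, so the
        individual-level decomposition doubles the among component relative to
        the gene-level θ."""
        from goatpop.differentiation import fst_pairwise

        data = simulate(
            SimConfig(pop_labels=("A", "B"), n_per_pop=(24, 24),
                      fst_per_pop=(0.02, 0.02), n_loci=5000,
                      n_outlier_loci=0, missing_rate=0.0, seed=31)
        )
        x = data.genotypes.dosage.astype(float)
        diff = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        dm = DistanceMatrix(data.genotypes.sample_ids, diff)
        res = amova(dm, data.samples, permutations=0)
        theta = fst_pairwise(data.genotypes, data.samples,
                             bootstrap_reps=0)[("A", "B")].theta
        assert res.phi_st == pytest.approx(2 * theta / (1 + theta), abs=0.01)

    def test_group_of_one_rejected(self, rng):
        a = rng.random((4, 4))
        v = (a + a.T) / 2
        np.fill_diagonal(v, 0)
        dm = DistanceMatrix(["a", "b", "c", "d"], v)
        samples = [SampleRecord("a", "G1"), SampleRecord("b", "G1"),
                   SampleRecord("c", "G1"), SampleRecord("d", "G2")]
        with pytest.raises(ValidationError, match="at least 2 individuals"):
            amova(dm, samples, permutations=0)


class TestKinship:
    def test_self_is_one_and_opposites_zero(self):
        gm = _gm([[0, 0, 0], [2, 2, 2]])
        k = ibs_kinship(gm)
        assert k.values[0, 0] == 1.0
        assert k.values[0, 1] == 0.0

    def test_unrelated_individuals_in_plausible_band(self):
        data = simulate(
            SimConfig(pop_labels=("P",), n_per_pop=(30,), fst_per_pop=(0.001,),
                      n_loci=4000, ancestral_maf_range=(0.05, 0.5),
                      n_outlier_loci=0, seed=29)
        )
        k = ibs_kinship(data.genotypes)
        off = k.values[~np.eye(30, dtype=bool)]
        assert 0.6 <= off.mean() <= 0.75
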