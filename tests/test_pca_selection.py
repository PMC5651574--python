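"""PCA, per-SNP contributions, high-contribution selection and FST validation."""

import numpy as np
import pytest

from goatpop.io_formats import GenotypeMatrix, MISSING, ValidationError
from goatpop.differentiation import fst_one_vs_rest
from goatpop.pca_selection import (
    ContributionTable,
    individual_contributions,
    run_pca,
    select_high_contribution,
    snp_contributions,
    validate_selected_by_fst,
)
from goatpop.qc import apply_qc
from goatpop.synthetic_data import SimConfig, simulate


class TestRunPca:
    def test_two_point_geometry(self, rng):
        x = np.vstack([np.tile([0.0, 0.0, 0.0, 4.0], (5, 1)),
                       np.tile([2.0, 2.0, 0.0, 0.0], (5, 1))])
        x += rng.normal(0, 1e-9, x.shape)
        pca = run_pca(x)
        # PC1 captures essentially all variance between the two clusters
        assert pca.var_fraction[0] > 0.999
        signs_a = np.sign(pca.scores[:5, 0])
        signs_b = np.sign(pca.scores[5:, 0])
        assert len(set(signs_a)) == 1 and len(set(signs_b)) == 1
        assert signs_a[0] != signs_b[0]

    def test_reconstructs_centered_matrix(self, rng):
        x = rng.normal(size=(10, 40))
        pca = run_pca(x)
        centered = x - x.mean(axis=0)
        np.testing.assert_allclose(
            pca.scores @ pca.loadings.T, centered, atol=1e-8
        )

    def test_agrees_with_sklearn(self, rng):
        from sklearn.decomposition import PCA as SkPCA

        x = rng.normal(size=(12, 30))
        pca = run_pca(x)
        sk = SkPCA().fit(x)
        np.testing.assert_allclose(
            pca.var_fraction[:11], sk.explained_variance_ratio_[:11], atol=1e-10
        )
        np.testing.assert_allclose(
            np.abs(pca.loadings[:, :5]), np.abs(sk.components_[:5].T), atol=1e-8
        )

    def test_mean_imputation_of_missing(self):
        d = np.array([[0, 1], [2, 1], [MISSING, 1]], dtype=np.int8)
        gm = GenotypeMatrix(["a", "b", "c"], ["l1", "l2"], d)
        pca = run_pca(gm)  # missing at l1 imputed to the column mean (1.0)
        assert np.isfinite(pca.scores).all()
        assert pca.scores[2, 0] == pytest.approx(0.0, abs=1e-10)

    def test_drifted_population_separates_on_pc1(self):
        separated = 0
        for seed in range(5):
            data = simulate(
                SimConfig(pop_labels=("A", "B", "T", "C"), n_per_pop=(24,) * 4,
                          fst_per_pop=(0.02, 0.02, 0.08, 0.02), n_loci=4000,
                          n_outlier_loci=0, missing_rate=0.0, seed=seed)
            )
            pca = run_pca(data.genotypes)
            pc1 = pca.scores[:, 0]
            is_t = np.array([s.breed == "T" for s in data.samples])
            from sklearn.metrics import silhouette_score

            if silhouette_score(pc1.reshape(-1, 1), is_t) > 0:
                separated += 1
        assert separated >= 4


class TestContributions:
    def test_single_variable_column_takes_all(self, rng):
        x = np.zeros((6, 5))
        x[:, 2] = rng.normal(size=6)
        pca = run_pca(x)
        con = snp_contributions(pca, 1)
        assert con.contribution_pct[2] == pytest.approx(100.0, abs=1e-8)

    def test_identity_with_squared_loadings(self, rng):
        pca = run_pca(rng.normal(size=(15, 60)))
        for comp in (1, 2, 3):
            con = snp_contributions(pca, comp)
            np.testing.assert_allclose(
                con.contribution_pct, 100 * pca.loadings[:, comp - 1] ** 2,
                atol=1e-9,
            )
            assert con.contribution_pct.sum() == pytest.approx(100.0, abs=1e-6)
            np.testing.assert_allclose(con.cos2, con.correlation**2, atol=1e-15)

    def test_chip_scale_uniform_expectation(self):
        table = ContributionTable(
            1, [f"l{j}" for j in range(48_505)], np.zeros(48_505),
            np.zeros(48_505), np.full(48_505, 100.0 / 48_505),
        )
        sel = select_high_contribution(table, 10.0)
        assert float(f"{sel.expected_pct:.2g}") == pytest.approx(0.0021)
        assert sel.threshold_pct >= 0.02


class TestSelection:
    def test_uniform_contributions_select_nothing(self):
        table = ContributionTable(
            1, [f"l{j}" for j in range(100)], np.zeros(100), np.zeros(100),
            np.full(100, 1.0),
        )
        assert select_high_contribution(table, 10.0).locus_ids == []

    def test_dominant_locus_selected(self):
        pct = np.zeros(1000)
        pct[7] = 100.0
        table = ContributionTable(1, [f"l{j}" for j in range(1000)],
                                  np.zeros(1000), np.zeros(1000), pct)
        assert select_high_contribution(table, 10.0).locus_ids == ["l7"]

    def test_threshold_is_inclusive(self):
        pct = np.full(10, 0.0)
        pct[0] = 10 * 100.0 / 10  # exactly the threshold
        table = ContributionTable(1, [f"l{j}" for j in range(10)],
                                  np.zeros(10), np.zeros(10), pct)
        assert "l0" in select_high_contribution(table, 10.0).locus_ids

    def test_scale_equivariance(self, rng):
        x = rng.integers(0, 3, size=(20, 300)).astype(float)
        sel_a = select_high_contribution(snp_contributions(run_pca(x), 1))
        sel_b = select_high_contribution(snp_contributions(run_pca(3.0 * x), 1))
        assert sel_a.locus_ids == sel_b.locus_ids

    def test_planted_loci_found_with_few_false_selections(self):
        """≥60% median sensitivity and <1% false selections for 50 planted
        frequency-shifted loci (δ=0.35) on an undifferentiated background."""
        sens, fpr = [], []
        for seed in (100, 101, 102, 103, 104):
            data = simulate(
                SimConfig(pop_labels=("A", "B", "T", "C"), n_per_pop=(24,) * 4,
                          n_loci=10_000, fst_per_pop=(0.002,) * 4,
                          n_outlier_loci=50, outlier_target_pop="T",
                          outlier_delta=0.35, seed=seed)
            )
            gm, _ = apply_qc(data.genotypes, data.snps)
            sel = set(
                select_high_contribution(
                    snp_contributions(run_pca(gm), 1), 10.0
                ).locus_ids
            )
            planted = set(data.truth.outlier_locus_ids) & set(gm.locus_ids)
            sens.append(len(sel & planted) / len(planted))
            fpr.append(len(sel - planted) / (gm.n_loci - len(planted)))
        assert np.median(sens) >= 0.6
        assert max(fpr) < 0.01


class TestIndividualContributions:
    def test_sums_and_brute_force(self, rng):
        pca = run_pca(rng.normal(size=(12, 50)))
        contrib = individual_contributions(pca, 10)
        np.testing.assert_allclose(contrib.sum(axis=0), 100.0, atol=1e-9)
        expected = 100 * pca.scores[:, :10] ** 2 / (
            (pca.scores[:, :10] ** 2).sum(axis=0)
        )
        np.testing.assert_allclose(contrib, expected, atol=1e-9)

    def test_outlier_individual_dominates_its_component(self, rng):
        x = rng.normal(0, 0.01, size=(10, 40))
        x[0] += 5.0 * rng.normal(size=40)
        contrib = individual_contributions(run_pca(x), 1)
        assert contrib[0, 0] > 80.0


class TestValidation:
    @staticmethod
    def _one_vs_rest(sim, gm):
        return {
            b: fst_one_vs_rest(gm, sim.samples, b, bootstrap_reps=0)
            for b in ("NU", "D", "T", "NI")
        }

    def test_drifted_population_counts_maximal(self, small_sim, small_qc):
        gm, _ = small_qc
        pca = run_pca(gm)
        sel = select_high_contribution(snp_contributions(pca, 1), 10.0)
        val = validate_selected_by_fst(
            sel, self._one_vs_rest(small_sim, gm), 2.0, pca.locus_ids
        )
        counts = {b: v.n_selected_above for b, v in val.items()}
        assert counts["T"] == max(counts.values())
        assert counts["T"] > counts["NU"]

    def test_constant_theta_degenerate_counts_zero(self):
        from goatpop.differentiation import FstEstimate
        from goatpop.pca_selection import SelectedSnpSet

        est = FstEstimate(("X", "rest"), 0.1, None, None, None, None,
                          ["l0", "l1", "l2"], np.full(3, 0.1),
                          np.zeros(3), np.ones(3))
        sel = SelectedSnpSet(1, 1.0, 10.0, 10.0, ["l1"], np.array([50.0]))
        val = validate_selected_by_fst(sel, {"X": est}, 2.0)
        assert val["X"].theta_sd == pytest.approx(0.0, abs=1e-12)
        assert val["X"].n_selected_above == 0  # strict '>' at threshold = mean

    def test_k_zero_counts_loci_above_mean(self, rng):
        from goatpop.differentiation import FstEstimate
        from goatpop.pca_selection import SelectedSnpSet

        theta = rng.normal(0.01, 0.005, 100)
        est = FstEstimate(("X", "rest"), 0.01, None, None, None, None,
                          [f"l{j}" for j in range(100)], theta,
                          np.zeros(100), np.ones(100))
        sel = SelectedSnpSet(1, 1.0, 10.0, 10.0, [], np.array([]))
        val = validate_selected_by_fst(sel, {"X": est}, 0.0)
        assert val["X"].n_genomewide_above == (theta > theta.mean()).sum()

    def test_misaligned_locus_sets_rejected(self):
        from goatpop.differentiation import FstEstimate
        from goatpop.pca_selection import SelectedSnpSet

        est = FstEstimate(("X", "rest"), 0.1, None, None, None, None,
                          ["stray"], np.array([0.1]), np.zeros(1), np.ones(1))
        sel = SelectedSnpSet(1, 1.0, 10.0, 10.0, [], np.array([]))
        with pytest.raises(ValidationError, match="misaligned"):
            validate_selected_by_fst(sel, {"X": est}, 2.0, ["l0", "l1"])


def test_end_to_end_planted_recovery_and_validation():
    """On one-drifted-population simulations the selected set overlaps the
    planted loci (median Jaccard ≥ 0.4) and the drifted population's
    validation count is maximal in ≥ 18/20 seeds."""
    jaccards, maximal = [], 0
    for seed in range(20):
        data = simulate(
            SimConfig(pop_labels=("A", "B", "T", "C"), n_per_pop=(24,) * 4,
                      n_loci=10_000, fst_per_pop=(0.005, 0.005, 0.02, 0.005),
                      n_outlier_loci=50, outlier_target_pop="T",
                      outlier_delta=0.35, seed=seed)
        )
        gm, _ = apply_qc(data.genotypes, data.snps)
        pca = run_pca(gm)
        sel = select_high_contribution(snp_contributions(pca, 1), 10.0)
        planted = set(data.truth.outlier_locus_ids) & set(gm.locus_ids)
        s = set(sel.locus_ids)
        jaccards.append(len(s & planted) / len(s | planted))
        fst = {
            b: fst_one_vs_rest(gm, data.samples, b, bootstrap_reps=0)
            for b in ("A", "B", "T", "C")
        }
        val = validate_selected_by_fst(sel, fst, 2.0, pca.locus_ids)
        counts = {b: v.n_selected_above for b, v in val.items()}
        others = max(v for b, v in counts.items() if b != "T")
        if counts["T"] == max(counts.values()) and counts["T"] > others:
            maximal += 1
    assert np.median(jaccards) >= 0.4
    assert maximal >= 18
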