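import numpy as np
import pytest
from scipy.stats import poisson

from sper.core import (
    SPERConfig,
    adjust_by_prevalence,
    build_bins,
    composition_shell_operators,
    paired_expression_ratio,
    poisson_weights,
    run_sper,
    sper_score,
)
from sper.datatypes import CompositionMatrix, ExpressionMatrix, PrevalenceMatrix, SpotGeometry
from sper.io import normalize_expression

from conftest import grid_geometry, random_instance
from oracles import sper_oracle


class TestBins:
    def test_half_open_shell_membership(self):
        geom = SpotGeometry(["a", "b", "c"], np.array([[0.0, 0], [150.0, 0], [100.0, 0]]), spacing=100.0)
        bins = build_bins(geom, bin_width=100, max_distance=300)
        A2 = bins.shell_indicator(2)
        assert A2[0, 1] and A2[1, 0]  # 150 um -> (100, 200]
        A1 = bins.shell_indicator(1)
        assert A1[0, 2]  # exactly 100 um belongs to the inner shell

    def test_same_spot_is_shell_zero(self, small_grid):
        bins = build_bins(small_grid)
        A0 = bins.shell_indicator(0)
        np.testing.assert_array_equal(A0, np.eye(small_grid.n_spots, dtype=bool))

    def test_distant_pairs_capped_into_last_shell(self):
        geom = SpotGeometry(["a", "b"], np.array([[0.0, 0], [450.0, 0]]), spacing=100.0)
        bins = build_bins(geom, bin_width=100, max_distance=300)
        last = bins.shell_indicator(bins.n_shells - 1)
        assert last[0, 1]

    def test_partition_property(self, small_grid):
        """Every spot pair falls into exactly one shell after capping."""
        bins = build_bins(small_grid, bin_width=100, max_distance=300)
        total = np.zeros((small_grid.n_spots,) * 2, dtype=int)
        for i in range(bins.n_shells):
            ind = bins.shell_indicator(i)
            np.testing.assert_array_equal(ind, ind.T)  # symmetric
            total += ind
        np.testing.assert_array_equal(total, 1)

    def test_neighbor_counts_match_indicators(self, small_grid):
        bins = build_bins(small_grid)
        for i in range(bins.n_shells):
            np.testing.assert_array_equal(
                bins.neighbor_counts[:, i], bins.shell_indicator(i).sum(axis=1)
            )

    def test_fewer_than_two_spots_rejected(self):
        geom = SpotGeometry(["only"], np.zeros((1, 2)), spacing=1.0)
        with pytest.raises(ValueError, match="2 spots"):
            build_bins(geom)


class TestPoissonWeights:
    def test_unit_sum_any_shape(self):
        for lam, n in [(0.3, 1), (2.5, 11), (7.0, 4)]:
            w = poisson_weights(lam, n)
            assert w.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_shell_degenerate(self):
        np.testing.assert_array_equal(poisson_weights(2.5, 1).weights, [1.0])

    def test_default_rate_peaks_at_shell_two(self):
        w = poisson_weights(2.5, 11)
        assert int(np.argmax(w.weights)) == 2
        # independent pmf evaluation
        pmf = poisson.pmf(np.arange(11), 2.5)
        np.testing.assert_allclose(w.weights, pmf / pmf.sum(), rtol=1e-12)


class TestPairedExpressionRatio:
    def test_hand_evaluated_row_of_three_spots(self):
        geom = SpotGeometry(["s0", "s1", "s2"], np.array([[0.0, 0], [100.0, 0], [200.0, 0]]), spacing=100.0)
        bins = build_bins(geom, bin_width=100, max_distance=200)
        E = ExpressionMatrix(["s0", "s1", "s2"], ["g"], np.array([[0.0], [2.0], [0.0]]), normalized=True)
        C = CompositionMatrix(
            ["t", "other"], ["s0", "s1", "s2"], np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 1.0]])
        )
        R1 = paired_expression_ratio(C, bins, E, shell_index=1)
        assert R1[0, 0] == pytest.approx(2.0)  # sole neighbor of s0 in shell 1 is s1

    def test_constant_gene_scores_one_everywhere(self, small_grid):
        n = small_grid.n_spots
        E = ExpressionMatrix(small_grid.spot_ids, ["g"], np.ones((n, 1)), normalized=True)
        C = CompositionMatrix(["t1", "t2"], small_grid.spot_ids, np.full((2, n), 0.5))
        bins = build_bins(small_grid, bin_width=100, max_distance=400)
        for i in range(bins.n_shells):
            if (bins.neighbor_counts[:, i] > 0).all():
                R = paired_expression_ratio(C, bins, E, i)
                np.testing.assert_allclose(R, 1.0, atol=1e-12)

    def test_requires_normalized_expression(self, small_grid):
        n = small_grid.n_spots
        E = ExpressionMatrix(small_grid.spot_ids, ["g"], np.ones((n, 1)), normalized=False)
        C = CompositionMatrix(["t"], small_grid.spot_ids, np.full((1, n), 1.0))
        bins = build_bins(small_grid)
        with pytest.raises(ValueError, match="normalized"):
            paired_expression_ratio(C, bins, E, 0)

    def test_shell_index_out_of_range(self, small_grid):
        n = small_grid.n_spots
        E = ExpressionMatrix(small_grid.spot_ids, ["g"], np.ones((n, 1)), normalized=True)
        C = CompositionMatrix(["t"], small_grid.spot_ids, np.full((1, n), 1.0))
        bins = build_bins(small_grid)
        with pytest.raises(IndexError):
            paired_expression_ratio(C, bins, E, bins.n_shells)


class TestScoreAlgebra:
    def test_one_hot_weight_selects_single_shell(self, rng):
        R = rng.normal(size=(4, 2, 3))
        w = poisson_weights(2.5, 4)
        w.weights = np.array([0.0, 0.0, 1.0, 0.0])
        np.testing.assert_array_equal(sper_score(R, w), R[2])

    def test_weight_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="weights"):
            sper_score(rng.normal(size=(3, 2, 2)), poisson_weights(2.5, 4))

    def test_resummation_oracle(self, rng):
        R = rng.normal(size=(6, 3, 5))
        w = poisson_weights(1.7, 6)
        expected = sum(w.weights[i] * R[i] for i in range(6))
        np.testing.assert_allclose(sper_score(R, w), expected, atol=1e-12)

    @pytest.mark.parametrize(
        "s, p, expected",
        [(1.0, 1.0, 1.0), (1.0, 0.0, np.exp(-1.0)), (2.0, 0.5, 2.0 * np.exp(-0.5))],
    )
    def test_prevalence_adjustment_closed_form(self, s, p, expected):
        out = adjust_by_prevalence(np.array([[s]]), np.array([[p]]))
        assert out[0, 0] == pytest.approx(expected, rel=1e-12)


class TestOracleEquivalence:
    def test_vectorized_matches_triple_loop_on_random_instances(self):
        """The chunked/vectorized pipeline reproduces the brute-force
        (type, spot, neighbor) reference on 20 random small instances."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            expr, comp, geom = random_instance(rng, n_max=60, m_max=8, k_max=4)
            bin_width, max_distance, lam = 120.0, 480.0, 2.5
            R_ref, phi_ref, S_ref = sper_oracle(
                expr.values, comp.values, geom.coordinates, bin_width, max_distance, lam
            )
            res = run_sper(
                expr, comp, geom,
                SPERConfig(bin_width_um=bin_width, max_distance_um=max_distance, weight_lambda=lam),
            )
            np.testing.assert_allclose(res.ratio_curves, R_ref, atol=1e-10)
            np.testing.assert_allclose(res.weights.weights, phi_ref, atol=1e-12)
            np.testing.assert_allclose(res.raw_scores, S_ref, atol=1e-10)


class TestRunSper:
    def _fixture(self, rng, side=10, m=12, k=3):
        geom = grid_geometry(side)
        n = geom.n_spots
        counts = rng.poisson(3.0, size=(n, m)).astype(float)
        expr = ExpressionMatrix(geom.spot_ids, [f"g{i}" for i in range(m)], counts)
        comp = CompositionMatrix(
            [f"t{i}" for i in range(k)], geom.spot_ids, rng.dirichlet(np.ones(k), size=n).T
        )
        return expr, comp, geom

    def test_deterministic_across_runs(self, rng):
        expr, comp, geom = self._fixture(rng)
        a = run_sper(expr, comp, geom, SPERConfig())
        b = run_sper(expr, comp, geom, SPERConfig())
        np.testing.assert_array_equal(a.raw_scores, b.raw_scores)
        np.testing.assert_array_equal(a.adjusted_scores, b.adjusted_scores)

    def test_scale_equivariance_of_gene_columns(self, rng):
        """Multiplying one gene's counts by a constant leaves its score unchanged."""
        expr, comp, geom = self._fixture(rng)
        scaled = expr.values.copy()
        scaled[:, 3] *= 37.0
        a = run_sper(expr, comp, geom)
        b = run_sper(ExpressionMatrix(expr.spot_ids, expr.gene_ids, scaled), comp, geom)
        np.testing.assert_allclose(a.raw_scores, b.raw_scores, rtol=1e-10)

    def test_all_zero_gene_scores_zero(self, rng):
        expr, comp, geom = self._fixture(rng)
        values = expr.values.copy()
        values[:, 5] = 0.0
        res = run_sper(ExpressionMatrix(expr.spot_ids, expr.gene_ids, values), comp, geom)
        np.testing.assert_array_equal(res.raw_scores[:, 5], 0.0)

    def test_no_prevalence_means_adjusted_equals_raw(self, rng):
        expr, comp, geom = self._fixture(rng)
        res = run_sper(expr, comp, geom)
        np.testing.assert_array_equal(res.adjusted_scores, res.raw_scores)

    def test_prevalence_changes_only_adjusted(self, rng):
        expr, comp, geom = self._fixture(rng)
        prev = PrevalenceMatrix(
            comp.cell_type_ids, expr.gene_ids, np.zeros((comp.n_types, expr.n_genes))
        )
        res = run_sper(expr, comp, geom, prevalence=prev)
        np.testing.assert_allclose(res.adjusted_scores, res.raw_scores * np.exp(-1.0), rtol=1e-12)

    def test_raw_scores_recomputable_from_ratio_curves(self, rng):
        expr, comp, geom = self._fixture(rng)
        res = run_sper(expr, comp, geom)
        np.testing.assert_allclose(
            res.raw_scores, sper_score(res.ratio_curves, res.weights), atol=1e-12
        )


class TestNullCalibration:
    def test_permuted_gene_ratio_means_near_one(self):
        """For iid permutations of fixed values, E[R_i] = 1 at every shell."""
        rng = np.random.default_rng(11)
        geom = grid_geometry(8)
        n = geom.n_spots
        values = rng.poisson(4.0, size=n).astype(float) + 0.5
        x = values / values.mean()
        u = rng.uniform(0.05, 0.95, size=n)
        comp = CompositionMatrix(["t", "rest"], geom.spot_ids, np.vstack([u, 1.0 - u]))
        bins = build_bins(geom)
        Ct = comp.values / comp.values.sum(axis=1, keepdims=True)
        B = composition_shell_operators(Ct, bins)  # (n_shells, 1, n)
        n_perm = 1000
        samples = np.empty((n_perm, bins.n_shells))
        for p in range(n_perm):
            xp = x[rng.permutation(n)]
            samples[p] = (B @ xp)[:, 0]
        mean = samples.mean(axis=0)
        se = samples.std(axis=0, ddof=1) / np.sqrt(n_perm)
        covered = bins.neighbor_counts.min(axis=0) > 0
        assert (np.abs(mean[covered] - 1.0) <= 3 * np.maximum(se[covered], 1e-12)).all()


def test_monotone_locality_of_default_weights():
    """Moving a gene's sole expression mass from a target-adjacent spot to a
    far spot strictly decreases the target's score."""
    geom = grid_geometry(7)
    n = geom.n_spots
    ids = list(geom.spot_ids)
    target_spot = ids.index("s3_3")
    near, far = ids.index("s3_4"), ids.index("s0_6")
    comp = np.full((2, n), 0.0)
    comp[0, target_spot] = 1.0
    comp[1] = (1.0 - comp[0]) / (n - 1)
    C = CompositionMatrix(["target", "rest"], ids, comp / comp.sum(axis=0))
    scores = {}
    for name, spot in [("near", near), ("far", far)]:
        counts = np.zeros((n, 1))
        counts[spot, 0] = 50.0
        expr = ExpressionMatrix(ids, ["g"], counts)
        scores[name] = run_sper(expr, C, geom).raw_scores[0, 0]
    assert scores["near"] > scores["far"]


def test_raw_composition_mode_scales_with_abundance(rng):
    """'raw' composition normalization reproduces the literal matrix product:
    doubling a type's total composition mass doubles its score."""
    expr, comp, geom = random_instance(rng, n_max=30, m_max=4, k_max=2)
    res1 = run_sper(expr, comp, geom, SPERConfig(c_normalization="raw"))
    res2 = run_sper(expr, comp, geom, SPERConfig(c_normalization="rowsum"))
    row_mass = comp.values.sum(axis=1)
    np.testing.assert_allclose(res1.raw_scores, res2.raw_scores * row_mass[:, None], rtol=1e-10)
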