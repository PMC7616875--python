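"""Lee's L, Moran's I, spatial weights and the permutation test."""

import subprocess
import sys
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pgsmap.errors import (
    AlignmentError,
    DegenerateWeightsError,
    TransformError,
    ZeroVarianceError,
)
from pgsmap.grid import AnalysisGrid, build_hex_grid
from pgsmap.spatial import (
    SpatialWeightMatrix,
    bonferroni_flag,
    compare_maps,
    contiguity_weights,
    env_transform,
    lee_permutation_test,
    lee_statistic,
    moran_i,
)

from oracles import lee_L_oracle, moran_I_oracle, random_weight_matrix


def path_graph_W(n, row_standardize=True):
    V = np.zeros((n, n))
    for i in range(n - 1):
        V[i, i + 1] = V[i + 1, i] = 1.0
    W = SpatialWeightMatrix(V)
    return W.row_standardize() if row_standardize else W


class TestSpatialWeightMatrix:
    def test_rejects_nonzero_diagonal_and_negative_weights(self):
        with pytest.raises(ValueError):
            SpatialWeightMatrix(np.eye(3))
        with pytest.raises(ValueError):
            SpatialWeightMatrix(-np.ones((2, 2)) + np.eye(2))

    def test_row_standardization_sums_to_one(self, rng):
        V = random_weight_matrix(rng, 20)
        W = SpatialWeightMatrix(V).row_standardize()
        assert np.allclose(W.matrix.sum(axis=1), 1.0, atol=1e-12)
        assert W.row_standardized


class TestContiguityWeights:
    def test_interior_node_row_standardized_entries(self, grid300, W300):
        interior = max(range(grid300.n_nodes), key=lambda i: len(grid300.adjacency[i]))
        assert len(grid300.adjacency[interior]) == 6
        row = W300.matrix[interior]
        assert np.allclose(row[row > 0], 1 / 6)

    def test_two_adjacent_nodes(self):
        grid = AnalysisGrid(
            nodes=np.array([[0.0, 0.0], [1.0, 0.0]]),
            spacing=1.0,
            region=build_hex_grid((0, 0, 2, 2), spacing=1.0).region,
        )
        W = contiguity_weights(grid, row_standardize=False)
        assert np.array_equal(W.matrix, np.array([[0.0, 1.0], [1.0, 0.0]]))

    def test_matches_brute_force_distance_threshold(self, grid300):
        W = contiguity_weights(grid300, row_standardize=False).matrix
        nodes = grid300.nodes
        d = np.hypot(
            nodes[:, 0:1] - nodes[None, :, 0], nodes[:, 1:2] - nodes[None, :, 1]
        )
        brute = ((d <= 1.01 * grid300.spacing) & (d > 0)).astype(float)
        assert np.array_equal(W, brute)

    def test_isolated_node_logs_warning(self, caplog):
        grid = AnalysisGrid(
            nodes=np.array([[0.0, 0.0], [1.0, 0.0], [50.0, 50.0]]),
            spacing=1.0,
            region=build_hex_grid((0, 0, 100, 100), spacing=1.0).region,
        )
        with caplog.at_level("WARNING", logger="pgsmap.spatial"):
            W = contiguity_weights(grid)
        assert "isolated" in caplog.text
        assert W.matrix[2].sum() == 0


class TestLeeStatistic:
    def test_self_only_diagonal_weights_reduce_to_pearson(self, rng):
        # bypass the zero-diagonal constraint: this special case is the
        # analytic limit where the spatial lag is the value itself
        for _ in range(20):
            n = rng.integers(10, 60)
            x, y = rng.normal(size=(2, n))
            W = SpatialWeightMatrix(np.zeros((n, n)))
            W.matrix = np.eye(n)
            L = lee_statistic(x, y, W)
            assert L == pytest.approx(stats.pearsonr(x, y).statistic, abs=1e-12)

    def test_identical_inputs_self_only_weights_give_one(self, rng):
        x = rng.normal(size=30)
        W = SpatialWeightMatrix(np.zeros((30, 30)))
        W.matrix = np.eye(30)
        assert lee_statistic(x, x, W) == pytest.approx(1.0, abs=1e-12)

    def test_path_graph_matches_direct_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([4.0, 3.0, 2.0, 1.0])
        W = path_graph_W(4)
        expected = lee_L_oracle(x.tolist(), y.tolist(), W.matrix.tolist())
        assert lee_statistic(x, y, W) == pytest.approx(expected, abs=1e-12)

    def test_oracle_equivalence_random_instances(self, rng):
        for k in range(50):
            n = int(rng.integers(5, 200))
            x, y = rng.normal(size=(2, n))
            V = random_weight_matrix(rng, n, row_standardize=bool(k % 2))
            W = SpatialWeightMatrix(V, row_standardized=bool(k % 2))
            assert lee_statistic(x, y, W) == pytest.approx(
                lee_L_oracle(x.tolist(), y.tolist(), V.tolist()), rel=1e-8
            )

    def test_symmetry_in_arguments(self, rng, W300):
        x, y = rng.normal(size=(2, W300.n))
        assert lee_statistic(x, y, W300) == lee_statistic(y, x, W300)

    @settings(max_examples=30, deadline=None)
    @given(
        a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-10, 10),
        c=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
        d=st.floats(-10, 10),
    )
    def test_affine_equivariance(self, a, b, c, d):
        rng = np.random.default_rng(7)
        n = 40
        x, y = rng.normal(size=(2, n))
        V = random_weight_matrix(rng, n, row_standardize=True)
        W = SpatialWeightMatrix(V, row_standardized=True)
        L = lee_statistic(x, y, W)
        L2 = lee_statistic(a * x + b, c * y + d, W)
        assert L2 == pytest.approx(np.sign(a * c) * L, abs=1e-10)

    def test_bounded_by_one_with_row_standardized_weights(self, rng):
        for _ in range(1000):
            n = int(rng.integers(5, 40))
            x, y = rng.normal(size=(2, n))
            V = random_weight_matrix(rng, n, row_standardize=True)
            W = SpatialWeightMatrix(V, row_standardized=True)
            assert abs(lee_statistic(x, y, W)) <= 1.0 + 1e-12

    def test_degenerate_inputs_raise(self, W300, rng):
        x = rng.normal(size=W300.n)
        with pytest.raises(ZeroVarianceError):
            lee_statistic(x, np.ones(W300.n), W300)
        Wz = SpatialWeightMatrix(np.zeros((10, 10)))
        with pytest.raises(DegenerateWeightsError):
            lee_statistic(np.arange(10.0), np.arange(10.0) ** 2, Wz)


class TestMoranI:
    def test_smooth_gradient_positive_autocorrelation(self):
        x = np.arange(20.0)
        assert moran_i(x, path_graph_W(20)) > 0

    def test_alternating_signs_on_path_graph(self):
        x = np.tile([1.0, -1.0], 10)
        assert moran_i(x, path_graph_W(20)) == pytest.approx(-1.0, abs=1e-12)

    def test_oracle_equivalence_random_instances(self, rng):
        for k in range(50):
            n = int(rng.integers(5, 200))
            x = rng.normal(size=n)
            V = random_weight_matrix(rng, n, row_standardize=bool(k % 2))
            W = SpatialWeightMatrix(V, row_standardized=bool(k % 2))
            assert moran_i(x, W) == pytest.approx(
                moran_I_oracle(x.tolist(), V.tolist()), rel=1e-8
            )

    def test_permutation_null_mean(self, rng):
        """Expected Moran's I under random relabelling is -1/(n-1)."""
        n = 50
        x = rng.normal(size=n)
        V = random_weight_matrix(rng, n, row_standardize=True)
        W = SpatialWeightMatrix(V, row_standardized=True)
        draws = np.array(
            [moran_i(rng.permutation(x), W) for _ in range(10_000)]
        )
        expected = -1.0 / (n - 1)
        mc_err = 4 * draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < mc_err


class TestMoranAgainstApe:
    def test_agreement_with_R_ape(self, rng, tmp_path):
        """Cross-check Moran's I against the R `ape` implementation."""
        cases = []
        for _ in range(10):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=n)
            V = random_weight_matrix(rng, n)
            # ape row-standardizes the supplied weights internally
            W = SpatialWeightMatrix(V).row_standardize()
            cases.append((x, V, moran_i(x, W)))
        for i, (x, V, _) in enumerate(cases):
            np.savetxt(tmp_path / f"x{i}.txt", x)
            np.savetxt(tmp_path / f"V{i}.txt", V)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(ape))
            for (i in 0:{len(cases) - 1}) {{
              x <- scan(sprintf("%s/x%d.txt", "{tmp_path}", i), quiet=TRUE)
              V <- as.matrix(read.table(sprintf("%s/V%d.txt", "{tmp_path}", i)))
              cat(sprintf("%.12f\\n", Moran.I(x, V, scaled=FALSE)$observed))
            }}
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert out.returncode == 0, out.stderr
        got = [float(v) for v in out.stdout.split()]
        for (_, _, ours), theirs in zip(cases, got):
            assert ours == pytest.approx(theirs, abs=1e-8)


class TestPermutationTest:
    def test_minimum_attainable_p_is_two_over_m_plus_one(self, grid300, W300):
        x = grid300.nodes[:, 0] + grid300.nodes[:, 1]  # perfectly smooth
        res = lee_permutation_test(x, x, W300, M=999, seed=3)
        assert res.p_two_tailed == pytest.approx(2.0 / 1000)

    def test_p_respects_floor_and_cap(self, rng, W300):
        x, y = rng.normal(size=(2, W300.n))
        res = lee_permutation_test(x, y, W300, M=199, seed=1)
        assert 2.0 / 200 <= res.p_two_tailed <= 1.0

    def test_deterministic_under_seed(self, rng, W300):
        x, y = rng.normal(size=(2, W300.n))
        r1 = lee_permutation_test(x, y, W300, M=199, seed=42)
        r2 = lee_permutation_test(x, y, W300, M=199, seed=42)
        assert r1 == r2

    def test_strong_spatial_smoothing_hits_floor(self, rng, grid300, W300):
        base = grid300.nodes[:, 0] / 1000.0
        x = base + 0.1 * rng.normal(size=W300.n)
        y = base + 0.1 * rng.normal(size=W300.n)
        res = lee_permutation_test(x, y, W300, M=199, seed=9)
        assert res.p_two_tailed == pytest.approx(2.0 / 200)

    def test_single_scheme_keeps_first_variable_fixed(self, rng, W300):
        x, y = rng.normal(size=(2, W300.n))
        res = lee_permutation_test(x, y, W300, M=99, seed=5, scheme="single")
        assert res.scheme == "single"

    def test_rejects_bad_arguments(self, rng, W300):
        x, y = rng.normal(size=(2, W300.n))
        with pytest.raises(ValueError):
            lee_permutation_test(x, y, W300, M=50)
        with pytest.raises(ValueError):
            lee_permutation_test(x, y, W300, M=99, scheme="bogus")


class TestCompareMaps:
    def test_self_comparison_hits_floor(self, grid300, W300):
        vals = grid300.nodes[:, 0] + 0.3 * grid300.nodes[:, 1]
        res = compare_maps(vals, vals.copy(), W300, M=199, seed=2)
        assert res.p_two_tailed == pytest.approx(2.0 / 200)
        assert res.L_obs > 0.9

    def test_alignment_error_lists_unmatched_nodes(self, W300, rng):
        import pandas as pd

        a = pd.Series(rng.normal(size=W300.n), index=range(W300.n))
        b = pd.Series(rng.normal(size=W300.n), index=range(1, W300.n + 1))
        with pytest.raises(AlignmentError):
            compare_maps(a, b, W300, M=99)

    def test_shuffled_map_p_uniform_under_single_scheme(self, rng, grid300, W300):
        """Shuffling one map's node values destroys any co-patterning; the
        conditional (single-permutation) test should then be calibrated."""
        smooth = grid300.nodes[:, 0] + grid300.nodes[:, 1]
        ps = []
        for rep in range(200):
            shuffled = rng.permutation(smooth)
            res = compare_maps(
                smooth, shuffled, W300, M=199, seed=1000 + rep, scheme="single"
            )
            ps.append(res.p_two_tailed)
        rej = np.mean(np.asarray(ps) < 0.05)
        lo, hi = stats.binom.interval(0.99, 200, 0.05)
        assert lo / 200 <= rej <= hi / 200


class TestEnvTransformAndBonferroni:
    def test_log_transform_and_round_trip(self):
        vals = np.array([1.0, np.e, np.e**2])
        assert np.allclose(env_transform(vals, "log"), [0, 1, 2], atol=1e-12)
        assert np.allclose(np.exp(env_transform(vals, "log")), vals, atol=1e-12)
        assert np.array_equal(env_transform(vals, "identity"), vals)

    def test_log_of_nonpositive_reports_offenders(self):
        with pytest.raises(TransformError, match="2"):
            env_transform(np.array([1.0, 2.0, -1.0]), "log")
        with pytest.raises(TransformError):
            env_transform(np.ones(3), "sqrt")

    def test_bonferroni_rule(self):
        flags = bonferroni_flag([0.01, 2e-4, 0.04], alpha=0.05, k=15)
        assert flags.tolist() == [False, True, False]
        assert bonferroni_flag([0.04], k=1).tolist() == [True]
        with pytest.raises(ValueError):
            bonferroni_flag([0.01], k=0)
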