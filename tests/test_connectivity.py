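"""RV coefficient, Pearson FC, thresholding and knee selection."""

import numpy as np
import pytest

from mhnet.connectivity import (
    RetainedEdgeCurve,
    ThresholdConfig,
    pearson_fc,
    retained_edge_curve,
    rv_coefficient,
    select_cutoff,
    threshold_adjacency,
)
from mhnet.data_model import RegionMeanSeries
from mhnet.errors import ConfigError, DegenerateInputError, NoKneeError


def rv_bruteforce(A, B):
    """Trace-formula oracle forming AA' and BB' explicitly."""
    A = A - A.mean(axis=0, keepdims=True)
    B = B - B.mean(axis=0, keepdims=True)
    AAt, BBt = A @ A.T, B @ B.T
    return np.trace(AAt @ BBt) / np.sqrt(
        np.trace(AAt @ AAt) * np.trace(BBt @ BBt)
    )


class TestRVCoefficient:
    def test_self_similarity_is_one(self, rng):
        A = rng.standard_normal((12, 5))
        assert rv_coefficient(A, A) == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(100):
            A = rng.standard_normal((10, 3))
            B = rng.standard_normal((10, 4))
            assert abs(rv_coefficient(A, B) - rv_bruteforce(A, B)) < 1e-10

    def test_single_column_equals_squared_pearson(self, rng):
        for _ in range(50):
            a = rng.standard_normal((20, 1))
            b = rng.standard_normal((20, 1))
            r = np.corrcoef(a[:, 0], b[:, 0])[0, 1]
            assert rv_coefficient(a, b) == pytest.approx(r**2, abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        A = rng.standard_normal((9, 2))
        B = rng.standard_normal((9, 6))
        assert rv_coefficient(A, B) == pytest.approx(
            rv_coefficient(B, A), abs=1e-14
        )

    def test_orthogonal_rotation_invariance(self, rng):
        A = rng.standard_normal((15, 4))
        B = rng.standard_normal((15, 3))
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        assert rv_coefficient(A @ Q, B) == pytest.approx(
            rv_coefficient(A, B), abs=1e-10
        )

    def test_constant_matrix_raises(self):
        A = np.ones((6, 2))
        B = np.arange(12.0).reshape(6, 2)
        with pytest.raises(DegenerateInputError):
            rv_coefficient(A, B)

    def test_uncentered_option_changes_result(self, rng):
        A = rng.standard_normal((10, 2)) + 5.0
        B = rng.standard_normal((10, 3)) + 5.0
        assert rv_coefficient(A, B, center=False) > rv_coefficient(A, B)


class TestPearsonFC:
    def test_identical_and_negated_columns(self, rng):
        x = rng.standard_normal(30)
        series = RegionMeanSeries(
            "s", np.column_stack([x, x, -x]), ["r1", "r2", "r3"]
        )
        fc = pearson_fc(series)
        assert fc[0, 1] == pytest.approx(1.0)
        assert fc[0, 2] == pytest.approx(-1.0)
        assert np.all(np.diag(fc) == 1.0)

    def test_matches_covariance_formula(self, rng):
        X = rng.standard_normal((50, 20))
        series = RegionMeanSeries("s", X, [f"r{i}" for i in range(20)])
        fc = pearson_fc(series)
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        sd = np.sqrt(np.diag(cov))
        expected = cov / np.outer(sd, sd)
        assert np.max(np.abs(fc - expected)) < 1e-12

    def test_zero_variance_column_names_region(self):
        X = np.column_stack([np.arange(10.0), np.ones(10)])
        series = RegionMeanSeries("s", X, ["ok", "flat"])
        with pytest.raises(DegenerateInputError, match="flat"):
            pearson_fc(series)

    def test_squared_fc_equals_rv_of_single_columns(self, rng):
        X = rng.standard_normal((40, 4))
        series = RegionMeanSeries("s", X, list("abcd"))
        fc = pearson_fc(series)
        for i in range(4):
            for j in range(i + 1, 4):
                rv = rv_coefficient(X[:, [i]], X[:, [j]])
                assert fc[i, j] ** 2 == pytest.approx(rv, abs=1e-10)


class TestThresholdAdjacency:
    def test_high_gamma_gives_identity(self, rng):
        R = np.abs(np.corrcoef(rng.standard_normal((20, 5)), rowvar=False))
        A = threshold_adjacency(R, 1 - 1e-12)
        assert np.array_equal(A, np.eye(5))

    def test_gamma_zero_keeps_positive_entries(self):
        R = np.array([[1.0, 0.3], [0.3, 1.0]])
        A = threshold_adjacency(R, 0.0)
        assert A[0, 1] == 0.3

    def test_strict_inequality_drops_equal_entries(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert threshold_adjacency(R, 0.5)[0, 1] == 0.0

    def test_exact_count_small_matrix(self):
        R = np.zeros((4, 4))
        np.fill_diagonal(R, 1.0)
        for (i, j), v in {(0, 1): 0.9, (0, 2): 0.8, (1, 3): 0.7}.items():
            R[i, j] = R[j, i] = v
        A = threshold_adjacency(R, 0.5)
        assert np.count_nonzero(A) == 6 + 4
        assert np.allclose(A, A.T)

    def test_gamma_out_of_range(self):
        with pytest.raises(ConfigError):
            threshold_adjacency(np.eye(3), 1.0)

    def test_edge_count_non_increasing_in_gamma(self, rng):
        R = np.abs(np.corrcoef(rng.standard_normal((30, 10)), rowvar=False))
        counts = [
            np.count_nonzero(threshold_adjacency(R, g)) - 10
            for g in np.arange(0.0, 1.0, 0.01)
        ]
        assert np.all(np.diff(counts) <= 0)


class TestRetainedEdgeCurve:
    def test_constant_offdiagonal(self):
        R = np.full((4, 4), 0.5)
        np.fill_diagonal(R, 1.0)
        curve = retained_edge_curve(R, [0.4, 0.6])
        assert list(curve.retained_fraction) == [1.0, 0.0]

    def test_empty_support(self):
        R = np.eye(2)
        curve = retained_edge_curve(R, [0.1, 0.5])
        assert np.all(curve.retained_fraction == 0.0)

    def test_matches_counting_oracle(self, rng):
        R = np.abs(np.corrcoef(rng.standard_normal((25, 8)), rowvar=False))
        grid = np.arange(0.0, 1.0, 0.01)
        curve = retained_edge_curve(R, grid)
        iu = np.triu_indices(8, k=1)
        for g, f in zip(grid, curve.retained_fraction):
            assert f == np.sum(R[iu] > g) / len(R[iu])

    def test_monotone_invariant_enforced(self):
        with pytest.raises(Exception):
            RetainedEdgeCurve(
                gammas=np.array([0.1, 0.2]),
                retained_fraction=np.array([0.2, 0.5]),
            )


class TestSelectCutoff:
    @staticmethod
    def analytic_knee(scale=0.1, grid=None):
        """Max curvature of the min-max-normalized exponential, computed
        from closed-form derivatives on a dense grid."""
        if grid is None:
            grid = np.arange(0.0, 1.0, 0.01)
        y = np.exp(-grid / scale)
        x0, x1 = grid.min(), grid.max()
        y0, y1 = y.min(), y.max()
        dense = np.linspace(x0, x1, 100001)
        # normalized coordinates: u = (x-x0)/(x1-x0), v = (y-y0)/(y1-y0)
        f = np.exp(-dense / scale)
        dv_du = (-f / scale) * (x1 - x0) / (y1 - y0)
        d2v_du2 = (f / scale**2) * (x1 - x0) ** 2 / (y1 - y0)
        curvature = np.abs(d2v_du2) / (1 + dv_du**2) ** 1.5
        return dense[np.argmax(curvature)]

    def test_exponential_knee_matches_analytic(self):
        grid = np.arange(0.0, 1.0, 0.01)
        y = np.exp(-grid / 0.1)
        curve = RetainedEdgeCurve(gammas=grid, retained_fraction=y)
        knee = select_cutoff(curve)
        assert abs(knee - self.analytic_knee()) <= 2 * 0.01 + 1e-12

    def test_step_curve_knee_near_step(self):
        grid = np.arange(0.0, 1.0, 0.01)
        y = (grid < 0.3).astype(float)
        curve = RetainedEdgeCurve(gammas=grid, retained_fraction=y)
        assert abs(select_cutoff(curve) - 0.3) <= 0.011

    def test_linear_curve_raises(self):
        grid = np.arange(0.0, 1.0, 0.01)
        curve = RetainedEdgeCurve(gammas=grid, retained_fraction=1.0 - grid)
        with pytest.raises(NoKneeError):
            select_cutoff(curve)

    def test_constant_curve_raises(self):
        grid = np.arange(0.0, 1.0, 0.01)
        curve = RetainedEdgeCurve(gammas=grid, retained_fraction=np.full(100, 0.5))
        with pytest.raises(NoKneeError):
            select_cutoff(curve)


def test_threshold_config_validation():
    with pytest.raises(ConfigError):
        ThresholdConfig(gamma=1.0)
    with pytest.raises(ConfigError):
        ThresholdConfig(gamma=0.5, grid=[0.2, 0.1])


class TestRVProperties:
    """Hypothesis property checks on randomly seeded inputs."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_range_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((8, 3))
        B = rng.standard_normal((8, 2))
        v = rv_coefficient(A, B)
        assert 0.0 <= v <= 1.0 + 1e-12
        assert v == pytest.approx(rv_coefficient(B, A), abs=1e-12)

    @given(st.integers(0, 10**6))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_threshold_monotone_over_grid(self, seed):
        rng = np.random.default_rng(seed)
        R = np.abs(np.corrcoef(rng.standard_normal((20, 6)), rowvar=False))
        curve = retained_edge_curve(R, np.arange(0.0, 1.0, 0.05))
        assert np.all(np.diff(curve.retained_fraction) <= 1e-15)
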