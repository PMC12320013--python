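"""Unit tests for the windowed second-order decision pipeline."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soc.analytic import ar_variance
from soc.core import (
    UNDETERMINED,
    X_TO_Y,
    Y_TO_X,
    InsufficientDataError,
    NumericalSingularityError,
    SOCConfig,
    WindowSet,
    ZeroVarianceError,
    build_window_set,
    estimate_alpha,
    gaussian_entropy,
    gaussian_mutual_information,
    joint_covariance,
    logdet_psd,
    mutual_information_from_cov,
    pooled_correlation,
    residual_windows,
    soc_decide,
    standardize,
    window_covariance,
)
from soc.simulate import ARSpec, PairSpec, simulate_ar, simulate_pair


class TestStandardize:
    def test_three_point_closed_form(self):
        out = standardize(np.array([1.0, 2.0, 3.0]))
        expected = np.array([-math.sqrt(1.5), 0.0, math.sqrt(1.5)])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_idempotent(self, rng):
        z = standardize(rng.normal(size=500))
        np.testing.assert_allclose(standardize(z), z, atol=1e-12)

    def test_constant_raises(self):
        with pytest.raises(ZeroVarianceError):
            standardize(np.array([5.0, 5.0, 5.0]))

    def test_population_moments(self, rng):
        z = standardize(rng.normal(loc=3, scale=7, size=100))
        assert abs(z.mean()) < 1e-12
        assert abs(z.std() - 1.0) < 1e-12


class TestWindowing:
    def test_non_overlapping_exact_cover(self):
        ws = build_window_set(np.arange(10.0), 5, 5)
        assert ws.n_instances == 2
        np.testing.assert_array_equal(ws.values[0], np.arange(5.0))
        np.testing.assert_array_equal(ws.values[1], np.arange(5.0, 10.0))

    def test_trailing_partial_window_discarded(self):
        ws = build_window_set(np.arange(11.0), 5, 5)
        assert ws.n_instances == 2
        assert 10.0 not in ws.values

    def test_overlapping_stride(self):
        ws = build_window_set(np.arange(6.0), 5, 1)
        assert ws.n_instances == 2
        np.testing.assert_array_equal(ws.values[1], np.arange(1.0, 6.0))

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            build_window_set(np.arange(5.0), 5, 5)


class TestAlphaAndResiduals:
    def test_exact_linear_map_raw_and_standardized(self, rng):
        x = standardize(rng.normal(size=400))
        y_raw = 0.5 * x
        wx = build_window_set(x, 4, 4)
        wy = build_window_set(y_raw, 4, 4)
        assert estimate_alpha(wx, wy) == pytest.approx(0.5, abs=1e-12)
        ys = standardize(y_raw)
        wys = build_window_set(ys, 4, 4)
        assert estimate_alpha(wx, wys) == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_alpha_near_zero(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        wx = build_window_set(x, 5, 5)
        wy = build_window_set(y, 5, 5)
        assert abs(estimate_alpha(wx, wy)) < 0.05  # 3 / sqrt(mL) bound

    def test_alpha_recovers_population_lag0_correlation(self):
        # oracle: closed-form stationary variances of the generative model
        alpha, r = 0.5, 0.8
        var_x = ar_variance([r])
        var_d = ar_variance([0.2])
        rho_pop = alpha * math.sqrt(var_x / (alpha**2 * var_x + var_d))
        x, y, _ = simulate_pair(
            PairSpec(ARSpec((r,)), ARSpec((0.2,)), alpha=alpha, n_samples=100_000), 3
        )
        wx = build_window_set(standardize(x), 5, 5)
        wy = build_window_set(standardize(y), 5, 5)
        assert estimate_alpha(wx, wy) == pytest.approx(rho_pop, abs=0.02)

    def test_shape_mismatch_raises(self, rng):
        wx = WindowSet(rng.normal(size=(10, 4)))
        wy = WindowSet(rng.normal(size=(10, 5)))
        with pytest.raises(ValueError):
            estimate_alpha(wx, wy)

    def test_residual_reconstruction(self, rng):
        wx = WindowSet(rng.normal(size=(8, 3)))
        wy = WindowSet(rng.normal(size=(8, 3)))
        d = residual_windows(wx, wy, 0.37)
        np.testing.assert_allclose(d.values + 0.37 * wx.values, wy.values, atol=0)

    def test_residual_exact_and_zero_alpha(self, rng):
        wx = WindowSet(rng.normal(size=(6, 4)))
        wy = WindowSet(0.9 * wx.values)
        assert np.all(residual_windows(wx, wy, 0.9).values == 0.0)
        np.testing.assert_array_equal(
            residual_windows(wx, wy, 0.0).values, wy.values
        )


class TestCovariances:
    def test_identical_rows_zero_covariance(self):
        ws = WindowSet(np.array([[1.0, 2.0], [1.0, 2.0]]))
        np.testing.assert_array_equal(window_covariance(ws).matrix, np.zeros((2, 2)))

    def test_two_row_hand_computation(self):
        ws = WindowSet(np.array([[1.0, -1.0], [-1.0, 1.0]]))
        np.testing.assert_allclose(
            window_covariance(ws).matrix, np.array([[1.0, -1.0], [-1.0, 1.0]])
        )

    def test_ar1_windows_match_analytic_autocovariance(self):
        s = standardize(simulate_ar(ARSpec((0.8,)), 120_000, seed=5))
        ws = build_window_set(s, 5, 5)
        cov = window_covariance(ws).matrix
        i, j = np.indices(cov.shape)
        np.testing.assert_allclose(cov, 0.8 ** np.abs(i - j), atol=0.02)

    def test_toeplitz_projection_structure_and_ridge(self, rng):
        ws = WindowSet(rng.normal(size=(50, 4)))
        est = window_covariance(ws, ridge=1e-3, toeplitz_proj=True)
        c = est.matrix - est.ridge_used * np.eye(4)
        for k in range(1, 4):
            diag = np.diagonal(c, k)
            assert np.allclose(diag, diag[0])
        assert est.toeplitz_projected
        assert est.ridge_used > 0

    def test_joint_blocks_and_duplicate_singularity(self, rng):
        wa = WindowSet(rng.normal(size=(40, 3)))
        wb = WindowSet(rng.normal(size=(40, 3)))
        joint = joint_covariance(wa, wb).matrix
        np.testing.assert_allclose(joint[:3, :3], window_covariance(wa).matrix)
        dup = joint_covariance(wa, wa).matrix
        assert np.linalg.eigvalsh(dup).min() < 1e-10  # rank <= L before ridge
        with pytest.raises(NumericalSingularityError):
            logdet_psd(dup - 1e-9 * np.eye(6))

    def test_independent_joint_off_diagonal_small(self):
        rng = np.random.default_rng(11)
        m = 20_000
        wa = WindowSet(rng.normal(size=(m, 3)))
        wb = WindowSet(rng.normal(size=(m, 3)))
        joint = joint_covariance(wa, wb).matrix
        assert np.max(np.abs(joint[:3, 3:])) < 3 / math.sqrt(m)


class TestEntropyAndMI:
    def test_standard_normal_entropy(self):
        assert gaussian_entropy(np.array([[1.0]])) == pytest.approx(
            0.5 * (1 + math.log(2 * math.pi)), abs=1e-10
        )

    def test_entropy_additive_over_identity(self):
        h1 = gaussian_entropy(np.eye(1))
        assert gaussian_entropy(np.eye(6)) == pytest.approx(6 * h1, abs=1e-10)

    def test_correlated_2x2_closed_form(self):
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        expected = 0.5 * math.log(0.75) + (1 + math.log(2 * math.pi))
        assert gaussian_entropy(cov) == pytest.approx(expected, abs=1e-10)

    def test_block_diagonal_mi_zero(self):
        ca = np.array([[2.0, 0.3], [0.3, 1.0]])
        cb = np.array([[1.5, -0.2], [-0.2, 0.8]])
        joint = np.block([[ca, np.zeros((2, 2))], [np.zeros((2, 2)), cb]])
        assert mutual_information_from_cov(ca, cb, joint) == pytest.approx(0, abs=1e-12)

    def test_scalar_gaussian_mi_closed_form(self):
        rho = 0.6
        ca = np.array([[1.0]])
        joint = np.array([[1.0, rho], [rho, 1.0]])
        expected = -0.5 * math.log(1 - rho**2)
        assert mutual_information_from_cov(ca, ca, joint) == pytest.approx(
            expected, abs=1e-12
        )

    def test_near_copy_mi_large(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=(1000, 3))
        wa = WindowSet(a)
        wb = WindowSet(a + rng.normal(scale=1e-3, size=a.shape))
        assert gaussian_mutual_information(wa, wb, ridge=1e-10) > 5.0

    def test_plugin_mi_nonnegative_on_noise(self, rng):
        for _ in range(20):
            wa = WindowSet(rng.normal(size=(30, 4)))
            wb = WindowSet(rng.normal(size=(30, 4)))
            assert gaussian_mutual_information(wa, wb) >= -1e-8


class TestSocDecide:
    def test_antisymmetry_exact(self, standard_pair_spec):
        x, y, _ = simulate_pair(standard_pair_spec, 21)
        a = soc_decide(x, y)
        b = soc_decide(y, x)
        assert a.criterion_C == pytest.approx(-b.criterion_C, abs=1e-10)
        assert a.mi_x_d == b.mi_y_e and a.mi_y_e == b.mi_x_d
        assert a.alpha_hat == b.alpha_hat

    def test_decision_result_internal_consistency(self, standard_pair_spec):
        x, y, _ = simulate_pair(standard_pair_spec, 4)
        res = soc_decide(x, y)
        assert res.criterion_C == pytest.approx(
            2 * res.mi_x_d - 2 * res.mi_y_e, abs=1e-10
        )
        assert res.mi_x_d >= -1e-8 and res.mi_y_e >= -1e-8
        assert res.direction in (X_TO_Y, Y_TO_X, UNDETERMINED)

    def test_scale_invariance(self, standard_pair_spec):
        x, y, _ = simulate_pair(standard_pair_spec, 8)
        base = soc_decide(x, y)
        scaled = soc_decide(250.0 * x - 3.0, 1e-4 * y + 17.0)
        assert scaled.direction == base.direction
        assert scaled.criterion_C == pytest.approx(base.criterion_C, abs=1e-10)

    def test_recovers_true_direction_across_seeds(self):
        spec = PairSpec(ARSpec((0.8,)), ARSpec((0.2,)), alpha=0.7, n_samples=2000)
        hits = sum(
            soc_decide(*simulate_pair(spec, s)[:2]).direction == X_TO_Y
            for s in range(20)
        )
        assert hits >= 18

    def test_insufficient_data_with_explicit_stride(self):
        rng = np.random.default_rng(0)
        with pytest.raises(InsufficientDataError):
            soc_decide(
                rng.normal(size=60),
                rng.normal(size=60),
                SOCConfig(window_length=5, stride=5),
            )

    def test_short_series_falls_back_to_overlapping_windows(self):
        spec = PairSpec(ARSpec((0.8,)), ARSpec((0.2,)), alpha=0.7, n_samples=100)
        x, y, _ = simulate_pair(spec, 5)
        res = soc_decide(x, y)  # default stride=None allows the fallback
        assert res.direction in (X_TO_Y, Y_TO_X)

    def test_constant_input_raises(self):
        with pytest.raises(ZeroVarianceError):
            soc_decide(np.ones(500), np.random.default_rng(0).normal(size=500))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), coupled=st.booleans())
def test_antisymmetry_and_mi_nonnegativity_property(seed, coupled):
    """C(x,y) = -C(y,x) and plug-in MIs stay nonnegative for arbitrary pairs."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=400)
    y = 0.6 * x + rng.normal(size=400) if coupled else rng.normal(size=400)
    a = soc_decide(x, y)
    b = soc_decide(y, x)
    assert a.criterion_C == -b.criterion_C  # bitwise, by construction
    assert a.mi_x_d >= -1e-8 and a.mi_y_e >= -1e-8


def test_pooled_correlation_symmetric(rng):
    wx = WindowSet(rng.normal(size=(30, 5)))
    wy = WindowSet(rng.normal(size=(30, 5)))
    assert pooled_correlation(wx, wy) == pooled_correlation(wy, wx)
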