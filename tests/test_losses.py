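import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from jointcal.losses import (KernelConfig, LossWeights, calibration_loss,
                             calibration_loss_grad, discrimination_loss,
                             gaussian_mmd2, median_heuristic_bandwidths,
                             reconstruction_loss, reconstruction_loss_grad,
                             total_loss)

GAUSS = KernelConfig()
LINEAR = KernelConfig(kind="linear_mean_l1")


def naive_mmd2(Z1, Z2, bandwidths):
    """Brute-force double loop over every kernel pair (the oracle)."""
    def k(a, b):
        return sum(np.exp(-np.sum((a - b) ** 2) / h) for h in bandwidths)
    n, m = len(Z1), len(Z2)
    t11 = sum(k(a, b) for a in Z1 for b in Z1) / n ** 2
    t22 = sum(k(a, b) for a in Z2 for b in Z2) / m ** 2
    t12 = sum(k(a, b) for a in Z1 for b in Z2) / (n * m)
    return t11 + t22 - 2 * t12


class TestCalibrationLoss:
    def test_gaussian_matches_double_loop_oracle(self, rng):
        for _ in range(5):
            Z1 = rng.normal(size=(rng.integers(3, 20), 3))
            Z2 = rng.normal(1.0, 1.0, size=(rng.integers(3, 20), 3))
            h = median_heuristic_bandwidths(Z1, Z2)
            assert gaussian_mmd2(Z1, Z2, h) == pytest.approx(
                naive_mmd2(Z1, Z2, h), abs=1e-10)

    def test_identical_matrices(self, rng):
        Z = rng.normal(size=(10, 4))
        assert calibration_loss(Z, Z, LINEAR) == 0.0
        assert calibration_loss(Z, Z, GAUSS) == pytest.approx(0.0, abs=1e-12)

    def test_single_point_linear_mean(self):
        assert calibration_loss([[0.0, 0.0]], [[3.0, 4.0]], LINEAR) == 7.0

    def test_symmetry_and_permutation_invariance(self, rng):
        Z1 = rng.normal(size=(12, 3))
        Z2 = rng.normal(0.5, 1.2, size=(9, 3))
        for k in (GAUSS, LINEAR):
            assert calibration_loss(Z1, Z2, k) == pytest.approx(
                calibration_loss(Z2, Z1, k), rel=1e-12)
        h = KernelConfig(bandwidths=(1.0, 3.0))
        perm = rng.permutation(12)
        assert calibration_loss(Z1[perm], Z2, h) == pytest.approx(
            calibration_loss(Z1, Z2, h), rel=1e-12)

    def test_linear_translation_invariance(self, rng):
        Z1 = rng.normal(size=(6, 4))
        Z2 = rng.normal(size=(8, 4))
        shift = rng.normal(size=4)
        assert calibration_loss(Z1 + shift, Z2 + shift, LINEAR) == pytest.approx(
            calibration_loss(Z1, Z2, LINEAR), rel=1e-12)

    def test_unbiased_estimator_removes_self_terms(self, rng):
        Z1 = rng.normal(size=(15, 3))
        Z2 = rng.normal(2.0, 1.0, size=(15, 3))
        h = (2.0,)
        # the V-statistic is exactly 0 on identical matrices; dropping the
        # diagonal self-similarity terms makes the U-statistic nonpositive
        assert gaussian_mmd2(Z1, Z1 + 0.0, h, unbiased=False) == pytest.approx(0, abs=1e-12)
        assert gaussian_mmd2(Z1, Z1 + 0.0, h, unbiased=True) <= 1e-12
        assert gaussian_mmd2(Z1, Z2, h, unbiased=True) < \
            gaussian_mmd2(Z1, Z2, h, unbiased=False)
        assert gaussian_mmd2(Z1, Z2, h, unbiased=False) >= 0.0

    def test_gradient_matches_finite_differences(self, rng):
        kernel = KernelConfig(bandwidths=(0.8, 2.0))
        Z1 = rng.normal(size=(5, 3))
        Z2 = rng.normal(0.3, 1.0, size=(4, 3))
        _, g1, g2 = calibration_loss_grad(Z1, Z2, kernel)
        eps = 1e-6
        for Z, G in ((Z1, g1), (Z2, g2)):
            for idx in [(0, 0), (1, 2), (Z.shape[0] - 1, 1)]:
                old = Z[idx]
                Z[idx] = old + eps
                up = calibration_loss(Z1, Z2, kernel)
                Z[idx] = old - eps
                dn = calibration_loss(Z1, Z2, kernel)
                Z[idx] = old
                assert G[idx] == pytest.approx((up - dn) / (2 * eps), abs=1e-6)

    def test_errors(self, rng):
        with pytest.raises(ValueError, match="width"):
            calibration_loss(rng.normal(size=(3, 2)), rng.normal(size=(3, 3)))
        with pytest.raises(ValueError, match="2 rows"):
            calibration_loss(rng.normal(size=(1, 2)), rng.normal(size=(3, 2)), GAUSS)


class TestReconstructionLoss:
    def test_zero_iff_equal(self, rng):
        X = rng.normal(size=(6, 3))
        assert reconstruction_loss(X, X) == 0.0
        assert reconstruction_loss(X, X + 0.1) > 0.0

    def test_single_row_closed_form(self):
        assert reconstruction_loss([[1.0, 2.0]], [[0.0, 0.0]]) == 5.0

    def test_matches_elementwise_loop(self, rng):
        X = rng.normal(size=(7, 4))
        Xp = rng.normal(size=(7, 4))
        loop = sum(sum((X[i, j] - Xp[i, j]) ** 2 for j in range(4))
                   for i in range(7)) / 7
        assert reconstruction_loss(X, Xp) == pytest.approx(loop, abs=1e-12)
        _, g = reconstruction_loss_grad(X, Xp)
        np.testing.assert_allclose(g, 2 * (Xp - X) / 7, atol=1e-15)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            reconstruction_loss(rng.normal(size=(2, 2)), rng.normal(size=(3, 2)))


class TestDiscriminationLoss:
    def test_closed_forms(self):
        assert discrimination_loss([0.5], [1]) == pytest.approx(np.log(2))
        assert discrimination_loss([0.9, 0.1], [1, 0]) == pytest.approx(
            -np.log(0.9), rel=1e-12)

    def test_confident_correct_prediction_vanishes(self):
        eps = 1e-9
        assert discrimination_loss([1 - eps, eps], [1, 0]) < 1e-8

    def test_one_sided_variant_keeps_positive_term_only(self):
        # negative samples contribute nothing in the literal one-sided form
        assert discrimination_loss([0.9, 0.999], [1, 0], one_sided=True) == \
            pytest.approx(-np.log(0.9) / 2)

    def test_probability_domain_enforced(self):
        with pytest.raises(ValueError, match="strictly"):
            discrimination_loss([0.0, 0.5], [0, 1])
        with pytest.raises(ValueError, match="strictly"):
            discrimination_loss([1.0], [1])
        with pytest.raises(ValueError, match="length"):
            discrimination_loss([0.5], [1, 0])


class TestTotalLoss:
    @pytest.mark.parametrize("components,weights,expected", [
        ((1, 1, 1), (1, 1, 1), 3.0),
        ((2, 3, 4), (0.5, 1, 2), 12.0),
        ((5, 7, 11), (0, 0, 1), 11.0),
    ])
    def test_weighted_sum(self, components, weights, expected):
        assert total_loss(*components, LossWeights(*weights)) == expected

    @given(lr=st.floats(-5, 5), lc=st.floats(-5, 5), ld=st.floats(-5, 5),
           s=st.floats(0.1, 3.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_linear_in_each_component(self, lr, lc, ld, s):
        w = LossWeights(0.5, 1.5, 2.0)
        base = total_loss(lr, lc, ld, w)
        assert total_loss(lr * s, lc, ld, w) == pytest.approx(
            base + w.alpha * lr * (s - 1), rel=1e-9, abs=1e-9)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            total_loss(np.inf, 0, 0, LossWeights())

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(0, 0, 0)
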