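import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampliconcna.normalization import (
    NormalizationError,
    adjust_tumor,
    fit_control_baseline,
    fit_tumor_effects,
    normalize_tumors,
    read_baseline,
    scale_residuals,
    write_baseline,
)
from ampliconcna.panel_io import CONTROL, TUMOR

from conftest import make_depths, random_depths


def sum_to_zero_lstsq(log_y):
    """Independent oracle: constrained least squares via explicit design.

    Codes region and sample factors with sum-to-zero contrasts and solves
    the normal equations with lstsq; no row/column-mean shortcut.
    """
    m, k = log_y.shape
    n = m * k
    X = np.zeros((n, 1 + (m - 1) + (k - 1)))
    X[:, 0] = 1.0
    row = 0
    for i in range(m):
        for j in range(k):
            if i < m - 1:
                X[row, 1 + i] = 1.0
            else:
                X[row, 1:m] = -1.0
            if j < k - 1:
                X[row, m + j] = 1.0
            else:
                X[row, m:] = -1.0
            row += 1
    coef, *_ = np.linalg.lstsq(X, log_y.ravel(), rcond=None)
    mu = coef[0]
    alpha = np.append(coef[1:m], -coef[1:m].sum())
    beta = np.append(coef[m:], -coef[m:].sum())
    return mu, alpha, beta


def reference_level_lstsq(log_y):
    """Second oracle: drop-first (reference level) coding; returns fitted values."""
    m, k = log_y.shape
    n = m * k
    X = np.zeros((n, 1 + (m - 1) + (k - 1)))
    X[:, 0] = 1.0
    row = 0
    for i in range(m):
        for j in range(k):
            if i > 0:
                X[row, i] = 1.0
            if j > 0:
                X[row, m - 1 + j] = 1.0
            row += 1
    coef, *_ = np.linalg.lstsq(X, log_y.ravel(), rcond=None)
    return (X @ coef).reshape(m, k)


class TestControlBaseline:
    def test_constant_matrix_has_zero_effects(self):
        dm = make_depths(np.full((4, 3), 1000.0), [CONTROL] * 3)
        b = fit_control_baseline(dm)
        assert b.mu_n == pytest.approx(np.log2(1000), abs=1e-12)
        np.testing.assert_allclose(b.alpha, 0, atol=1e-12)
        np.testing.assert_allclose(b.beta_control, 0, atol=1e-12)
        assert b.sigma_n == pytest.approx(0, abs=1e-12)

    def test_doubled_region_shifts_alpha_by_one(self, rng):
        base = rng.uniform(500, 1500, size=3)
        values = np.vstack([base, 2 * base, rng.uniform(500, 1500, size=3)])
        b = fit_control_baseline(make_depths(values, [CONTROL] * 3))
        assert b.alpha[1] - b.alpha[0] == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        dm = random_depths(rng, 50, 10, 0)
        b = fit_control_baseline(dm)
        mu, alpha, beta = sum_to_zero_lstsq(np.log2(dm.values))
        assert b.mu_n == pytest.approx(mu, abs=1e-10)
        np.testing.assert_allclose(b.alpha, alpha, atol=1e-10)
        np.testing.assert_allclose(b.beta_control, beta, atol=1e-10)

    def test_identifiability_constraints_hold(self, rng):
        dm = random_depths(rng, 20, 5, 0)
        b = fit_control_baseline(dm)
        assert abs(b.alpha.sum()) < 1e-9
        assert abs(b.beta_control.sum()) < 1e-9
        # mu + alpha_i equals the control row mean of log2 depth
        np.testing.assert_allclose(
            b.mu_n + b.alpha, np.log2(dm.values).mean(axis=1), atol=1e-10
        )

    def test_fitted_values_invariant_to_parameterization(self, rng):
        dm = random_depths(rng, 12, 6, 0)
        log_y = np.log2(dm.values)
        b = fit_control_baseline(dm)
        fitted = b.mu_n + b.alpha[:, None] + b.beta_control[None, :]
        np.testing.assert_allclose(fitted, reference_level_lstsq(log_y), atol=1e-10)

    def test_too_few_samples_or_regions(self, rng):
        with pytest.raises(NormalizationError, match="control"):
            fit_control_baseline(make_depths(np.ones((5, 1)) * 10, [CONTROL]))
        with pytest.raises(NormalizationError, match="region"):
            fit_control_baseline(make_depths(np.ones((1, 5)) * 10, [CONTROL] * 5))

    def test_zero_depth_pseudocount_and_warning(self):
        values = np.array([[100.0, 0.0], [200.0, 300.0]])
        dm = make_depths(values, [CONTROL] * 2)
        with pytest.warns(UserWarning, match="zero depth"):
            b = fit_control_baseline(dm, pseudocount=0.5)
        # only the zero cell is modified
        expected = np.log2(np.array([[100.0, 0.5], [200.0, 300.0]])).mean()
        assert b.mu_n == pytest.approx(expected, abs=1e-12)

    def test_zero_depth_with_zero_pseudocount_fails(self):
        dm = make_depths(np.array([[100.0, 0.0], [200.0, 300.0]]), [CONTROL] * 2)
        with pytest.raises(NormalizationError):
            with pytest.warns(UserWarning):
                fit_control_baseline(dm, pseudocount=0.0)

    def test_baseline_persistence_bit_exact(self, tmp_path, rng):
        b = fit_control_baseline(random_depths(rng, 10, 4, 0))
        path = tmp_path / "baseline.tsv"
        write_baseline(b, path)
        back = read_baseline(path)
        assert back.mu_n == b.mu_n
        assert back.sigma_n == b.sigma_n
        np.testing.assert_array_equal(back.alpha, b.alpha)
        np.testing.assert_array_equal(back.beta_control, b.beta_control)
        assert back.amplicon_ids == b.amplicon_ids


class TestTumorAdjustment:
    def test_depths_at_baseline_give_zero_z(self, rng):
        controls = random_depths(rng, 8, 4, 0)
        b = fit_control_baseline(controls)
        tumor_values = 2 ** (b.mu_n + b.alpha)[:, None] * np.ones((8, 3))
        tumors = make_depths(tumor_values, [TUMOR] * 3)
        tumors.amplicon_ids = controls.amplicon_ids
        np.testing.assert_allclose(adjust_tumor(tumors, b), 0, atol=1e-10)

    def test_doubling_one_cell_raises_z_by_one(self, rng):
        controls = random_depths(rng, 8, 4, 0)
        b = fit_control_baseline(controls)
        tumors = random_depths(rng, 8, 0, 3)
        z1 = adjust_tumor(tumors, b)
        tumors.values[2, 1] *= 2
        z2 = adjust_tumor(tumors, b)
        assert z2[2, 1] - z1[2, 1] == pytest.approx(1.0, abs=1e-12)
        z2[2, 1] = z1[2, 1]
        np.testing.assert_array_equal(z1, z2)

    def test_z_matches_cellwise_formula(self, rng):
        controls = random_depths(rng, 15, 5, 0)
        b = fit_control_baseline(controls)
        tumors = random_depths(rng, 15, 0, 6)
        z = adjust_tumor(tumors, b)
        for i in range(15):
            for j in range(6):
                expected = np.log2(tumors.values[i, j]) - b.mu_n - b.alpha[i]
                assert z[i, j] == pytest.approx(expected, abs=1e-12)

    def test_region_mismatch_rejected(self, rng):
        b = fit_control_baseline(random_depths(rng, 10, 4, 0))
        with pytest.raises(NormalizationError):
            adjust_tumor(random_depths(rng, 9, 0, 3), b)


class TestTumorEffects:
    def test_constant_columns_absorbed(self):
        c = np.array([1.0, 3.0, -2.0])
        z = np.tile(c, (5, 1))
        mu_c, beta, resid = fit_tumor_effects(z)
        assert mu_c == pytest.approx(c.mean())
        np.testing.assert_allclose(beta, c - c.mean(), atol=1e-12)
        np.testing.assert_allclose(resid, 0, atol=1e-12)

    def test_hand_worked_two_by_two(self):
        z = np.array([[1.0, 0.0], [0.0, 1.0]])
        mu_c, beta, resid = fit_tumor_effects(z)
        assert mu_c == pytest.approx(0.5)
        np.testing.assert_allclose(beta, [0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(resid, [[0.5, -0.5], [-0.5, 0.5]], atol=1e-12)

    def test_residual_is_log_ratio_of_observed_to_expected(self, rng):
        """The residual equals log2(y / y_hat) with y_hat from all fitted effects."""
        controls = random_depths(rng, 20, 6, 0)
        b = fit_control_baseline(controls)
        tumors = random_depths(rng, 20, 0, 8)
        z = adjust_tumor(tumors, b)
        mu_c, beta, resid = fit_tumor_effects(z)
        y_hat = 2 ** (b.mu_n + b.alpha[:, None] + mu_c + beta[None, :])
        np.testing.assert_allclose(
            resid, np.log2(tumors.values / y_hat), atol=1e-10
        )

    def test_residuals_sum_to_zero_per_sample(self, rng):
        _, _, resid = fit_tumor_effects(rng.normal(size=(30, 7)))
        np.testing.assert_allclose(resid.sum(axis=0), 0, atol=1e-10)

    def test_empty_matrix_rejected(self):
        with pytest.raises(NormalizationError):
            fit_tumor_effects(np.empty((0, 0)))


class TestScaleResiduals:
    def test_hand_sd_with_unbiased_denominator(self):
        resid = np.array([[-2.0, 2.0], [1.0, 1.0]])
        with pytest.warns(UserWarning):  # constant second region clamps
            sd, adj = scale_residuals(resid)
        assert sd[0] == pytest.approx(2 * np.sqrt(2), abs=1e-12)
        np.testing.assert_allclose(
            adj[0], [-1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12
        )

    def test_zero_residual_region_clamped_to_zero_adjusted(self):
        resid = np.array([[0.0, 0.0], [-1.0, 1.0]])
        with pytest.warns(UserWarning, match="clamp"):
            sd, adj = scale_residuals(resid, min_sd=1e-8)
        np.testing.assert_array_equal(adj[0], [0.0, 0.0])

    def test_adjusted_rows_have_unit_sd(self, rng):
        resid = rng.normal(size=(25, 12))
        resid -= resid.mean(axis=0)  # emulate per-sample centering
        sd, adj = scale_residuals(resid)
        np.testing.assert_allclose(adj.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_single_tumor_rejected(self):
        with pytest.raises(NormalizationError):
            scale_residuals(np.ones((5, 1)))


class TestModelInvariances:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 50.0))
    def test_tumor_sample_scaling_leaves_residuals_unchanged(self, seed, scale):
        """Multiplying one tumor's depths by c>0 is absorbed by its sample effect."""
        rng = np.random.default_rng(seed)
        dm = random_depths(rng, 10, 4, 5)
        b = fit_control_baseline(dm.subset(CONTROL))
        tumors = dm.subset(TUMOR)
        before = normalize_tumors(tumors, b)
        tumors.values[:, 2] *= scale
        after = normalize_tumors(tumors, b)
        np.testing.assert_allclose(after.residuals, before.residuals, atol=1e-10)
        np.testing.assert_allclose(after.adjusted, before.adjusted, atol=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 50.0))
    def test_joint_region_scaling_leaves_residuals_unchanged(self, seed, scale):
        """Scaling one region in controls AND tumors cancels via its alpha."""
        rng = np.random.default_rng(seed)
        dm = random_depths(rng, 10, 4, 5)
        b1 = fit_control_baseline(dm.subset(CONTROL))
        before = normalize_tumors(dm.subset(TUMOR), b1)
        dm.values[3, :] *= scale
        b2 = fit_control_baseline(dm.subset(CONTROL))
        after = normalize_tumors(dm.subset(TUMOR), b2)
        np.testing.assert_allclose(after.residuals, before.residuals, atol=1e-10)
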