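"""Solver contracts: soft-thresholding, penalized fits, deflation,
cross-loadings, covariance explained, effect filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from braincca import (
    SyntheticSpec,
    covariance_explained,
    cross_loadings,
    filter_by_effect,
    fit_first_mode,
    fit_modes,
    generate_linked_blocks,
    soft_threshold,
    standardize,
    weight_recovery_score,
)


class TestSoftThreshold:
    def test_hand_example(self):
        out = soft_threshold(np.array([3.0, -1.0, 0.5]), 1.0)
        assert np.array_equal(out, [2.0, 0.0, 0.0])

    def test_zero_delta_is_identity(self):
        v = np.array([0.3, -2.0, 0.0])
        assert np.array_equal(soft_threshold(v, 0.0), v)

    def test_large_delta_annihilates(self):
        v = np.array([0.3, -2.0, 1.0])
        assert np.array_equal(soft_threshold(v, 2.0), np.zeros(3))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        v=hnp.arrays(float, 8, elements=st.floats(-100, 100)),
        delta=st.floats(0, 50),
    )
    def test_shrinks_toward_zero_and_preserves_sign(self, v, delta):
        out = soft_threshold(v, delta)
        assert np.all(np.abs(out) <= np.abs(v))
        assert np.all((out == 0) | (np.sign(out) == np.sign(v)))


def classical_cca_first_r(X, Y):
    """Independent oracle: first canonical correlation by the
    generalized-eigenvalue route on the sample covariance blocks."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n = X.shape[0]
    Sxx = X.T @ X / (n - 1)
    Syy = Y.T @ Y / (n - 1)
    Sxy = X.T @ Y / (n - 1)
    M = np.linalg.solve(Sxx, Sxy) @ np.linalg.solve(Syy, Sxy.T)
    return float(np.sqrt(np.max(np.linalg.eigvals(M).real)))


def small_cohort(seed=11, **kw):
    base = dict(
        n_subjects=500, p_imaging=30, q_nonimaging=20, n_modes=1,
        support_x=(5,), support_y=(5,), target_r=(0.7,), noise_sd=1.0, seed=seed,
    )
    base.update(kw)
    data, truth = generate_linked_blocks(SyntheticSpec(**base))
    return standardize(data.imaging), standardize(data.nonimaging), truth


class TestFitFirstMode:
    def test_single_identical_column(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((100, 1))
        x = (x - x.mean()) / x.std(ddof=1)
        mode = fit_first_mode(x, x.copy(), 1.0, 1.0)
        assert mode.r == pytest.approx(1.0, abs=1e-10)
        assert abs(mode.weights_x[0]) == pytest.approx(1.0)

    def test_mode_invariants(self, single_mode_cohort):
        X, Y, _ = single_mode_cohort
        mode = fit_first_mode(X, Y, 0.5, 0.5)
        assert np.array_equal(mode.variate_x, X.to_numpy() @ mode.weights_x)
        assert mode.r == pytest.approx(
            np.corrcoef(mode.variate_x, mode.variate_y)[0, 1], abs=1e-10
        )
        assert mode.r >= 0
        assert np.linalg.norm(mode.weights_x) <= 1 + 1e-8
        assert np.abs(mode.weights_x).sum() <= 0.5 * np.sqrt(X.shape[1]) + 1e-6
        assert np.all(np.abs(mode.cross_loadings_x) <= 1)
        assert np.all(np.abs(mode.cross_loadings_y) <= 1)

    def test_unpenalized_fit_tracks_classical_cca(self):
        """The covariance-criterion fit at penalty 1 is a close lower
        bound on the classical first canonical correlation (they agree
        in the noiseless limit; at finite n the correlation-maximizing
        classical solution sits slightly above)."""
        X, Y, _ = small_cohort(seed=4, p_imaging=5, q_nonimaging=5,
                               support_x=(5,), support_y=(5,))
        r_pmd = fit_first_mode(X, Y, 1.0, 1.0).r
        r_cca = classical_cca_first_r(X, Y)
        assert r_pmd <= r_cca + 1e-10
        assert r_cca - r_pmd < 0.05

    def test_sparse_recovery_at_fixed_penalty(self):
        """Planted 5-of-50 mode, penalties 0.3: median support F1 >= 0.8
        and cosine >= 0.9 over 20 seeds."""
        f1s, cosines = [], []
        for seed in range(20):
            X, Y, truth = small_cohort(
                seed=seed, n_subjects=1000, p_imaging=50, q_nonimaging=40
            )
            mode = fit_first_mode(X, Y, 0.3, 0.3)
            cos, f1 = weight_recovery_score(mode.weights_x, truth.true_weights_x[0])
            f1s.append(f1)
            cosines.append(cos)
        assert np.median(f1s) >= 0.8
        assert np.median(cosines) >= 0.9

    def test_objective_ascends_to_convergence(self, single_mode_cohort):
        X, Y, _ = single_mode_cohort
        mode = fit_first_mode(X, Y, 0.4, 0.4)
        assert mode.converged  # flag also covers the per-iteration ascent check

    def test_feature_permutation_equivariance(self, single_mode_cohort):
        X, Y, _ = single_mode_cohort
        mode = fit_first_mode(X, Y, 0.5, 0.5)
        rng = np.random.default_rng(1)
        perm = rng.permutation(X.shape[1])
        mode_p = fit_first_mode(X.iloc[:, perm], Y, 0.5, 0.5)
        assert mode_p.r == pytest.approx(mode.r, abs=1e-10)
        assert np.allclose(mode_p.weights_x, mode.weights_x[perm], atol=1e-8)

    def test_monotone_sparsity_along_penalty_ladder(self):
        violations = 0
        for seed in range(10):
            X, Y, _ = small_cohort(seed=seed)
            nnz = []
            for pen in np.linspace(0.2, 1.0, 6):
                mode = fit_first_mode(X, Y, pen, 0.5)
                nnz.append(int((mode.weights_x != 0).sum()))
            violations += sum(b < a for a, b in zip(nnz, nnz[1:]))
        assert violations == 0

    def test_non_finite_input_rejected(self):
        X = np.ones((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_first_mode(X, np.ones((10, 2)), 1.0, 1.0)


class TestFitModes:
    def test_single_mode_matches_first_mode(self, single_mode_cohort):
        X, Y, _ = single_mode_cohort
        model = fit_modes(X, Y, 0.5, 0.5, n_modes=1)
        mode = fit_first_mode(X, Y, 0.5, 0.5)
        assert model.first.r == pytest.approx(mode.r, abs=1e-12)
        assert np.array_equal(model.first.weights_x, mode.weights_x)

    def test_two_planted_modes_recovered_in_order(self):
        wins = 0
        for seed in range(20):
            data, _ = generate_linked_blocks(SyntheticSpec(
                n_subjects=800, p_imaging=30, q_nonimaging=30, n_modes=2,
                support_x=(5, 5), support_y=(5, 5), target_r=(0.8, 0.5),
                noise_sd=1.0, seed=seed,
            ))
            X, Y = standardize(data.imaging), standardize(data.nonimaging)
            model = fit_modes(X, Y, 0.8, 0.8, n_modes=2)
            if model.modes[0].r > model.modes[1].r:
                wins += 1
        assert wins >= 18

    def test_deflated_mode_nearly_uncorrelated_with_first(self):
        data, _ = generate_linked_blocks(SyntheticSpec(
            n_subjects=800, p_imaging=30, q_nonimaging=30, n_modes=2,
            support_x=(5, 5), support_y=(5, 5), target_r=(0.8, 0.5),
            noise_sd=1.0, seed=3,
        ))
        X, Y = standardize(data.imaging), standardize(data.nonimaging)
        model = fit_modes(X, Y, 0.8, 0.8, n_modes=2)
        m1, m2 = model.modes
        assert abs(np.corrcoef(m1.variate_x, m2.variate_x)[0, 1]) < 0.1
        assert abs(np.corrcoef(m1.variate_y, m2.variate_y)[0, 1]) < 0.1

    def test_too_many_modes_rejected(self, single_mode_cohort):
        X, Y, _ = single_mode_cohort
        with pytest.raises(ValueError):
            fit_modes(X, Y, 0.5, 0.5, n_modes=21)


class TestCrossLoadings:
    def test_single_column_equals_signed_correlation(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((200, 1))
        y = 0.6 * x + 0.8 * rng.standard_normal((200, 1))
        x = (x - x.mean()) / x.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
        mode = fit_first_mode(x, y, 1.0, 1.0)
        clx, _ = cross_loadings(mode, x, y)
        expected = np.sign(mode.weights_y[0]) * np.corrcoef(x[:, 0], y[:, 0])[0, 1]
        assert clx[0] == pytest.approx(expected, abs=1e-12)

    def test_column_identical_to_variate_loads_one(self, single_mode_cohort):
        X, Y, _ = single_mode_cohort
        mode = fit_first_mode(X, Y, 0.5, 0.5)
        X_aug = X.copy()
        X_aug["echo"] = mode.variate_y
        clx, _ = cross_loadings(mode, X_aug, Y)
        assert clx[-1] == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_four_subject_example(self):
        # x=(1,2,3,4) against variate (1,3,2,4): Pearson rho = 0.8
        x = np.array([1.0, 2, 3, 4])
        v = np.array([1.0, 3, 2, 4])
        rho = np.corrcoef(x, v)[0, 1]
        assert rho == pytest.approx(0.8)


class TestCovarianceExplained:
    @pytest.mark.parametrize(
        "r,percent",
        [(0.30, 9), (0.34, 12), (0.62, 38), (0.59, 35), (0.65, 42), (0.54, 29)],
    )
    def test_reported_pairs(self, r, percent):
        assert round(100 * covariance_explained(r)) == percent

    def test_extremes(self):
        assert covariance_explained(0.0) == 0.0
        assert covariance_explained(1.0) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            covariance_explained(1.2)


class TestFilterByEffect:
    def test_strict_inequality_at_threshold(self):
        out = filter_by_effect(np.array([0.05, -0.10, 0.11]), 0.1)
        assert out.tolist() == [2]

    def test_zero_threshold_keeps_all_nonzero(self):
        out = filter_by_effect(np.array([0.0, -0.3, 0.001]), 0.0)
        assert out.tolist() == [1, 2]

    def test_all_zero_vector_empty(self):
        assert filter_by_effect(np.zeros(4)).size == 0
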