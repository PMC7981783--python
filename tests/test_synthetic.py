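"""Generator contracts: determinism, planted-correlation calibration,
site effects, missingness, longitudinal pairs, recovery scoring."""

import numpy as np
import pandas as pd
import pytest

from braincca import (
    InvalidSpecError,
    SyntheticSpec,
    generate_linked_blocks,
    generate_longitudinal_pair,
    inject_missingness,
    inject_site_effects,
    weight_recovery_score,
    write_dataset,
    read_dataset,
)


def spec_with(**kw):
    base = dict(
        n_subjects=400, p_imaging=20, q_nonimaging=15, n_modes=1,
        support_x=(4,), support_y=(4,), target_r=(0.6,), noise_sd=1.0, seed=5,
    )
    base.update(kw)
    return SyntheticSpec(**base)


class TestGenerateLinkedBlocks:
    def test_same_seed_bit_identical(self):
        d1, t1 = generate_linked_blocks(spec_with())
        d2, t2 = generate_linked_blocks(spec_with())
        pd.testing.assert_frame_equal(d1.imaging, d2.imaging)
        pd.testing.assert_frame_equal(d1.nonimaging, d2.nonimaging)
        assert np.array_equal(t1.true_weights_x, t2.true_weights_x)

    def test_true_weights_unit_norm_and_support(self):
        _, truth = generate_linked_blocks(spec_with(n_modes=2, support_x=(4, 3),
                                                    support_y=(4, 2), target_r=(0.6, 0.3)))
        norms = np.linalg.norm(truth.true_weights_x, axis=1)
        assert np.allclose(norms, 1.0)
        assert [(w != 0).sum() for w in truth.true_weights_x] == [4, 3]
        assert [(w != 0).sum() for w in truth.true_weights_y] == [4, 2]

    def test_null_spec_gives_independent_blocks(self):
        spec = spec_with(n_modes=0, support_x=(), support_y=(), target_r=(),
                         n_subjects=2000)
        data, _ = generate_linked_blocks(spec)
        rng = np.random.default_rng(0)
        u = rng.standard_normal(20); u /= np.linalg.norm(u)
        v = rng.standard_normal(15); v /= np.linalg.norm(v)
        r = np.corrcoef(data.imaging.to_numpy() @ u, data.nonimaging.to_numpy() @ v)[0, 1]
        assert abs(r) < 3 / np.sqrt(2000)

    def test_noiseless_single_mode_has_unit_correlation(self):
        spec = spec_with(noise_sd=0.0, target_r=(1.0,))
        data, truth = generate_linked_blocks(spec)
        a = data.imaging.to_numpy() @ truth.true_weights_x[0]
        b = data.nonimaging.to_numpy() @ truth.true_weights_y[0]
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_target_r_calibration_monte_carlo(self):
        # variance-ratio formula: mean sample corr of the true variates
        # over 50 seeds should sit in a tight band around the target
        rs = []
        for seed in range(50):
            spec = spec_with(n_subjects=2000, target_r=(0.6,), seed=seed)
            data, truth = generate_linked_blocks(spec)
            a = data.imaging.to_numpy() @ truth.true_weights_x[0]
            b = data.nonimaging.to_numpy() @ truth.true_weights_y[0]
            rs.append(np.corrcoef(a, b)[0, 1])
        assert 0.55 < np.mean(rs) < 0.65
        assert all(0.5 < r < 0.7 for r in rs)

    def test_too_many_modes_rejected(self):
        with pytest.raises(InvalidSpecError):
            spec_with(n_modes=30, support_x=(2,) * 30, support_y=(2,) * 30,
                      target_r=tuple(np.linspace(0.9, 0.1, 30))).validate()

    def test_non_decreasing_target_r_rejected(self):
        with pytest.raises(InvalidSpecError):
            spec_with(n_modes=2, support_x=(3, 3), support_y=(3, 3),
                      target_r=(0.4, 0.6)).validate()


class TestSiteEffects:
    def test_degenerate_parameters_are_identity(self):
        spec = spec_with(site_shift_sd=0.0, site_scale_range=(1.0, 1.0))
        data, truth = generate_linked_blocks(spec)
        out = inject_site_effects(data, truth)
        pd.testing.assert_frame_equal(out.imaging, data.imaging)

    def test_shift_moves_site_means_by_construction(self):
        spec = spec_with(n_sites=2, site_scale_range=(1.0, 1.0), n_modes=0,
                         support_x=(), support_y=(), target_r=())
        data, truth = generate_linked_blocks(spec)
        out = inject_site_effects(data, truth)
        for site in ("site1", "site2"):
            members = data.sites == site
            shift_applied = (out.imaging[members] - data.imaging[members]).mean()
            expected = truth.site_shift.loc[site]
            assert np.allclose(shift_applied, expected, atol=1e-12)

    def test_injection_increases_between_site_variance(self):
        spec = spec_with(n_modes=0, support_x=(), support_y=(), target_r=(),
                         site_shift_sd=0.5)
        data, truth = generate_linked_blocks(spec)
        out = inject_site_effects(data, truth)

        def between_site_var(df):
            return df.groupby(data.sites).mean().var().mean()

        assert between_site_var(out.imaging) > between_site_var(data.imaging)

    def test_unknown_site_label_rejected(self):
        data, truth = generate_linked_blocks(spec_with())
        data.sites.iloc[0] = "siteX"
        with pytest.raises(ValueError, match="siteX"):
            inject_site_effects(data, truth)


class TestMissingness:
    def test_rate_zero_is_complete(self):
        data, _ = generate_linked_blocks(spec_with())
        out = inject_missingness(data, 0.0, seed=1)
        assert not out.nonimaging.isna().any().any()

    def test_missing_count_within_binomial_interval(self):
        spec = spec_with(n_subjects=1000, q_nonimaging=10)
        data, _ = generate_linked_blocks(spec)
        out = inject_missingness(data, 0.05, seed=2)
        count = int(out.nonimaging.isna().sum().sum())
        # binomial(10000, 0.05): 99% interval ~ 500 +/- 2.58*sqrt(475)
        assert 500 - 57 <= count <= 500 + 57

    def test_imaging_block_never_touched(self):
        data, _ = generate_linked_blocks(spec_with())
        out = inject_missingness(data, 0.3, seed=3)
        assert not out.imaging.isna().any().any()
        pd.testing.assert_frame_equal(out.imaging, data.imaging)

    def test_rate_one_rejected(self):
        data, _ = generate_linked_blocks(spec_with())
        with pytest.raises(ValueError):
            inject_missingness(data, 1.0, seed=0)


class TestLongitudinal:
    def test_thinning_mean_recovered(self):
        spec = spec_with(n_subjects=2000, longitudinal=True,
                         thinning_mean=-0.12, thinning_sd=0.06)
        base, follow, _ = generate_longitudinal_pair(spec)
        mean_change = (follow.imaging - base.imaging).mean().mean()
        assert -0.13 < mean_change < -0.11

    def test_degenerate_followup_equals_baseline(self):
        spec = spec_with(longitudinal=True, thinning_mean=0.0, thinning_sd=0.0,
                         noise_sd=0.0, n_modes=0, support_x=(), support_y=(),
                         target_r=())
        base, follow, _ = generate_longitudinal_pair(spec)
        pd.testing.assert_frame_equal(base.imaging, follow.imaging)
        pd.testing.assert_frame_equal(base.nonimaging, follow.nonimaging)

    def test_subject_ordering_aligned(self):
        base, follow, _ = generate_longitudinal_pair(spec_with(longitudinal=True))
        assert base.imaging.index.equals(follow.imaging.index)


class TestWeightRecoveryScore:
    def test_perfect_and_sign_flipped(self):
        w = np.array([0.0, 0.6, 0.8])
        assert weight_recovery_score(w, w) == (1.0, 1.0)
        cos, f1 = weight_recovery_score(-w, w)
        assert cos == pytest.approx(1.0)
        assert f1 == 1.0

    def test_hand_computed_partial_overlap(self):
        truth = np.zeros(6); truth[[1, 2, 3]] = 1 / np.sqrt(3)
        est = np.zeros(6); est[[2, 3, 4]] = 1 / np.sqrt(3)
        cos, f1 = weight_recovery_score(est, truth)
        assert f1 == pytest.approx(2 / 3)
        assert cos == pytest.approx(2 / 3)  # direct dot product of the unit vectors

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            weight_recovery_score(np.zeros(3), np.ones(3))


def test_dataset_round_trip(tmp_path):
    data, truth = generate_linked_blocks(spec_with())
    data = inject_missingness(data, 0.1, seed=9)
    write_dataset(data, tmp_path, truth=truth)
    back = read_dataset(tmp_path)
    pd.testing.assert_frame_equal(back.imaging, data.imaging)
    pd.testing.assert_frame_equal(back.nonimaging, data.nonimaging)
    assert (back.sites == data.sites).all()
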