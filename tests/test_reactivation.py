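"""Templates, reactivation indices, group models and permutation FWE."""

import math

import numpy as np
import pytest
from scipy import stats

from tmrpipe import phantom
from tmrpipe import reactivation as react
from tmrpipe.searchlight import SphereSpec


def vectors_with_correlations(target_rs, dim=64, seed=0):
    """Construct a probe vector s and unit 'templates' with prescribed
    Pearson correlations r_c = corr(s, T_c) via Gram-Schmidt."""
    rng = np.random.default_rng(seed)
    s = rng.normal(size=dim)
    s = (s - s.mean()) / np.linalg.norm(s - s.mean())
    templates = []
    for r in target_rs:
        noise = rng.normal(size=dim)
        noise -= noise.mean()
        noise -= (noise @ s) * s
        noise /= np.linalg.norm(noise)
        templates.append(r * s + math.sqrt(1 - r**2) * noise)
    return s, np.stack(templates)


def probe_with_correlations(templates, target_rs, seed=0):
    """Unit centred vector with prescribed correlations to the given
    centred unit-norm template rows (span solve + orthogonal residual)."""
    rng = np.random.default_rng(seed)
    target = np.asarray(target_rs, dtype=float)
    gram = templates @ templates.T
    span = templates.T @ np.linalg.solve(gram, target)
    resid = rng.normal(size=span.size)
    resid -= resid.mean()
    resid -= templates.T @ np.linalg.solve(gram, templates @ resid)
    missing = 1.0 - np.linalg.norm(span) ** 2
    assert missing > 0, "requested correlations are infeasible"
    return span + resid / np.linalg.norm(resid) * math.sqrt(missing)


class TestTemplates:
    def test_zero_noise_wake_gives_centred_generating_patterns(self, small_space, small_templates):
        wake = phantom.simulate_wake_runs(small_space, small_templates, n_runs=4, noise_sd=0.0)
        templates = react.build_category_templates(wake)
        expected = small_templates - small_templates.mean(axis=0)
        np.testing.assert_allclose(templates, expected, atol=1e-12)

    def test_per_voxel_sum_is_zero(self):
        rng = np.random.default_rng(0)
        templates = react.build_category_templates(rng.normal(size=(4, 12, 50)))
        np.testing.assert_allclose(templates.sum(axis=0), 0.0, atol=1e-9)

    def test_centred_mean_noise_variance(self):
        # var(template) = sigma^2 / n_runs * (1 - 1/n_categories)
        rng = np.random.default_rng(1)
        sigma, n_runs = 1.0, 12
        samples = [react.build_category_templates(rng.normal(0, sigma, size=(4, n_runs, 200))) for _ in range(80)]
        var = np.var(np.stack(samples), axis=0).mean()
        expected = sigma**2 / n_runs * (1 - 1 / 4)
        assert var == pytest.approx(expected, rel=0.1)

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError):
            react.build_category_templates(np.zeros((1, 12, 50)))


class TestReactivationIndex:
    def test_closed_form_06_vs_01(self):
        expected = math.atanh(0.6) - math.atanh(0.1)
        assert react.reactivation_from_correlations(0.6, [0.1, 0.1, 0.1]) == pytest.approx(expected, abs=1e-12)
        # full path: each odor's pattern correlates 0.6 with its cued
        # template and 0.1 with the three others (vector construction)
        s0, templates = vectors_with_correlations([0.6, 0.1, 0.1, 0.1])
        s1 = probe_with_correlations(templates, [0.1, 0.6, 0.1, 0.1], seed=42)
        val = react.reactivation_index(np.stack([s0, s1]), templates, (0, 1))
        assert val == pytest.approx(expected, abs=1e-9)

    def test_equal_correlations_give_zero(self):
        s, templates = vectors_with_correlations([0.4, 0.4, 0.4, 0.4])
        assert react.reactivation_index(np.stack([s, s]), templates, (0, 1)) == pytest.approx(0.0, abs=1e-9)

    def test_affine_invariance_of_sleep_pattern(self):
        rng = np.random.default_rng(2)
        sleep = rng.normal(size=(2, 40))
        templates = rng.normal(size=(4, 40))
        base = react.reactivation_index(sleep, templates, (0, 1))
        scaled = react.reactivation_index(sleep * 3.0 + 5.0, templates, (0, 1))
        assert scaled == pytest.approx(base, abs=1e-10)

    def test_same_cued_category_rejected(self):
        with pytest.raises(ValueError):
            react.reactivation_index(np.zeros((2, 10)), np.zeros((4, 10)), (1, 1))


class TestCuedOnlyIndex:
    def test_closed_form_05_vs_02(self):
        # each odor: r = 0.5 with its own cued template, 0.2 with the other
        s0, templates = vectors_with_correlations([0.5, 0.2, 0.0, 0.0], seed=3)
        s1 = probe_with_correlations(templates, [0.2, 0.5, 0.0, 0.0], seed=4)
        sleep = np.stack([s0, s1])
        expected = math.atanh(0.5) - math.atanh(0.2)
        assert react.cued_only_index(sleep, templates, (0, 1)) == pytest.approx(expected, abs=1e-9)

    def test_symmetric_patterns_give_zero(self):
        s, templates = vectors_with_correlations([0.3, 0.3, 0.1, 0.6], seed=5)
        assert react.cued_only_index(np.stack([s, s]), templates, (0, 1)) == pytest.approx(0.0, abs=1e-9)

    def test_swapping_cue_labels_negates_index(self):
        rng = np.random.default_rng(6)
        sleep = rng.normal(size=(2, 50))
        templates = rng.normal(size=(4, 50))
        a = react.cued_only_index(sleep, templates, (0, 1))
        b = react.cued_only_index(sleep, templates, (1, 0))
        assert b == pytest.approx(-a, abs=1e-10)


class TestRoiReactivation:
    def test_roi_equal_to_single_sphere(self, small_space, small_templates):
        from tmrpipe.searchlight import sphere_offsets

        wake = phantom.simulate_wake_runs(small_space, small_templates, seed=7)
        templates = react.build_category_templates(wake)
        sleep = phantom.simulate_sleep_patterns(small_space, small_templates, (0, 1), np.array([0.5, 0.5]), seed=8)
        sphere = SphereSpec(2.0, 5)
        stat = react.reactivation_map_fast(sleep, templates, (0, 1), small_space.brain_mask, sphere)
        center = tuple(np.array(np.nonzero(small_space.region_labels["vmpfc_like"])).T[0])
        # assemble that sphere's ROI by hand
        mask = small_space.brain_mask
        vec_index = -np.ones(mask.shape, dtype=int)
        vec_index[mask] = np.arange(mask.sum())
        pts = np.array(center) + sphere.offsets
        ok = np.all((pts >= 0) & (pts < np.array(mask.shape)), axis=1)
        idx = vec_index[tuple(pts[ok].T)]
        roi = idx[idx >= 0]
        assert react.roi_reactivation(sleep, templates, (0, 1), roi) == pytest.approx(
            stat.values[center], abs=1e-10
        )

    def test_signal_roi_positive_at_high_rho(self, small_space, small_templates):
        roi = small_space.region_indices("vmpfc_like")
        hits = 0
        for seed in range(30):
            sleep = phantom.simulate_sleep_patterns(
                small_space, small_templates, (0, 1), np.array([0.8, 0.8]), seed=seed
            )
            wake = phantom.simulate_wake_runs(small_space, small_templates, seed=500 + seed)
            templates = react.build_category_templates(wake)
            hits += react.roi_reactivation(sleep, templates, (0, 1), roi) > 0
        assert hits >= 0.95 * 30

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            react.roi_reactivation(np.zeros((2, 10)), np.zeros((4, 10)), (0, 1), np.array([], dtype=int))


class TestMonotonicity:
    def test_index_monotone_in_rho(self, small_space, small_templates):
        roi = small_space.region_indices("vmpfc_like")
        levels = [0.0, 0.2, 0.4, 0.6, 0.8]
        means = []
        for level in levels:
            vals = []
            for seed in range(20):
                sleep = phantom.simulate_sleep_patterns(
                    small_space, small_templates, (0, 1), np.array([level, level]), seed=seed
                )
                wake = phantom.simulate_wake_runs(small_space, small_templates, seed=9000 + seed)
                templates = react.build_category_templates(wake)
                vals.append(react.roi_reactivation(sleep, templates, (0, 1), roi))
            means.append(np.mean(vals))
        assert stats.spearmanr(levels, means).statistic >= 0.9


class TestFisherCI:
    def test_paper_value_r070_n18(self):
        lo, hi = react.fisher_ci(0.70, 18, 0.90)
        assert round(lo, 2) == 0.42
        assert round(hi, 2) == 0.86

    def test_closed_form_r05_n20(self):
        lo, hi = react.fisher_ci(0.5, 20, 0.90)
        assert lo == pytest.approx(0.149, abs=1e-3)
        assert hi == pytest.approx(0.739, abs=1e-3)

    def test_symmetric_about_zero(self):
        lo, hi = react.fisher_ci(0.0, 1000, 0.90)
        assert lo == pytest.approx(-hi, abs=1e-12)

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError):
            react.fisher_ci(1.0, 18)


class TestGroupCorrelation:
    def test_broadcast_covariate_gives_min_p(self):
        rng = np.random.default_rng(10)
        benefit = rng.normal(size=10)
        mask = np.ones((3, 3, 3), dtype=bool)
        maps = np.tile(benefit[:, None, None, None], (1, 3, 3, 3))
        res = react.group_covariate_correlation(maps, benefit, mask, n_perm=500, seed=1)
        assert res.peak_r == pytest.approx(1.0, abs=1e-6)
        assert res.p_fwe == pytest.approx(1 / 501)

    def test_r_matches_direct_formula(self):
        rng = np.random.default_rng(11)
        maps = rng.normal(size=(18, 2, 2, 2))
        benefit = rng.normal(size=18)
        mask = np.ones((2, 2, 2), dtype=bool)
        res = react.group_covariate_correlation(maps, benefit, mask, n_perm=100, seed=2)
        v = maps[:, 0, 0, 0]
        r_direct = ((v - v.mean()) @ (benefit - benefit.mean())) / (
            np.sqrt(((v - v.mean()) ** 2).sum()) * np.sqrt(((benefit - benefit.mean()) ** 2).sum())
        )
        assert res.r_map[0, 0, 0] == pytest.approx(r_direct, abs=1e-12)

    def test_t_r_identity_and_p_ordering(self):
        rng = np.random.default_rng(12)
        maps = rng.normal(size=(12, 4, 4, 4))
        benefit = rng.normal(size=12)
        mask = np.ones((4, 4, 4), dtype=bool)
        res = react.group_covariate_correlation(maps, benefit, mask, n_perm=200, seed=3)
        n = 12
        t_expected = res.peak_r * np.sqrt((n - 2) / (1 - res.peak_r**2))
        assert res.peak_stat == pytest.approx(t_expected, abs=1e-9)
        assert res.p_fwe >= res.p_uncorrected - 1e-12

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            react.group_covariate_correlation(
                np.zeros((6, 2, 2, 2)), np.ones(6), np.ones((2, 2, 2), dtype=bool)
            )

    def test_headline_recovery_peak_localises_in_coupled_region(self, small_space, small_templates):
        from scipy import ndimage

        sphere = SphereSpec(2.0, 5)
        coupled = np.zeros(small_space.dims, dtype=bool)
        for name in phantom.SIGNAL_REGIONS:
            coupled |= small_space.region_labels[name]
        coupled = ndimage.binary_dilation(coupled, iterations=2)
        a, b = phantom.DEFAULT_COUPLING
        rng = np.random.default_rng(13)
        hits = 0
        n_groups = 10
        for g in range(n_groups):
            truth = phantom.make_ground_truth(n_subjects=18, seed=g)
            maps, benefits = [], []
            for s in range(18):
                cued = truth.cued_categories[s]
                sleep = phantom.simulate_sleep_patterns(
                    small_space, small_templates, cued, truth.rho[s], seed=int(rng.integers(2**31))
                )
                wake = phantom.simulate_wake_runs(small_space, small_templates, seed=int(rng.integers(2**31)))
                templates = react.build_category_templates(wake)
                stat = react.reactivation_map_fast(sleep, templates, cued, small_space.brain_mask, sphere)
                maps.append(stat.values)
                benefits.append(
                    100 * (a + b * truth.mean_rho[s]) + rng.normal(0, 100 * phantom.DEFAULT_BEHAVIOR_NOISE_SD)
                )
            res = react.group_covariate_correlation(
                np.stack(maps), np.asarray(benefits), stat.valid, n_perm=200, seed=g
            )
            hits += bool(coupled[res.peak_index])
        assert hits >= 0.9 * n_groups


class TestGroupOneSample:
    def test_zero_maps_give_zero_t(self):
        res = react.main_effect_reactivation(np.zeros((6, 3, 3, 3)), np.ones((3, 3, 3), dtype=bool), n_perm=100)
        assert res.peak_stat == 0.0

    def test_positive_rho_detected(self, small_space, small_templates):
        sphere = SphereSpec(2.0, 5)
        rng = np.random.default_rng(14)
        detections = 0
        n_sims = 10
        for g in range(n_sims):
            maps = []
            for s in range(18):
                sleep = phantom.simulate_sleep_patterns(
                    small_space, small_templates, (0, 1), np.array([0.6, 0.6]), seed=int(rng.integers(2**31))
                )
                wake = phantom.simulate_wake_runs(small_space, small_templates, seed=int(rng.integers(2**31)))
                stat = react.reactivation_map_fast(
                    sleep, react.build_category_templates(wake), (0, 1), small_space.brain_mask, sphere
                )
                maps.append(stat.values)
            region_vals = np.stack(maps)[:, small_space.region_labels["vmpfc_like"]].mean(axis=1)
            t = region_vals.mean() / (region_vals.std(ddof=1) / np.sqrt(18))
            detections += stats.t.sf(t, 17) < 0.001
        assert detections >= 0.9 * n_sims

    def test_sign_flip_calibration(self):
        rng = np.random.default_rng(15)
        rejections = 0
        n_sims = 200
        for _ in range(n_sims):
            maps = rng.normal(size=(10, 40))
            res = react.GroupOneSample(n_permutations=200, seed=int(rng.integers(2**31))).fit(
                maps.reshape(10, 40, 1, 1), np.ones((40, 1, 1), dtype=bool)
            )
            rejections += res.result_.p_fwe < 0.05
        assert 0.01 <= rejections / n_sims <= 0.10


class TestFirTimecourse:
    def test_equal_maps_give_equal_r(self):
        rng = np.random.default_rng(16)
        one = rng.normal(size=(12, 30))
        maps = np.repeat(one[None], 10, axis=0)
        benefits = rng.normal(size=12)
        out = react.fir_timecourse_correlation(maps, benefits, np.arange(5))
        rs = [r for r, _ in out]
        assert np.ptp(rs) < 1e-12

    def test_onset_locked_signal_only_elevates_post_onset_bins(self, small_space, small_templates):
        sphere = SphereSpec(2.0, 5)
        rng = np.random.default_rng(17)
        n_subj, offsets = 16, list(range(-3, 7))
        signal_bins = {1, 2, 3, 4}
        rhos = rng.uniform(0.2, 0.8, size=n_subj)
        tp_maps = {off: [] for off in offsets}
        benefits = 100 * (0.02 + 0.3 * rhos) + rng.normal(0, 1.0, size=n_subj)
        for s in range(n_subj):
            wake = phantom.simulate_wake_runs(small_space, small_templates, seed=int(rng.integers(2**31)))
            templates = react.build_category_templates(wake)
            for off in offsets:
                rho = rhos[s] if off in signal_bins else 0.0
                sleep = phantom.simulate_sleep_patterns(
                    small_space, small_templates, (0, 1), np.array([rho, rho]), seed=int(rng.integers(2**31))
                )
                stat = react.reactivation_map_fast(sleep, templates, (0, 1), small_space.brain_mask, sphere)
                tp_maps[off].append(stat.values[small_space.brain_mask])
        stack = np.stack([np.stack(tp_maps[off]) for off in offsets])
        vec_index = np.zeros(small_space.dims, dtype=int)
        vec_index[small_space.brain_mask] = np.arange(small_space.n_voxels)
        cluster = vec_index[small_space.region_labels["vmpfc_like"]]
        out = react.fir_timecourse_correlation(stack, benefits, cluster)
        pre_rs = [abs(out[i][0]) for i, off in enumerate(offsets) if off < 0]
        sig_los = [out[i][1][0] for i, off in enumerate(offsets) if off in signal_bins]
        assert np.mean([lo > 0 for lo in sig_los]) >= 0.75  # 90% CI excludes 0 in most signal bins
        assert max(pre_rs) < 0.7

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            react.fir_timecourse_correlation(np.zeros((10, 5, 4)), np.zeros(5), np.array([], dtype=int))
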