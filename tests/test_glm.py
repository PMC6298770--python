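"""Design construction, nuisance regressors and OLS estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmrpipe import glm


def events_frame(onsets, durations, conditions):
    return pd.DataFrame({"onset": onsets, "duration": durations, "trial_type": conditions})


class TestCanonicalHrf:
    def test_peak_normalised_and_positive_mass(self):
        h = glm.canonical_hrf(2.5)
        assert h.max() == pytest.approx(1.0)
        assert h.sum() > 0

    def test_argmax_near_gamma_mode(self):
        # the response gamma (shape 6, scale 1) has its mode at exactly 5 s
        tr = 2.5
        h = glm.canonical_hrf(tr, oversampling=16)
        dt = tr / 16
        assert abs(np.argmax(h) * dt - 5.0) <= dt

    def test_matches_spm_shape(self):
        nilearn_glm = pytest.importorskip("nilearn.glm.first_level")
        ours = glm.canonical_hrf(1.0, oversampling=16)
        ref = nilearn_glm.spm_hrf(1.0, oversampling=16)
        m = min(ours.size, ref.size)
        assert np.corrcoef(ours[:m], ref[:m])[0, 1] > 0.999


class TestBlockDesign:
    def test_empty_events_leave_only_constant(self):
        design = glm.build_block_design(events_frame([], [], []), 10, 2.5)
        assert design.column_names == ["constant"]

    def test_five_conditions_give_six_columns(self):
        conds = ["animals", "buildings", "faces", "tools", "scrambled"]
        design = glm.build_block_design(
            events_frame(np.arange(5) * 26.0, [14.0] * 5, conds), 60, 2.5
        )
        assert design.values.shape[1] == 6
        assert design.column_names[-1] == "constant"
        assert design.column_names[:-1] == sorted(conds)

    def test_task_columns_unit_peak(self):
        design = glm.build_block_design(events_frame([10.0], [14.0], ["a"]), 40, 2.5)
        assert np.abs(design.column("a")).max() == pytest.approx(1.0)

    def test_convolution_linearity_for_disjoint_blocks(self):
        both = glm.build_block_design(events_frame([0.0, 100.0], [14.0, 14.0], ["a", "a"]), 80, 2.5)
        first = glm.build_block_design(events_frame([0.0], [14.0], ["a"]), 80, 2.5)
        second = glm.build_block_design(events_frame([100.0], [14.0], ["a"]), 80, 2.5)
        # unit-peak normalisation uses the same peak for well-separated blocks
        np.testing.assert_allclose(both.column("a"), first.column("a") + second.column("a"), atol=1e-12)

    def test_event_past_scan_end_rejected(self):
        with pytest.raises(ValueError):
            glm.build_block_design(events_frame([95.0], [14.0], ["a"]), 40, 2.5)


class TestFirDesign:
    def test_two_odors_give_twenty_task_columns(self):
        design = glm.build_fir_design({"odor_1": [50.0], "odor_2": [150.0]}, 100, 2.5)
        assert len(design.task_columns) == 20
        assert design.values.shape[1] == 21

    def test_stick_lands_on_onset_volume(self):
        design = glm.build_fir_design({"o": [25.0]}, 40, 2.5)
        col = design.column("o_t+0")
        assert col[10] == 1.0 and col.sum() == 1.0

    def test_pre_onset_sticks_clamped(self):
        design = glm.build_fir_design({"o": [2.5]}, 40, 2.5)
        assert design.column("o_t-3").sum() == 0.0
        assert design.column("o_t-1").sum() == 1.0


class TestNuisance:
    def test_six_motion_columns_expand_to_24(self):
        rng = np.random.default_rng(0)
        nuis = glm.build_nuisance_matrix(rng.normal(size=(20, 6)), None, None, 2.5)
        assert nuis.motion24.shape == (20, 24)

    def test_constant_motion_has_zero_derivatives(self):
        motion = np.tile(np.array([1.0, 2, 3, 0.1, 0.2, 0.3]), (15, 1))
        nuis = glm.build_nuisance_matrix(motion, None, None, 2.5)
        assert np.all(nuis.motion24[:, 12:] == 0)

    def test_bright_slice_spikes_variance_column(self):
        vols = np.ones((4, 4, 6, 10))
        vols[:, :, 2, 7] = 5.0  # one bright slice in volume 7
        nuis = glm.build_nuisance_matrix(np.zeros((10, 6)), vols, None, 2.5)
        slice_means = vols.mean(axis=(0, 1))
        expected = slice_means.var(axis=0)
        np.testing.assert_allclose(nuis.quality4[:, 1], expected)
        assert np.argmax(nuis.quality4[:, 1]) == 7

    def test_spike_columns_one_hot_at_high_fd(self):
        motion = np.zeros((12, 6))
        motion[5, 0] = 3.0  # 3 mm jump
        nuis = glm.build_nuisance_matrix(motion, None, None, 2.5, fd_spike_threshold=1.8)
        assert nuis.spike_columns.shape[1] == 2  # jump in and out
        assert nuis.spike_columns[5, 0] == 1.0

    def test_wrong_motion_shape_rejected(self):
        with pytest.raises(ValueError):
            glm.build_nuisance_matrix(np.zeros((10, 5)), None, None, 2.5)

    def test_respiration_downsampled_by_tr_mean(self):
        trace = glm.RespirationTrace(np.arange(100, dtype=float), fs=4.0)  # 10 samples per TR
        nuis = glm.build_nuisance_matrix(np.zeros((10, 6)), None, trace, 2.5)
        np.testing.assert_allclose(nuis.respiration, [np.arange(i * 10, (i + 1) * 10).mean() for i in range(10)])


class TestInhalationAlignment:
    def test_trigger_on_inhalation_unchanged(self):
        fs = 25.0
        t = np.arange(0, 60, 1 / fs)
        trace = glm.RespirationTrace(np.sin(2 * np.pi * 0.25 * t), fs)
        # trace minimum (inhalation onset) at t = 3 s within each 4 s period
        adjusted, flags = glm.align_onsets_to_inhalation(np.array([3.0]), trace)
        assert not flags.any()
        assert adjusted[0] == pytest.approx(3.0, abs=2 / fs)

    def test_trigger_at_exhalation_peak_shifts_half_period(self):
        fs = 25.0
        period = 4.0
        t = np.arange(0, 60, 1 / fs)
        trace = glm.RespirationTrace(np.sin(2 * np.pi * t / period), fs)
        adjusted, _ = glm.align_onsets_to_inhalation(np.array([1.0]), trace)  # peak of sin
        assert adjusted[0] - 1.0 == pytest.approx(period / 2, abs=0.15)

    def test_never_moves_backward(self):
        fs = 25.0
        t = np.arange(0, 60, 1 / fs)
        trace = glm.RespirationTrace(np.sin(2 * np.pi * 0.25 * t), fs)
        triggers = np.array([5.0, 17.3, 33.1])
        adjusted, _ = glm.align_onsets_to_inhalation(triggers, trace)
        assert np.all(adjusted >= triggers - 1e-9)

    def test_monotonically_falling_trace_flags_trigger(self):
        trace = glm.RespirationTrace(-np.arange(0, 500, dtype=float), fs=25.0)
        adjusted, flags = glm.align_onsets_to_inhalation(np.array([2.0]), trace)
        assert flags[0]
        assert adjusted[0] == 2.0


@pytest.mark.parametrize(
    "n_volumes,first,last,expected",
    [
        (1500, 100, 900, (94, 906)),
        (1500, 3, 900, (0, 906)),
        (1000, 100, 998, (94, 999)),
    ],
)
def test_trim_sleep_volumes(n_volumes, first, last, expected):
    assert glm.trim_sleep_volumes(n_volumes, first, last) == expected


class TestFitGlm:
    def test_noiseless_recovery_is_exact(self):
        rng = np.random.default_rng(1)
        design = glm.build_block_design(
            events_frame([10.0, 80.0], [14.0, 14.0], ["a", "b"]), 60, 2.5
        )
        true = rng.normal(size=(2, 30))
        Y = design.values[:, :2] @ true + 3.0
        betas, _ = glm.fit_glm(Y, design)
        np.testing.assert_allclose(betas, true, atol=1e-8)

    def test_unbiased_under_noise(self):
        rng = np.random.default_rng(2)
        design = glm.build_block_design(events_frame([10.0], [14.0], ["a"]), 60, 2.5)
        true = 1.5
        errs = []
        for _ in range(200):
            Y = (design.column("a") * true + rng.normal(0, 1, 60)).reshape(-1, 1)
            betas, _ = glm.fit_glm(Y, design)
            errs.append(betas[0, 0] - true)
        assert abs(np.mean(errs)) < 3 * np.std(errs) / np.sqrt(len(errs)) + 1e-3

    def test_duplicated_column_raises_named_error(self):
        design = glm.build_block_design(events_frame([10.0], [14.0], ["a"]), 60, 2.5)
        dup = design.values[:, [0]]
        with pytest.raises(glm.RankDeficientDesignError):
            glm.fit_glm(np.zeros((60, 4)), design, nuisance=dup)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(3)
        design = glm.build_block_design(
            events_frame([10.0, 80.0], [14.0, 14.0], ["a", "b"]), 60, 2.5
        )
        Y = rng.normal(size=(60, 12))
        model = glm.FirstLevelGLM().fit(Y, design)
        inner = design.values.T @ model.residuals_
        assert np.abs(inner).max() < 1e-6 * np.abs(Y).max() * 60

    def test_fir_recovers_injected_response_shape(self):
        # zero-noise FIR estimates must reproduce the injected curve
        rng = np.random.default_rng(4)
        n_vol, tr = 200, 2.5
        onsets = np.arange(30.0, 450.0, 50.0)
        curve = glm.canonical_hrf(tr, oversampling=1)[:7]  # injected response, offsets 0..6
        signal = np.zeros(n_vol)
        for onset in onsets:
            v = int(onset / tr)
            signal[v : v + 7] += curve
        Y = np.outer(signal, rng.normal(size=5)) + 1.0
        design = glm.build_fir_design({"o": onsets}, n_vol, tr)
        betas, _ = glm.fit_glm(Y, design)
        est_curve = betas[3:, 0]  # offsets 0..+6 for the first voxel
        assert abs(np.corrcoef(est_curve, curve)[0, 1]) > 0.95


class TestSmoothing:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(5)
        vol = rng.normal(size=(8, 8, 8))
        np.testing.assert_array_equal(glm.smooth_volume(vol, 0.0, 2.0), vol)

    def test_delta_reproduces_gaussian_normalisation(self):
        vol = np.zeros((21, 21, 21))
        vol[10, 10, 10] = 1.0
        fwhm, voxel = 6.0, 2.0
        out = glm.smooth_volume(vol, fwhm, voxel)
        sigma = fwhm / voxel / (2 * np.sqrt(2 * np.log(2)))
        expected_center = (2 * np.pi * sigma**2) ** -1.5
        assert out[10, 10, 10] == pytest.approx(expected_center, rel=1e-3)

    def test_constant_volume_preserved(self):
        vol = np.full((12, 12, 12), 3.7)
        np.testing.assert_allclose(glm.smooth_volume(vol, 6.0, 2.0), vol, atol=1e-9)
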