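"""ΔR/R computation, ROI range rule, and evoked-amplitude estimation."""

import numpy as np
import pytest

from neurophenopipe.ios import (DegenerateBaselineError, DegenerateMapError,
                                IOSMovie, ResponseMap, TrialSet,
                                analyze_trialset, average_trials,
                                compute_drr, evoked_amplitude, jaccard,
                                select_roi)
from neurophenopipe.synthetic import gen_ios_trialset


def _movie(frames, onset=30, fps=30.0):
    return IOSMovie(frames=np.asarray(frames, dtype=float), fps=fps,
                    stim_onset_frame=onset)


class TestComputeDrr:
    def test_baseline_identity_maps_to_zero(self, flat_movie):
        drr = compute_drr(flat_movie)
        assert np.allclose(drr, 0.0)

    def test_simple_fractional_change(self):
        frames = np.full((40, 4, 4), 100.0)
        frames[30:] = 99.0
        drr = compute_drr(_movie(frames))
        assert np.allclose(drr[30:], -0.01)
        assert np.allclose(drr[:30], 0.0)

    def test_zero_baseline_pixel_raises(self):
        frames = np.full((40, 4, 4), 100.0)
        frames[:30, 1, 2] = 0.0
        with pytest.raises(DegenerateBaselineError, match="1 pixel"):
            compute_drr(_movie(frames))


class TestAverageTrials:
    def test_identical_trials_equal_single_trial(self, small_trialset):
        single = TrialSet(trials=small_trialset.trials[:1])
        all_trials = average_trials(small_trialset)
        one = average_trials(single)
        assert np.allclose(all_trials.drr, one.drr)

    def test_opposite_signals_cancel(self):
        base = np.full((40, 4, 4), 100.0)
        up, down = base.copy(), base.copy()
        up[30:] += 1.0
        down[30:] -= 1.0
        rmap = average_trials(TrialSet(trials=[_movie(up), _movie(down)]))
        assert np.allclose(rmap.drr, 0.0, atol=1e-12)

    def test_heterogeneous_geometry_rejected(self):
        a = _movie(np.full((40, 4, 4), 100.0))
        b = _movie(np.full((40, 5, 5), 100.0))
        with pytest.raises(ValueError, match="geometry"):
            TrialSet(trials=[a, b])

    def test_noise_averaging_follows_root_n(self):
        # pixel SD of the averaged map ~ sigma / sqrt(n_trials * n_frames)
        sigma, n_trials = 0.02, 25
        trials = gen_ios_trialset(n_trials=n_trials, shape=(32, 32),
                                  evoked_amplitude=0.0, noise_sd=sigma,
                                  seed=42)
        rmap = average_trials(trials)
        w = rmap.response_window[1] - rmap.response_window[0]
        # window-mean noise plus the baseline-estimation term
        n_base = trials.trials[0].stim_onset_frame
        expected = sigma * np.sqrt(1.0 / (n_trials * w)
                                   + 1.0 / (n_trials * n_base))
        assert rmap.drr.std() == pytest.approx(expected, rel=0.15)


class TestSelectRoi:
    def test_range_rule_on_linear_ramp(self):
        # values uniformly spread over [-1, 0]: lowest 30 % of the range
        values = np.linspace(-1.0, 0.0, 400).reshape(20, 20)
        rmap = ResponseMap(drr=values, response_window=(0, 1), fps=30.0)
        roi = select_roi(rmap, fraction=0.30, smooth_sigma_px=0.0)
        frac = roi.n_pixels / values.size
        assert 0.28 <= frac <= 0.32
        assert np.all(values[roi.mask] <= roi.threshold_value)
        assert roi.threshold_value == pytest.approx(-0.7, abs=1e-6)

    def test_constant_map_rejected(self):
        rmap = ResponseMap(drr=np.zeros((8, 8)), response_window=(0, 1),
                           fps=30.0)
        with pytest.raises(DegenerateMapError):
            select_roi(rmap)

    def test_extreme_fraction_keeps_all_but_maximum(self):
        values = np.linspace(-1.0, 0.0, 64).reshape(8, 8)
        rmap = ResponseMap(drr=values, response_window=(0, 1), fps=30.0)
        roi = select_roi(rmap, fraction=0.999, smooth_sigma_px=0.0)
        assert roi.n_pixels == 63

    def test_noiseless_dip_mask_overlaps_truth(self, small_trialset):
        res = analyze_trialset(small_trialset, smooth_sigma_px=0.0)
        truth = small_trialset.metadata["mask"]
        assert res.roi.mask[truth & res.roi.mask].all()
        assert jaccard(res.roi.mask, truth) >= 0.8

    def test_percentile_mode_selects_exact_fraction(self):
        rng = np.random.default_rng(0)
        rmap = ResponseMap(drr=rng.normal(size=(20, 20)),
                           response_window=(0, 1), fps=30.0)
        roi = select_roi(rmap, fraction=0.30, smooth_sigma_px=0.0,
                         mode="percentile")
        assert roi.n_pixels == pytest.approx(120, abs=2)


class TestEvokedAmplitude:
    def test_zero_map_gives_zero(self):
        rmap = ResponseMap(drr=np.zeros((8, 8)), response_window=(0, 1),
                           fps=30.0)
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:4, 2:4] = True
        from neurophenopipe.ios import ROIMask
        roi = ROIMask(mask=mask, fraction=0.3, threshold_value=0.0)
        assert evoked_amplitude(rmap, roi) == 0.0

    def test_constant_dip_recovered_with_positive_sign(self):
        rmap = ResponseMap(drr=np.full((8, 8), -0.005),
                           response_window=(0, 1), fps=30.0)
        from neurophenopipe.ios import ROIMask
        roi = ROIMask(mask=np.ones((8, 8), dtype=bool), fraction=0.3,
                      threshold_value=0.0)
        assert evoked_amplitude(rmap, roi) == pytest.approx(0.005)

    def test_empty_mask_rejected(self):
        rmap = ResponseMap(drr=np.zeros((8, 8)), response_window=(0, 1),
                           fps=30.0)
        from neurophenopipe.ios import ROIMask
        roi = ROIMask(mask=np.zeros((8, 8), dtype=bool), fraction=0.3,
                      threshold_value=0.0)
        with pytest.raises(ValueError, match="empty"):
            evoked_amplitude(rmap, roi)


class TestInvariants:
    def test_scale_invariance_of_full_chain(self):
        trials = gen_ios_trialset(n_trials=5, shape=(32, 32),
                                  evoked_amplitude=0.005, noise_sd=0.01,
                                  seed=3)
        scaled = TrialSet(trials=[
            IOSMovie(frames=m.frames * 7.5, fps=m.fps,
                     stim_onset_frame=m.stim_onset_frame)
            for m in trials.trials])
        r1 = analyze_trialset(trials)
        r2 = analyze_trialset(scaled)
        assert np.allclose(r1.response_map.drr, r2.response_map.drr)
        assert np.array_equal(r1.roi.mask, r2.roi.mask)
        assert r1.amplitude == pytest.approx(r2.amplitude, rel=1e-12)

    def test_amplitude_monotone_in_generator_amplitude(self):
        estimates = []
        for amp in (0.002, 0.005, 0.01):
            trials = gen_ios_trialset(n_trials=20, shape=(32, 32),
                                      evoked_amplitude=amp, noise_sd=0.01,
                                      blob_sigma_px=4.0, seed=7)
            estimates.append(analyze_trialset(trials).amplitude)
        assert estimates[0] < estimates[1] < estimates[2]

    def test_recovery_against_noiseless_pipeline_truth(self):
        # the ROI mean of the window-averaged map is an attenuated
        # estimate of the peak dip; compare against the analytic
        # noiseless value from the emitted envelope and blob profile
        hits = 0
        for seed in range(5):
            trials = gen_ios_trialset(n_trials=40, shape=(32, 32),
                                      evoked_amplitude=0.005,
                                      noise_sd=0.01, blob_sigma_px=4.0,
                                      seed=seed)
            res = analyze_trialset(trials)
            meta = trials.metadata
            lo, hi = res.response_map.response_window
            truth = (meta["amplitude"] * meta["envelope"][lo:hi].mean()
                     * meta["blob_profile"][meta["mask"]].mean())
            if abs(res.amplitude / truth - 1.0) <= 0.15:
                hits += 1
        assert hits >= 4
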