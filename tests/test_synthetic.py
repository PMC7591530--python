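"""Generator ground truth, reproducibility, and study-design checks."""

import numpy as np
import pytest

from neurophenopipe.eeg import band_power_table
from neurophenopipe.synthetic import (CohortDesign, EffectModel,
                                      DEFAULT_STATE_WEIGHTS,
                                      default_effect_model,
                                      gen_arm_entries,
                                      gen_cohort_outcomes, gen_eeg,
                                      gen_ios_trialset, gen_swim_path,
                                      make_state_schedule)


class TestCohortDesign:
    def test_defaults_valid(self):
        design = CohortDesign()
        assert design.n_for("H") == 15
        assert design.timepoints == (40, 110, 180)

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError, match="n_per_group"):
            CohortDesign(n_per_group=0)

    def test_unordered_doses_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            CohortDesign(dose_mg_per_kg={"H": 10.0, "M": 46.0, "L": 14.0})

    def test_non_increasing_timepoints_rejected(self):
        with pytest.raises(ValueError, match="timepoints"):
            CohortDesign(timepoints=(40, 40, 180))


class TestIOSGenerator:
    def test_null_stimulus_gives_constant_frames(self):
        trials = gen_ios_trialset(n_trials=2, shape=(16, 16),
                                  evoked_amplitude=0.0, noise_sd=0.0,
                                  seed=0)
        for movie in trials.trials:
            assert np.all(movie.frames == movie.frames[0])

    def test_peak_dip_equals_amplitude_parameter(self):
        trials = gen_ios_trialset(n_trials=1, shape=(33, 33),
                                  blob_center=(16, 16),
                                  evoked_amplitude=0.005, noise_sd=0.0,
                                  seed=0)
        frames = trials.trials[0].frames
        baseline = frames[0]
        dip = (baseline - frames.min(axis=0)) / baseline
        assert dip.max() == pytest.approx(0.005, rel=1e-12)

    def test_dip_is_reflectance_decrease_everywhere(self):
        trials = gen_ios_trialset(n_trials=1, shape=(16, 16),
                                  evoked_amplitude=0.01, noise_sd=0.0,
                                  seed=0)
        frames = trials.trials[0].frames
        assert np.all(frames <= frames[0] + 1e-9)

    def test_ground_truth_mask_matches_blob_level(self):
        trials = gen_ios_trialset(n_trials=1, shape=(32, 32),
                                  noise_sd=0.0, seed=0)
        meta = trials.metadata
        assert np.array_equal(meta["mask"],
                              meta["blob_profile"] >= meta["mask_level"])
        assert meta["mask"].any()

    def test_overlarge_amplitude_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            gen_ios_trialset(n_trials=1, evoked_amplitude=1.5)

    def test_blob_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="blob"):
            gen_ios_trialset(n_trials=1, shape=(16, 16),
                             blob_center=(30, 8))

    def test_seed_reproducibility(self):
        a = gen_ios_trialset(n_trials=2, shape=(16, 16), seed=11)
        b = gen_ios_trialset(n_trials=2, shape=(16, 16), seed=11)
        for ma, mb in zip(a.trials, b.trials):
            assert np.array_equal(ma.frames, mb.frames)


class TestEEGGenerator:
    def test_ground_truth_event_recorded(self):
        rec = gen_eeg(300.0, seizures=[(100.0, 15.0, 5.0, 10.0)], seed=0)
        events = rec.metadata["ground_truth_events"]
        assert len(events) == 1
        assert events[0]["duration_s"] == 15.0

    def test_overlapping_bursts_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            gen_eeg(300.0, seizures=[(100.0, 30.0, 5.0, 5.0),
                                     (120.0, 10.0, 6.0, 5.0)], seed=0)

    def test_out_of_band_burst_frequency_rejected(self):
        with pytest.raises(ValueError, match="2–10"):
            gen_eeg(300.0, seizures=[(100.0, 15.0, 12.0, 5.0)], seed=0)

    def test_theta_concentrated_weights_dominate_spectrum(self):
        weights = {s: {"theta": 1.0} for s in
                   ("active-wake", "passive-wake", "sleep")}
        rec = gen_eeg(120.0, band_weights=weights, seed=1)
        table = band_power_table(rec)
        frac = (table["theta"] / table["total"]).mean()
        assert frac >= 0.8

    def test_band_proportions_match_state_weights(self):
        schedule = make_state_schedule(10, block=("sleep",) * 10)
        rec = gen_eeg(300.0, state_schedule=schedule, seed=2)
        table = band_power_table(rec)
        target = DEFAULT_STATE_WEIGHTS["sleep"]
        for band, w in target.items():
            frac = (table[band] / table["total"]).mean()
            assert frac == pytest.approx(w, abs=0.05)

    def test_total_rms_close_to_requested(self):
        rec = gen_eeg(120.0, total_rms_uv=50.0, seed=3)
        assert rec.data.std() == pytest.approx(50.0, rel=0.1)

    def test_seed_reproducibility(self):
        a = gen_eeg(60.0, seizures=[(20.0, 12.0, 5.0, 5.0)], seed=4)
        b = gen_eeg(60.0, seizures=[(20.0, 12.0, 5.0, 5.0)], seed=4)
        assert np.array_equal(a.data, b.data)


class TestArmEntryGenerator:
    def test_forced_alternation_scores_100(self):
        from neurophenopipe.behavior import score_alternation

        seq = gen_arm_entries(6, p_alternate=1.0, seed=0)
        assert score_alternation(seq)["alternation_pct"] == 100.0

    def test_no_alternation_scores_0(self):
        from neurophenopipe.behavior import score_alternation

        seq = gen_arm_entries(10, p_alternate=0.0, seed=1)
        assert score_alternation(seq)["alternation_pct"] == 0.0

    def test_long_run_rate_matches_chain_expectation(self):
        # for the 3-arm chain each triad is distinct iff the last entry
        # took the novel branch, so the expected rate equals p_alternate
        from neurophenopipe.behavior import score_alternation

        seq = gen_arm_entries(10000, p_alternate=0.5, seed=2)
        score = score_alternation(seq)
        assert score["alternation_pct"] == pytest.approx(50.0, abs=2.0)

    def test_no_consecutive_duplicates_by_construction(self):
        seq = gen_arm_entries(500, p_alternate=0.3, seed=3)
        assert all(a != b for a, b in zip(seq.entries, seq.entries[1:]))

    def test_too_few_arms_rejected(self):
        with pytest.raises(ValueError, match="three arms"):
            gen_arm_entries(10, n_arms=2)


class TestSwimPathGenerator:
    def test_path_stays_in_tank_and_time_increases(self):
        p = gen_swim_path(duration_s=60.0, seed=0)
        assert np.all(np.hypot(p.x, p.y) <= 60.0 + 1e-9)
        assert np.all(np.diff(p.t) > 0)

    def test_biased_path_reaches_platform(self):
        p = gen_swim_path(duration_s=60.0, platform_center=(30.0, 0.0),
                          bias=0.6, stop_at_platform=True, seed=1)
        assert p.duration_s < 60.0


class TestCohortOutcomes:
    def test_missing_effect_entry_rejected(self):
        design = CohortDesign(n_per_group=2)
        effects = default_effect_model(design)
        effects.treatment_effect.pop(("H", 110))
        with pytest.raises(ValueError, match="missing treatment_effect"):
            gen_cohort_outcomes(design, effects, seed=0)

    def test_table_shape_and_groups(self):
        design = CohortDesign(n_per_group=3)
        table = gen_cohort_outcomes(design, default_effect_model(design),
                                    seed=0)
        assert set(table["group"]) == set(design.groups)
        per_tp = table.query(
            "outcome == 'alternation_pct' and timepoint == 40")
        assert len(per_tp) == 3 * len(design.groups)

    def test_seizure_probability_extremes(self):
        design = CohortDesign(n_per_group=10)
        effects = default_effect_model(design)
        effects.seizure_probability.update(
            {g: 0.0 for g in design.groups})
        effects.seizure_probability["untreated-KO"] = 1.0
        table = gen_cohort_outcomes(design, effects, seed=0)
        sz = table.query("outcome == 'spontaneous_seizure'")
        assert sz.query("group == 'untreated-KO'")["value"].sum() == 10
        assert sz.query("group != 'untreated-KO'")["value"].sum() == 0

    def test_effect_shifts_toward_wild_type(self):
        design = CohortDesign(n_per_group=200, timepoints=(40,))
        effects = default_effect_model(design)
        table = gen_cohort_outcomes(design, effects, seed=1)
        alt = table.query("outcome == 'alternation_pct'")
        means = alt.groupby("group")["value"].mean()
        assert means["H"] > means["M"] > means["L"] > means["untreated-KO"] - 2.0
        assert means["wild-type"] > means["untreated-KO"]

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="probability"):
            EffectModel(baseline={"x": {"KO": (0.0, 1.0)}},
                        treatment_effect={},
                        seizure_probability={"H": 1.5})

    def test_seed_reproducibility(self):
        design = CohortDesign(n_per_group=4)
        effects = default_effect_model(design)
        a = gen_cohort_outcomes(design, effects, seed=9)
        b = gen_cohort_outcomes(design, effects, seed=9)
        assert a.equals(b)
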