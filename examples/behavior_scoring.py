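"""Score the four behavioral assays from event-level inputs.

Y-maze spontaneous alternation (triads of three distinct arms), Morris
water maze training distance/speed and probe-trial quadrant occupancy,
rotarod fall latency, and cumulative self-grooming time.
"""

from neurophenopipe import (gen_arm_entries, gen_swim_path,
                            grooming_time, mwm_training_summary,
                            probe_quadrant_times, rotarod_latency,
                            score_alternation)

# Y maze: a working-memory-impaired animal alternates less often
seq = gen_arm_entries(n_entries=25, p_alternate=0.55, seed=4)
score = score_alternation(seq)
print(f"Y maze: {score['n_entries']} entries, {score['n_triads']} triads"
      f" -> alternation {score['alternation_pct']:.1f} %")

# MWM training: biased swim toward the platform, last 3 days of 7
paths = [gen_swim_path(duration_s=60.0, platform_center=(30.0, 0.0),
                       bias=0.4, stop_at_platform=True,
                       day=day, trial=trial, seed=100 * day + trial)
         for day in range(1, 8) for trial in range(1, 5)]
training = mwm_training_summary(paths, last_k_days=3, trials_per_day=4)
print(f"MWM training: mean path {training['mean_distance_cm']:.0f} cm, "
      f"mean speed {training['mean_speed_cm_s']:.1f} cm/s "
      f"over {training['n_trials']} trials")

# MWM probe: platform removed, 60 s of exploration
probe = gen_swim_path(duration_s=60.0, platform_center=(30.0, 0.0),
                      bias=0.25, seed=5)
times = probe_quadrant_times(probe)
print("MWM probe quadrant times:",
      ", ".join(f"{q}={t:.1f} s" for q, t in times.items()))

# rotarod: mean fall latency over the session's four trials
print(f"rotarod: mean fall latency "
      f"{rotarod_latency([210.0, 260.0, 240.0, 250.0]):.0f} s")

# self-grooming: bouts scored in minutes 10-20 after habituation
bouts = [(550.0, 640.0), (800.0, 830.0), (1150.0, 1260.0)]
print(f"grooming: {grooming_time(bouts):.0f} s in the scoring window")
print()
print("T is the target quadrant (platform direction); a memory trace")
print("shows as T-quadrant preference. Grooming bouts are clipped to")
print("the 600-1200 s scoring window.")
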