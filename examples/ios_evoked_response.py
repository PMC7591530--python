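"""Recover a visually evoked IOS response from synthetic trial movies.

Generates 80 reflectance trials (64x64 px, 30 fps) carrying a 0.5 %
stimulus-locked reflectance dip under 1 % pixel noise, then runs the
full analysis chain: per-pixel ΔR/R against the pre-stimulus baseline,
trial and response-window averaging, ROI selection by the lowest-30 %-
of-range rule, and the evoked amplitude (mean dip inside the ROI).
"""

import warnings

warnings.filterwarnings("ignore", message="TrialSet has")

from neurophenopipe import analyze_trialset, gen_ios_trialset
from neurophenopipe.ios import jaccard

trials = gen_ios_trialset(n_trials=80, shape=(64, 64),
                          evoked_amplitude=0.005, noise_sd=0.01,
                          blob_sigma_px=8.0, seed=1)
result = analyze_trialset(trials, fraction=0.30)

meta = trials.metadata
lo, hi = result.response_map.response_window
expected = (meta["amplitude"] * meta["envelope"][lo:hi].mean()
            * meta["blob_profile"][meta["mask"]].mean())

print(f"trials averaged      : {trials.n_trials}")
print(f"ROI pixels           : {result.roi.n_pixels}")
print(f"ROI threshold (ΔR/R) : {result.roi.threshold_value:.2e}")
print(f"evoked amplitude     : {result.amplitude:.2e}")
print(f"noiseless expectation: {expected:.2e}")
print(f"ROI Jaccard vs truth : {jaccard(result.roi.mask, meta['mask']):.3f}")
print()
print("The evoked amplitude is the mean fractional reflectance DECREASE")
print("inside the ROI over the 2-s response window; it is smaller than")
print("the 0.005 peak dip because the hemodynamic envelope and the")
print("Gaussian response profile are averaged over window and ROI.")
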