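# Methods

`neurophenopipe` re-implements, as a tested library, the functional and
behavioral analysis chain of a longitudinal dose-ranging efficacy study
in a mouse disease model: wild-type and knockout controls plus three
daily oral dose arms (high 140, medium 46, low 14 mg/kg), followed from
weaning with widefield intrinsic optical signal (IOS) imaging at three
ages, a behavioral battery (Y maze, Morris water maze, rotarod,
self-grooming), and video-EEG.  No public dataset accompanies the
design, so a first-class synthetic generator produces every input with
known ground truth; all quantitative claims made by the test suite are
claims about recovery of that ground truth.

## IOS evoked responses

A trial movie is a stack of reflectance frames (nominally 512×512 at
30 fps; tests default to 64×64 for speed, full size is supported).  Per
pixel, the fractional change against the mean of a 1-s pre-stimulus
baseline window is

ΔR/R(t, p) = (R(t, p) − B(p)) / B(p),  B(p) = mean of the baseline window.

An evoked response is a reflectance *decrease* (negative ΔR/R).  ΔR/R
is averaged over trials and over a response window, by default stimulus
onset → onset + 2 s (the 1-s stimulus plus hemodynamic lag; the window
is configurable since the protocol does not fix it).  The ROI is chosen
by a range rule on the trial-averaged map: pixels with value
≤ min + f·(max − min), f = 0.30 — i.e. the lowest 30 % of the min–max
range, not the 30th percentile (a percentile mode is available).  The
evoked amplitude is reported as −mean(ΔR/R) over the ROI, so a deeper
dip is a larger positive number.

Two numerical choices matter:

* **Smoothing before thresholding.**  The range rule depends on the two
  extreme pixels of the map, so residual pixel noise systematically
  widens the range and shrinks the mask.  The map is Gaussian-smoothed
  (default σ = 1 px) *only* for threshold and mask derivation; the
  amplitude is always measured on the unsmoothed map.
* **What "recovery" means.**  The generator's evoked response is a peak
  dip `A` modulated by a unit-peak temporal envelope (0.5-s linear
  rise, 1-s plateau, exponential decay τ = 1 s) and a unit-peak
  Gaussian spatial profile.  Averaging over the response window and the
  ROI therefore attenuates the measured amplitude below `A` by an
  analytically known factor (≈ 0.69 at the defaults).  Recovery tests
  compare the estimate against this noiseless pipeline value, computed
  from the envelope and blob profile the generator emits — the
  estimator is then unbiased and the test measures the effect of noise
  alone, rather than conflating it with the deterministic attenuation
  every window/ROI-mean estimator has.  Correspondingly, the emitted
  ground-truth mask is the *noiseless target of the ROI rule* (blob
  profile ≥ 1 − f = 0.70), so a mask Jaccard of 1.0 means the rule
  performed as well as it possibly could; comparing against an
  unrelated level set (e.g. the half-maximum contour) would bound the
  Jaccard away from 1 for purely geometric reasons.

The chain is invariant to overall gain (multiplying all raw frames by
c > 0 changes nothing downstream), monotone in the generated amplitude,
and errors out explicitly on degenerate inputs (non-positive baseline
pixels; constant maps).

## EEG spectra

Recordings are µV traces at 400 Hz (frontal/occipital).  They are cut
into non-overlapping 30-s epochs (trailing partial epoch dropped) and
each epoch is mean-removed, Hann-windowed and converted to a one-sided
periodogram (Welch averaging is available as an option).  Band powers
integrate the spectral density over delta 0.5–4, theta 4–8, alpha 8–12,
beta 12–30 and gamma 30–45 Hz with half-open edges [lo, hi), so the
five bands partition the 0.5–45 Hz analysis range exactly and sum to
the total to machine precision.  Epoch means are stratified by
vigilance state (active wake / passive wake / sleep) and light cycle;
a stratum mean is reported only with ≥ 12 epochs, otherwise the count
is kept and the mean is missing.  Epochs overlapping detected seizures
can be excluded before averaging so baseline spectra stay
uncontaminated.  Both absolute and (via the emitted total) relative
band powers are obtainable, since group contrasts can be phrased
either way.

## Seizure detection

The ictal feature is the classic line length: the sum of absolute
successive sample differences over a sliding window (1-s windows,
0.5-s steps by default; a per-sample-normalized variant is provided).
The trace is first band-passed 2–10 Hz with a zero-phase 4th-order
Butterworth filter, which makes "events in the 2–10 Hz range"
operational and hardware-independent.  A per-animal threshold is
calibrated on a user-designated seizure-free baseline as
mean + k·SD of the windowed line lengths (k = 8; sample SD, n−1,
recorded in the calibration output).  Supra-threshold windows are
merged across gaps < 1 s into candidate events.

Because a coarse window localises an edge only to within the window
length, candidate edges are refined on a finely stepped (0.05 s)
line-length profile: as the window slides across an event edge the
statistic ramps between its baseline and ictal levels over exactly one
window length, so the crossing of the midpoint level, shifted by half
a window, estimates the true edge to a fraction of the window.  The
≥ 10-s minimum-duration rule is applied to the refined span; on
synthetic bursts this gives duration errors of ~0.1–0.2 s, cleanly
separating 8-s (rejected) from 12-s (kept) events.  Detection is
invariant to overall gain once the threshold is recalibrated, and
raising k never adds events.

Behavioral severity uses the six-stage Racine scale collapsed to three
categories — stages 1–2 tonic, 3 clonic, 4–6 tonic–clonic — and
per-group incidence tables feed the exact tests below.  Event metrics
(latency to first event, events per hour, mean duration) summarise
chemoconvulsant-challenge recordings.

## Behavioral scoring

* **Y maze.**  An entry is a new arm only (consecutive duplicates are
  invalid input).  A triad is three consecutive entries into three
  distinct arms; the alternation percentage is
  100·triads/(entries − 2), the maximum-possible-triads denominator.
* **Morris water maze.**  Path length is the sum of consecutive
  Euclidean steps of the tracked position (120-cm tank); training
  summaries average distance and speed over the last 3 days × 4 trials,
  including time-limited trials where the platform was never reached.
  Probe-trial quadrant times split the tank into four 90° sectors
  centred on the platform direction (T, with R/L the clockwise/
  counter-clockwise neighbours and O opposite), assign each sample
  interval to its starting position's sector (half-open boundaries),
  and conserve the trial duration to within one sample interval.
* **Rotarod** is the mean recorded fall latency over a session's
  trials; **self-grooming** sums bout∩window durations over the
  10–20-min scoring window after habituation.

## Group statistics

The design compares several treated groups against a shared untreated
control, so the post-hoc procedure is Dunnett's many-to-one test.
Factorial ANOVA uses Type-II sums of squares (the study's groups are
mildly unbalanced, 15 vs 17); repeated-measures ANOVA is available for
within-subject factors such as probe-trial quadrant.  Dunnett adjusted
p-values come from the joint multivariate-t distribution of the
comparison statistics with the exact unbalanced correlations
ρᵢⱼ = √(nᵢnⱼ/((nᵢ+n₀)(nⱼ+n₀))) (ρ = 1/2 balanced) and pooled-variance
degrees of freedom, evaluated by seeded quasi-Monte-Carlo integration
(scipy's single-step implementation; the step-down variant is not
offered).  A vectorised many-to-one t-statistic and an equicoordinate
critical-value solver support large calibration simulations.

Fisher's exact test is two-sided by probability ordering (the sum of
hypergeometric probabilities of tables no more probable than the one
observed, margins fixed), χ² is Pearson's without continuity
correction, rank transformation mid-ranks ties for rank-based ANOVA of
non-normal outcomes, and a-priori per-group n is the smallest n whose
noncentral-t two-sample power reaches the target (α = 0.05, power 0.8
defaults).

Calibration at the study's group-size pattern (control 17, treated
15/15/17/17) over 10,000 null cohorts puts both the ANOVA and the
Dunnett family-wise rejection rates within Monte-Carlo error of
α = 0.05.  With dose-ordered standardized recovery effects
(H = 1.2, M = 0.8, L = 0.3 SD at every age) the primary endpoint is
each animal's mean over the three ages; Dunnett then flags H and M in
well over 80 % of cohorts and L in a small minority — the
minimum-efficacious-dose pattern.  Single-timepoint analysis at d = 0.8
and n ≈ 15–17 would have ≈ 40 % power under the Dunnett correction, so
the longitudinal mean is the appropriate primary readout at these
sample sizes.

## The synthetic cohort generator

The generator emulates, with ground truth always emitted alongside:

* **IOS trials** — constant baseline reflectance, a spatially Gaussian
  temporally ramped reflectance decrease, i.i.d. Gaussian pixel noise
  (SD as a fraction of baseline, default 1 %).  Defaults: 80 trials,
  64×64 (scaled from 512×512 to keep suites fast), peak dip 0.5 %.
* **EEG** — per-vigilance-state band-weighted Gaussian background,
  synthesised band-limited in the frequency domain (flat within each
  canonical band, zero outside 0.5–45 Hz) so band-power proportions are
  analytic; one contiguous synthesis per same-state run keeps spectra
  stationary within states.  Sleep is delta-dominated (0.55), active
  wake theta-dominated (0.45); total RMS 50 µV.  Ictal bursts are
  sinusoid-plus-harmonics (relative amplitudes 1/0.4/0.2) at 2–10 Hz
  with RMS a specified gain over background, added to it; overlapping
  bursts are rejected so ground truth stays unambiguous.
* **Arm entries** — first two entries distinct and uniform; thereafter
  the novel arm with probability `p_alternate`, otherwise the arm seen
  two entries back (an immediate re-entry is by definition not a new
  entry, so for a 3-arm maze the non-novel branch is deterministic and
  the expected alternation percentage equals 100·p_alternate exactly).
* **Swim paths** — bounded 2-D random walks with an optional heading
  bias toward the platform; training trials can stop at platform
  contact.  Summary MWM outcomes are generated at cohort level; the
  walk exists for the path-geometry operations, not as a biomechanical
  model.
* **Cohort outcomes** — per animal × age Gaussian draws from genotype
  baselines (knockouts: shallower IOS dip, lower alternation, longer
  MWM path, stereotypy-inflated rotarod latency and grooming), with
  the (group, age) standardized effect shifting treated knockouts
  toward the wild-type mean; Bernoulli spontaneous-seizure status per
  group (untreated/vehicle 0.30, H/M 0.02, L 0.22) and a Racine stage
  distribution shifted toward mild stages under effective treatment.

Ages are drawn independently within animal: the within-animal
correlation across ages is not reported for the original cohort, so
none is modelled (this makes the longitudinal mean conservative — real
positively correlated repeats would lower its effective n).  All
randomness flows through one seeded `numpy` Generator per call; the
same seed and parameters give bit-identical output.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: vascular and motion artifacts,
breathing/heartbeat periodics and photobleaching in IOS; 1/f spectral
shape, movement artifacts, electrode drift, and the gradual
(non-abrupt) onset of real ictal discharges in EEG; state transitions
misaligned with epoch boundaries; non-Gaussian, skewed behavioral
outcome distributions.  Results here certify the correctness and
calibration of the computations, not robustness to those artifacts.

## Pipeline and reproducibility

`run_study` executes cohort generation → IOS analysis → EEG spectra and
seizure detection → behavioral scoring → group statistics, writing
tidy CSVs and a JSON manifest with SHA-256 checksums of every output.
Stage seeds derive from the master seed via SHA-256 of
(master, stage, identifiers), so stages are decoupled and the whole run
is bit-reproducible.  Raw-signal simulation (trial movies, EEG records)
runs on a configurable demonstration subset of animals — summary
statistics need only the cohort table, and full-cohort raw simulation
adds nothing but runtime; the defaults (two groups × three ages of
20-trial 32×32 movies, two 20-min EEG records) complete in seconds.
Times are seconds from record start; image coordinates are 0-based
(row, col).

File formats: multi-page TIFF + JSON sidecar for image stacks, EDF
(16-bit, physical unit µV) for EEG — read via MNE, written by a
minimal built-in single-record-per-second writer since no installed
library writes EDF — and schema-checked CSV for tables.  EDF round
trips are exact to within one 16-bit quantisation step.

## Known limitations

* The ROI range rule is inherently sensitive to single-pixel outliers;
  the default 1-px smoothing mitigates but does not remove this, and
  maps dominated by artifacts will still produce distorted masks.
* The line-length detector assumes an approximately stationary baseline
  within the calibration interval; calibrating on one vigilance state
  and detecting across states with very different 2–10 Hz content will
  shift its operating point (the default synthetic schedule includes
  all states in the calibration window for this reason).
* Dunnett p-values rely on quasi-Monte-Carlo evaluation of the
  multivariate-t rectangle probability (seeded, ~10⁻³ accuracy); exact
  to that tolerance only.
* Repeated-measures ANOVA requires balanced within-subject data and no
  sphericity correction is applied; mixed-effects modelling is out of
  scope.
* The EDF writer emits the minimal header fields this pipeline needs
  (no annotations, integer sampling rates only).
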