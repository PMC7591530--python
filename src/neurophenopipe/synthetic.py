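"""Synthetic cohort generator for the longitudinal efficacy design.

Emulates every input the analysis pipeline consumes, with ground truth
carried alongside the data so downstream estimates can be checked
without re-derivation:

* IOS trial movies — constant baseline reflectance plus a spatially
  Gaussian, temporally ramped reflectance *decrease* at the stimulus,
  plus i.i.d. Gaussian pixel noise;
* EEG traces — per-state band-weighted Gaussian background (synthesised
  band-limited in the frequency domain, so band-power proportions are
  analytic) with optional injected ictal bursts (sinusoid plus
  harmonics, 2–10 Hz, RMS a fixed gain over background);
* Y-maze arm-entry sequences with a tunable alternation bias;
* swim paths as bounded 2-D random walks;
* per-animal scalar outcomes for the whole cohort, with dose- and
  age-dependent standardized effect sizes and Bernoulli spontaneous-
  seizure status.

Every generator routes randomness through one seeded generator per
call: identical seed and parameters give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .behavior import ArmEntrySequence, SwimPath
from .eeg import CANONICAL_BANDS, CYCLES, STATES, EEGRecording, VigilanceLabels
from .ios import IOSMovie, TrialSet

__all__ = [
    "CohortDesign",
    "EffectModel",
    "default_effect_model",
    "gen_ios_trialset",
    "gen_eeg",
    "make_state_schedule",
    "gen_arm_entries",
    "gen_swim_path",
    "gen_cohort_outcomes",
    "DEFAULT_STATE_WEIGHTS",
]

GROUPS = ("wild-type", "untreated-KO", "vehicle-KO", "H", "M", "L")

#: outcomes drawn per animal and timepoint by :func:`gen_cohort_outcomes`
OUTCOMES = ("ios_amplitude", "alternation_pct", "mwm_distance_cm",
            "mwm_speed_cm_s", "rotarod_latency_s", "grooming_time_s")


@dataclass
class CohortDesign:
    """Groups, sizes, imaging timepoints and doses of the study design.

    Defaults mirror a dose-ranging efficacy layout: wild-type and
    untreated / vehicle-treated knockout controls plus high, medium and
    low dose arms (140 / 46 / 14 mg/kg daily), with longitudinal imaging
    at postnatal days 40, 110 and 180.
    """

    groups: tuple[str, ...] = GROUPS
    n_per_group: int | Mapping[str, int] = 15
    timepoints: tuple[int, ...] = (40, 110, 180)
    dose_mg_per_kg: Mapping[str, float] = field(
        default_factory=lambda: {"H": 140.0, "M": 46.0, "L": 14.0})
    control_group: str = "untreated-KO"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        if self.control_group not in self.groups:
            raise ValueError("control_group must be one of groups")
        for g in self.groups:
            if self.n_for(g) < 1:
                raise ValueError(f"n_per_group for {g!r} must be >= 1")
        tps = list(self.timepoints)
        if sorted(set(tps)) != tps:
            raise ValueError("timepoints must be strictly increasing")
        doses = [self.dose_mg_per_kg.get(k) for k in ("H", "M", "L")
                 if k in self.dose_mg_per_kg]
        if len(doses) >= 2 and any(b >= a for a, b in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly ordered H > M > L")

    def n_for(self, group: str) -> int:
        if isinstance(self.n_per_group, Mapping):
            return int(self.n_per_group[group])
        return int(self.n_per_group)

    def animals(self) -> list[tuple[str, str]]:
        """(animal_id, group) pairs, deterministic ordering."""
        out = []
        for g in self.groups:
            for i in range(self.n_for(g)):
                out.append((f"{g}-{i + 1:02d}", g))
        return out


@dataclass
class EffectModel:
    """Outcome distributions and treatment effects for the generator.

    ``baseline`` maps outcome → genotype → (mean, sd); genotypes are
    ``"wild-type"`` and ``"KO"`` (all non-wild-type groups).
    ``treatment_effect`` maps ``(group, timepoint)`` → standardized
    effect size d; the drawn KO mean is shifted by ``d · sd`` *toward*
    the wild-type mean, so d is the recovery effect in SD units.
    ``seizure_probability`` maps group → Bernoulli probability of
    spontaneous seizures; ``racine_stage_probs`` maps group → six
    probabilities over Racine stages 1–6 for seized animals.
    """

    baseline: Mapping[str, Mapping[str, tuple[float, float]]]
    treatment_effect: Mapping[tuple[str, int], float]
    seizure_probability: Mapping[str, float]
    racine_stage_probs: Mapping[str, Sequence[float]] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        for outcome, per_geno in self.baseline.items():
            for geno, (mean, sd) in per_geno.items():
                if sd <= 0:
                    raise ValueError(
                        f"sd for {outcome}/{geno} must be positive")
        for g, p in self.seizure_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"seizure probability for {g!r} "
                                 "must lie in [0, 1]")
        for g, probs in self.racine_stage_probs.items():
            probs = np.asarray(probs, dtype=float)
            if probs.shape != (6,) or np.any(probs < 0) \
                    or not math.isclose(probs.sum(), 1.0, rel_tol=1e-9):
                raise ValueError(
                    f"racine_stage_probs for {g!r} must be six "
                    "probabilities summing to 1")


def default_effect_model(design: CohortDesign | None = None,
                         d_by_group: Mapping[str, float] | None = None
                         ) -> EffectModel:
    """Effect model with realistic rodent-phenotyping outcome scales.

    Baselines encode the knockout deficit (shallower evoked IOS dip,
    reduced alternation, longer MWM path, stereotypy-inflated rotarod
    latency and grooming time); ``d_by_group`` sets the dose-ordered
    standardized recovery (default H=1.2, M=0.8, L=0.3, controls 0) at
    every timepoint.
    """
    design = design or CohortDesign()
    if d_by_group is None:
        d_by_group = {"H": 1.2, "M": 0.8, "L": 0.3}
    baseline = {
        "ios_amplitude": {"wild-type": (2.5e-3, 5e-4),
                          "KO": (1.2e-3, 4e-4)},
        "alternation_pct": {"wild-type": (68.0, 7.0), "KO": (55.0, 8.0)},
        "mwm_distance_cm": {"wild-type": (500.0, 150.0),
                            "KO": (800.0, 200.0)},
        "mwm_speed_cm_s": {"wild-type": (18.0, 3.0), "KO": (18.0, 3.0)},
        "rotarod_latency_s": {"wild-type": (180.0, 50.0),
                              "KO": (280.0, 60.0)},
        "grooming_time_s": {"wild-type": (60.0, 20.0),
                            "KO": (120.0, 30.0)},
    }
    effect = {(g, tp): float(d_by_group.get(g, 0.0))
              for g in design.groups for tp in design.timepoints}
    seizure_p = {"wild-type": 0.0, "untreated-KO": 0.30,
                 "vehicle-KO": 0.30, "H": 0.02, "M": 0.02, "L": 0.22}
    seizure_p = {g: seizure_p.get(g, 0.0) for g in design.groups}
    stage_ctrl = [0.10, 0.15, 0.20, 0.25, 0.20, 0.10]
    stage_treated = [0.35, 0.30, 0.20, 0.10, 0.04, 0.01]
    racine = {g: (stage_treated if g in ("H", "M") else stage_ctrl)
              for g in design.groups}
    return EffectModel(baseline=baseline, treatment_effect=effect,
                       seizure_probability=seizure_p,
                       racine_stage_probs=racine)


# ---------------------------------------------------------------------------
# IOS trial movies
# ---------------------------------------------------------------------------

def _hemodynamic_envelope(t_s: np.ndarray, rise_s: float = 0.5,
                          plateau_s: float = 1.0,
                          decay_tau_s: float = 1.0) -> np.ndarray:
    """Unit-peak evoked envelope: linear rise, plateau, exponential decay.

    ``t_s`` is time from stimulus onset; negative times give 0.
    """
    env = np.zeros_like(t_s, dtype=float)
    rising = (t_s >= 0) & (t_s < rise_s)
    env[rising] = t_s[rising] / rise_s
    flat = (t_s >= rise_s) & (t_s < rise_s + plateau_s)
    env[flat] = 1.0
    tail = t_s >= rise_s + plateau_s
    env[tail] = np.exp(-(t_s[tail] - rise_s - plateau_s) / decay_tau_s)
    return env


def gen_ios_trialset(n_trials: int = 80,
                     shape: tuple[int, int] = (64, 64),
                     fps: float = 30.0,
                     baseline_s: float = 1.0,
                     post_s: float = 3.0,
                     evoked_amplitude: float = 0.005,
                     noise_sd: float = 0.01,
                     blob_center: tuple[float, float] | None = None,
                     blob_sigma_px: float = 8.0,
                     baseline_level: float = 10000.0,
                     rise_s: float = 0.5,
                     plateau_s: float = 1.0,
                     decay_tau_s: float = 1.0,
                     mask_level: float = 0.7,
                     seed: int | None = None) -> TrialSet:
    """Generate repeated IOS trials with a known evoked response.

    Each trial is ``baseline_s`` of pre-stimulus frames followed by
    ``post_s`` of response: frames are
    ``baseline_level · (1 − A · env(t) · g(x, y)) + noise`` with ``A``
    the peak fractional reflectance dip (``evoked_amplitude``), ``env``
    the unit-peak hemodynamic envelope and ``g`` a unit-peak Gaussian
    blob of width ``blob_sigma_px`` — a reflectance *decrease* only.
    Pixel noise is i.i.d. Gaussian with SD ``noise_sd`` expressed as a
    fraction of the baseline level.

    Ground truth in ``TrialSet.metadata``: the envelope samples, the
    blob profile, the peak amplitude, and ``mask`` — the pixels whose
    noiseless dip reaches ``mask_level`` (default 0.7, the noiseless
    target of the 30 %-of-range ROI rule).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 <= evoked_amplitude <= 1.0:
        raise ValueError("evoked_amplitude is a reflectance fraction "
                         "and must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    h, w = shape
    if h < 1 or w < 1:
        raise ValueError("frame size must be positive")
    if blob_center is None:
        blob_center = ((h - 1) / 2.0, (w - 1) / 2.0)
    cy, cx = blob_center
    if not (0 <= cy < h and 0 <= cx < w):
        raise ValueError("blob centre must lie inside the frame")
    rng = np.random.default_rng(seed)
    n_base = int(round(baseline_s * fps))
    n_post = int(round(post_s * fps))
    n_frames = n_base + n_post
    t_s = (np.arange(n_frames) - n_base) / fps
    env = _hemodynamic_envelope(t_s, rise_s, plateau_s, decay_tau_s)
    yy, xx = np.mgrid[0:h, 0:w]
    g = np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2)
                 / (2.0 * blob_sigma_px ** 2)))
    dip = evoked_amplitude * env[:, None, None] * g[None, :, :]
    clean = baseline_level * (1.0 - dip)
    trials = []
    for _ in range(n_trials):
        noise = rng.normal(0.0, noise_sd * baseline_level,
                           size=(n_frames, h, w)) if noise_sd > 0 else 0.0
        frames = np.clip(clean + noise, 0.0, None)
        trials.append(IOSMovie(frames=frames, fps=fps,
                               stim_onset_frame=n_base))
    truth = {
        "amplitude": evoked_amplitude,
        "noise_sd": noise_sd,
        "envelope": env,
        "blob_profile": g,
        "mask": g >= mask_level,
        "mask_level": mask_level,
        "blob_center": (cy, cx),
        "blob_sigma_px": blob_sigma_px,
        "stim_onset_frame": n_base,
    }
    return TrialSet(trials=trials, metadata=truth)


# ---------------------------------------------------------------------------
# EEG traces
# ---------------------------------------------------------------------------

#: per-state canonical band weights (fractions of total variance);
#: sleep is delta-dominated, active wake theta-dominated.
DEFAULT_STATE_WEIGHTS: dict[str, dict[str, float]] = {
    "active-wake": {"delta": 0.15, "theta": 0.45, "alpha": 0.15,
                    "beta": 0.15, "gamma": 0.10},
    "passive-wake": {"delta": 0.30, "theta": 0.30, "alpha": 0.15,
                     "beta": 0.15, "gamma": 0.10},
    "sleep": {"delta": 0.55, "theta": 0.20, "alpha": 0.10,
              "beta": 0.10, "gamma": 0.05},
}

#: relative amplitudes of an ictal burst's fundamental and harmonics
BURST_HARMONICS = (1.0, 0.4, 0.2)


def make_state_schedule(n_epochs: int, epoch_s: float = 30.0,
                        block: Sequence[str] = ("sleep",) * 8
                        + ("passive-wake",) * 6 + ("active-wake",) * 6
                        ) -> VigilanceLabels:
    """Deterministic vigilance schedule cycling through a block pattern.

    The light cycle flips at the record midpoint (light first), mirroring
    a recording that spans both photoperiods.
    """
    states = [block[i % len(block)] for i in range(n_epochs)]
    cycles = ["light" if i < n_epochs / 2 else "dark"
              for i in range(n_epochs)]
    return VigilanceLabels(states=np.array(states, dtype=object),
                           cycles=np.array(cycles, dtype=object),
                           epoch_s=epoch_s)


def _band_limited_noise(n: int, fs: float,
                        weights: Mapping[str, float],
                        total_rms: float, rng: np.random.Generator
                        ) -> np.ndarray:
    """Gaussian noise with prescribed band-power proportions.

    Synthesised in the frequency domain: within each canonical band the
    spectrum is flat with total power proportional to the band weight;
    outside 0.5–45 Hz the spectrum is zero.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    target = np.zeros_like(freqs)
    wsum = sum(weights.values())
    for band, (lo, hi) in CANONICAL_BANDS.items():
        wgt = weights.get(band, 0.0) / wsum
        sel = (freqs >= lo) & (freqs < hi)
        n_bins = int(sel.sum())
        if n_bins:
            target[sel] = wgt / n_bins
    coeff = (rng.standard_normal(len(freqs))
             + 1j * rng.standard_normal(len(freqs))) * np.sqrt(target / 2.0)
    coeff[0] = 0.0
    if n % 2 == 0:
        coeff[-1] = coeff[-1].real * np.sqrt(2.0)
    x = np.fft.irfft(coeff, n=n)
    # with E|X_k|^2 = target_k and sum(target) = 1 the synthesised trace
    # has E[var] = 2/n^2 * sum -> rescale analytically to total_rms
    scale = total_rms * n / np.sqrt(2.0)
    return x * scale


def gen_eeg(duration_s: float,
            fs: float = 400.0,
            state_schedule: VigilanceLabels | None = None,
            band_weights: Mapping[str, Mapping[str, float]] | None = None,
            seizures: Sequence[tuple[float, float, float, float]] = (),
            total_rms_uv: float = 50.0,
            channel_names: tuple[str, ...] = ("frontal",),
            seed: int | None = None) -> EEGRecording:
    """Generate an EEG record with state-dependent spectra and bursts.

    ``seizures`` is a list of ``(onset_s, duration_s, freq_hz, gain)``;
    each burst is a sinusoid plus harmonics at ``freq_hz`` (which must
    lie in 2–10 Hz) whose RMS is ``gain`` times the background RMS,
    added on top of the background.  Overlapping bursts are rejected so
    the ground truth stays unambiguous.  The injected event list and the
    state schedule are stored in ``metadata``.
    """
    n = int(round(duration_s * fs))
    if n < 2:
        raise ValueError("duration too short")
    epoch_s = 30.0
    if state_schedule is None:
        n_epochs = max(1, int(duration_s // epoch_s))
        state_schedule = make_state_schedule(n_epochs, epoch_s)
    epoch_s = state_schedule.epoch_s
    weights = band_weights or DEFAULT_STATE_WEIGHTS
    events = sorted((float(o), float(d), float(f), float(g))
                    for o, d, f, g in seizures)
    for onset, dur, freq, gain in events:
        if not 2.0 <= freq <= 10.0:
            raise ValueError("ictal burst frequency must lie in 2–10 Hz")
        if gain < 1.0:
            raise ValueError("burst gain must be >= 1")
        if onset < 0 or onset + dur > duration_s:
            raise ValueError("burst must lie within the record")
    for (o1, d1, *_), (o2, *_rest) in zip(events, events[1:]):
        if o2 < o1 + d1:
            raise ValueError("injected ictal events must not overlap")
    rng = np.random.default_rng(seed)
    x = np.zeros((len(channel_names), n))
    # one contiguous synthesis per same-state run keeps spectra stationary
    state_per_epoch = list(state_schedule.states)
    runs: list[tuple[int, int, str]] = []
    start_ep = 0
    for i in range(1, len(state_per_epoch) + 1):
        if i == len(state_per_epoch) \
                or state_per_epoch[i] != state_per_epoch[start_ep]:
            runs.append((start_ep, i, state_per_epoch[start_ep]))
            start_ep = i
    for ch in range(len(channel_names)):
        pos = 0
        for ep0, ep1, state in runs:
            i0 = int(round(ep0 * epoch_s * fs))
            i1 = min(n, int(round(ep1 * epoch_s * fs)))
            if i1 <= i0:
                continue
            x[ch, i0:i1] = _band_limited_noise(
                i1 - i0, fs, weights[state], total_rms_uv, rng)
            pos = i1
        if pos < n:  # beyond the labelled schedule: reuse the last state
            state = runs[-1][2] if runs else STATES[0]
            x[ch, pos:n] = _band_limited_noise(
                n - pos, fs, weights[state], total_rms_uv, rng)
        for onset, dur, freq, gain in events:
            i0 = int(round(onset * fs))
            i1 = min(n, int(round((onset + dur) * fs)))
            t = np.arange(i1 - i0) / fs
            amp_unit = math.sqrt(sum(h * h for h in BURST_HARMONICS) / 2.0)
            a = gain * total_rms_uv / amp_unit
            phase = rng.uniform(0.0, 2.0 * math.pi)
            burst = np.zeros(i1 - i0)
            for k, h in enumerate(BURST_HARMONICS, start=1):
                if k * freq < fs / 2.0:
                    burst += a * h * np.sin(
                        2.0 * math.pi * k * freq * t + phase * k)
            x[ch, i0:i1] += burst
    return EEGRecording(
        data=x, fs=fs, channel_names=channel_names,
        metadata={
            "ground_truth_events": [
                {"onset_s": o, "duration_s": d, "freq_hz": f, "gain": g}
                for o, d, f, g in events],
            "state_schedule": state_schedule,
            "total_rms_uv": total_rms_uv,
        })


# ---------------------------------------------------------------------------
# Behavioral inputs
# ---------------------------------------------------------------------------

def gen_arm_entries(n_entries: int, p_alternate: float = 0.5,
                    n_arms: int = 3,
                    seed: int | None = None) -> ArmEntrySequence:
    """Arm-entry sequence with a tunable alternation bias.

    The first two entries are distinct arms chosen uniformly; from the
    third on, with probability ``p_alternate`` the animal enters an arm
    not visited in the previous two entries (uniform among those),
    otherwise it returns to the arm seen two entries back (returning to
    the immediately previous arm is never a new entry).  For a 3-arm
    maze the expected alternation percentage therefore equals
    ``100 · p_alternate``.
    """
    if n_entries < 0:
        raise ValueError("n_entries must be >= 0")
    if not 0.0 <= p_alternate <= 1.0:
        raise ValueError("p_alternate must lie in [0, 1]")
    if n_arms < 3:
        raise ValueError("a Y maze needs at least three arms")
    arms = tuple(chr(ord("A") + i) for i in range(n_arms))
    rng = np.random.default_rng(seed)
    entries: list[str] = []
    if n_entries >= 1:
        entries.append(arms[rng.integers(n_arms)])
    if n_entries >= 2:
        others = [a for a in arms if a != entries[0]]
        entries.append(others[rng.integers(len(others))])
    while len(entries) < n_entries:
        recent = {entries[-1], entries[-2]}
        novel = [a for a in arms if a not in recent]
        if rng.random() < p_alternate:
            entries.append(novel[rng.integers(len(novel))])
        else:
            entries.append(entries[-2])
    return ArmEntrySequence(entries=entries, arms=arms)


def gen_swim_path(duration_s: float = 60.0, dt_s: float = 0.2,
                  speed_cm_s: float = 18.0,
                  tank_diameter_cm: float = 120.0,
                  platform_center: tuple[float, float] | None = None,
                  bias: float = 0.0,
                  stop_at_platform: bool = False,
                  platform_halfwidth_cm: float = 5.5,
                  day: int | None = None, trial: int | None = None,
                  seed: int | None = None) -> SwimPath:
    """Bounded 2-D random-walk swim path.

    The heading performs a random walk; ``bias`` (0..1) steers it toward
    the platform each step, emulating learned search.  With
    ``stop_at_platform`` the path ends at first platform contact (or at
    the time limit), as in a training trial.
    """
    rng = np.random.default_rng(seed)
    radius = tank_diameter_cm / 2.0
    n = int(round(duration_s / dt_s)) + 1
    xs = np.empty(n)
    ys = np.empty(n)
    ang = rng.uniform(0, 2 * math.pi)
    r0 = 0.9 * radius
    xs[0], ys[0] = r0 * math.cos(ang), r0 * math.sin(ang)
    heading = rng.uniform(0, 2 * math.pi)
    last = n - 1
    for i in range(1, n):
        heading += rng.normal(0.0, 0.8)
        if bias > 0 and platform_center is not None:
            goal = math.atan2(platform_center[1] - ys[i - 1],
                              platform_center[0] - xs[i - 1])
            diff = (goal - heading + math.pi) % (2 * math.pi) - math.pi
            heading += bias * diff
        nx = xs[i - 1] + speed_cm_s * dt_s * math.cos(heading)
        ny = ys[i - 1] + speed_cm_s * dt_s * math.sin(heading)
        rr = math.hypot(nx, ny)
        if rr > 0.98 * radius:  # reflect off the wall
            nx *= 0.96 * radius / rr
            ny *= 0.96 * radius / rr
            heading += math.pi / 2.0
        xs[i], ys[i] = nx, ny
        if stop_at_platform and platform_center is not None:
            if (abs(nx - platform_center[0]) <= platform_halfwidth_cm
                    and abs(ny - platform_center[1])
                    <= platform_halfwidth_cm):
                last = i
                break
    t = np.arange(last + 1) * dt_s
    return SwimPath(t=t, x=xs[:last + 1], y=ys[:last + 1],
                    tank_diameter_cm=tank_diameter_cm,
                    platform_center=platform_center,
                    platform_halfwidth_cm=platform_halfwidth_cm,
                    day=day, trial=trial)


# ---------------------------------------------------------------------------
# Cohort outcome table
# ---------------------------------------------------------------------------

def gen_cohort_outcomes(design: CohortDesign,
                        effects: EffectModel,
                        seed: int | None = None) -> pd.DataFrame:
    """Per-animal scalar outcomes for the whole cohort (tidy table).

    Gaussian outcomes are drawn per animal × timepoint from the genotype
    baseline, with the ``(group, timepoint)`` standardized effect
    shifting treated knockouts toward the wild-type mean.  Spontaneous
    seizure status (Bernoulli per group) and, for seized animals, a
    Racine stage are drawn once per animal and attached at the final
    timepoint as outcomes ``spontaneous_seizure`` and ``racine_stage``.

    Timepoints are drawn independently (no within-animal correlation is
    modelled).
    """
    rng = np.random.default_rng(seed if seed is not None else design.seed)
    for g in design.groups:
        for tp in design.timepoints:
            if (g, tp) not in effects.treatment_effect:
                raise ValueError(
                    f"missing treatment_effect entry for ({g!r}, {tp})")
        if g not in effects.seizure_probability:
            raise ValueError(f"missing seizure probability for {g!r}")
    rows = []
    final_tp = design.timepoints[-1]
    for animal_id, group in design.animals():
        genotype = "wild-type" if group == "wild-type" else "KO"
        for tp in design.timepoints:
            d = effects.treatment_effect[(group, tp)]
            for outcome in OUTCOMES:
                mean, sd = effects.baseline[outcome][genotype]
                if genotype == "KO":
                    wt_mean, _ = effects.baseline[outcome]["wild-type"]
                    direction = np.sign(wt_mean - mean)
                    mean = mean + d * sd * direction
                value = rng.normal(mean, sd)
                rows.append((animal_id, group, tp, outcome, value))
        p_sz = effects.seizure_probability[group]
        seized = bool(rng.random() < p_sz)
        rows.append((animal_id, group, final_tp,
                     "spontaneous_seizure", float(seized)))
        if seized:
            probs = effects.racine_stage_probs.get(
                group, [1 / 6.0] * 6)
            stage = int(rng.choice(np.arange(1, 7), p=probs))
            rows.append((animal_id, group, final_tp,
                         "racine_stage", float(stage)))
    return pd.DataFrame(
        rows, columns=["animal_id", "group", "timepoint",
                       "outcome", "value"])
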