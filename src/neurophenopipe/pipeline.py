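"""End-to-end study replica: generate → analyse → score → test.

:func:`run_study` executes the full longitudinal design on a synthetic
cohort: scalar outcomes for every animal at every timepoint, raw-signal
demonstrations (IOS trial movies and EEG records with injected ictal
bursts) for a configurable subset of animals, behavioral scoring, and
the inferential layer (ANOVA + Dunnett versus the untreated control,
Fisher's exact on seizure incidence, χ² on severity categories).

All randomness derives from one master seed through a stable splitting
scheme (SHA-256 of ``(master, stage, ...)``), so re-running with the
same configuration reproduces every numeric output bit-identically; a
manifest lists every output file with its SHA-256 checksum.

Conventions: times are seconds from record start; image coordinates are
0-based ``(row, col)``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import score_alternation
from .eeg import average_band_powers, band_power_table, exclude_epochs
from .ios import analyze_trialset, jaccard
from .seizure import (DetectorConfig, calibrate_threshold, classify_racine,
                      detect_seizures, event_metrics, incidence_table)
from .stats import anova, chi_square, dunnett, fisher_exact
from .synthetic import (CohortDesign, EffectModel, default_effect_model,
                        gen_cohort_outcomes, gen_eeg, gen_ios_trialset,
                        make_state_schedule, OUTCOMES)

__all__ = ["RunConfig", "StageError", "run_study", "stable_seed"]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def stable_seed(master: int, *parts) -> int:
    """Derive a child seed from the master seed and a stage identity."""
    key = repr((int(master),) + tuple(parts)).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of a full study run (synthetic profile)."""

    design: CohortDesign = field(default_factory=CohortDesign)
    effects: EffectModel | None = None
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    seed: int = 0
    out_dir: str | Path = "study_out"
    # raw-signal demonstration subset (full-cohort raw simulation is
    # configurable but unnecessary for the summary statistics)
    ios_groups: tuple[str, ...] = ("untreated-KO", "H")
    ios_n_trials: int = 20
    ios_shape: tuple[int, int] = (32, 32)
    ios_noise_sd: float = 0.01
    eeg_duration_s: float = 1200.0
    eeg_baseline_s: float = 300.0
    roi_fraction: float = 0.30
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "design" in raw:
            d = dict(raw["design"])
            for key in ("groups", "timepoints"):
                if key in d:
                    d[key] = tuple(d[key])
            kwargs["design"] = CohortDesign(**d)
        if "detector" in raw:
            kwargs["detector"] = DetectorConfig(**raw["detector"])
        if "effects" in raw:
            e = dict(raw["effects"])
            e["treatment_effect"] = {
                (g, int(tp)): float(v)
                for key, v in e.get("treatment_effect", {}).items()
                for g, tp in [key.rsplit("@", 1)]}
            kwargs["effects"] = EffectModel(**e)
        for key in ("seed", "out_dir", "ios_groups", "ios_n_trials",
                    "ios_shape", "ios_noise_sd", "eeg_duration_s",
                    "eeg_baseline_s", "roi_fraction", "alpha"):
            if key in raw:
                val = raw[key]
                if key in ("ios_groups", "ios_shape"):
                    val = tuple(val)
                kwargs[key] = val
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, index=index, float_format="%.12g")
    return path


def run_study(config: RunConfig) -> dict:
    """Run the full study replica; returns the result bundle.

    The bundle maps stage names to their DataFrames and includes
    ``manifest`` (also written to ``manifest.json``): configuration
    echo, per-stage seeds and SHA-256 checksums of every output file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design
    effects = config.effects or default_effect_model(design)
    master = config.seed
    results: dict = {}
    files: list[Path] = []
    seeds: dict[str, int] = {}

    # ---- stage: cohort ---------------------------------------------------
    stage = "cohort"
    try:
        seeds[stage] = stable_seed(master, stage)
        cohort = gen_cohort_outcomes(design, effects, seed=seeds[stage])
        files.append(_write(cohort, out / "cohort.csv"))
        results["cohort"] = cohort
    except Exception as exc:  # noqa: BLE001 - stage-named abort
        raise StageError(stage, exc) from exc

    # ---- stage: ios ------------------------------------------------------
    stage = "ios"
    try:
        rows = []
        for group in config.ios_groups:
            for tp in design.timepoints:
                geno = "wild-type" if group == "wild-type" else "KO"
                mean, sd = effects.baseline["ios_amplitude"][geno]
                if geno == "KO":
                    wt_mean, _ = effects.baseline["ios_amplitude"][
                        "wild-type"]
                    d = effects.treatment_effect[(group, tp)]
                    mean = mean + d * sd * np.sign(wt_mean - mean)
                s = stable_seed(master, stage, group, tp)
                trials = gen_ios_trialset(
                    n_trials=config.ios_n_trials, shape=config.ios_shape,
                    evoked_amplitude=float(mean),
                    noise_sd=config.ios_noise_sd,
                    blob_sigma_px=config.ios_shape[0] / 8.0, seed=s)
                res = analyze_trialset(trials,
                                       fraction=config.roi_fraction)
                rows.append({
                    "group": group, "timepoint": tp,
                    "true_peak_amplitude": float(mean),
                    "estimated_amplitude": res.amplitude,
                    "roi_pixels": res.roi.n_pixels,
                    "roi_jaccard_vs_truth": jaccard(
                        res.roi.mask, trials.metadata["mask"]),
                })
        ios_summary = pd.DataFrame(rows)
        files.append(_write(ios_summary, out / "ios_summary.csv"))
        results["ios"] = ios_summary
        seeds[stage] = stable_seed(master, stage)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: eeg ------------------------------------------------------
    stage = "eeg"
    try:
        demo = [("untreated-KO", [(600.0, 20.0, 5.0, 8.0),
                                  (900.0, 15.0, 7.0, 6.0)]),
                ("H", [])]
        ev_rows, bp_frames = [], []
        for group, bursts in demo:
            s = stable_seed(master, stage, group)
            n_epochs = int(config.eeg_duration_s // 30.0)
            schedule = make_state_schedule(n_epochs)
            rec = gen_eeg(config.eeg_duration_s, state_schedule=schedule,
                          seizures=bursts, seed=s)
            base = rec.data[:, :int(config.eeg_baseline_s * rec.fs)]
            cal = calibrate_threshold(base[0], config.detector, fs=rec.fs)
            events = detect_seizures(rec, cal, config.detector)
            metrics = event_metrics(events,
                                    record_duration_s=rec.duration_s)
            for ev in events:
                ev_rows.append({"group": group, "start_s": ev.start_s,
                                "end_s": ev.end_s,
                                "duration_s": ev.duration_s,
                                "peak_line_length": ev.peak_line_length,
                                "channel": ev.channel})
            table = band_power_table(rec)
            table = exclude_epochs(table, events)
            means = average_band_powers(table, schedule).reset_index()
            means.insert(0, "group", group)
            means["latency_s"] = (np.nan if metrics["latency_s"] is None
                                  else float(metrics["latency_s"]))
            means["events_per_h"] = float(metrics["frequency_per_h"])
            bp_frames.append(means)
        events_df = pd.DataFrame(
            ev_rows, columns=["group", "start_s", "end_s", "duration_s",
                              "peak_line_length", "channel"])
        band_df = pd.concat(bp_frames, ignore_index=True)
        files.append(_write(events_df, out / "eeg_events.csv"))
        files.append(_write(band_df, out / "eeg_band_means.csv"))
        results["eeg_events"] = events_df
        results["eeg_band_means"] = band_df
        seeds[stage] = stable_seed(master, stage)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: behavior -------------------------------------------------
    stage = "behavior"
    try:
        from .synthetic import gen_arm_entries

        rows = []
        alt_mean = {
            g: float(cohort.query(
                "group == @g and outcome == 'alternation_pct'")
                ["value"].mean())
            for g in design.groups}
        for group in design.groups:
            s = stable_seed(master, stage, group)
            p_alt = min(1.0, max(0.0, alt_mean[group] / 100.0))
            seq = gen_arm_entries(25, p_alternate=p_alt, seed=s)
            score = score_alternation(seq)
            rows.append({"group": group, "assay": "y-maze",
                         "n_entries": score["n_entries"],
                         "n_triads": score["n_triads"],
                         "alternation_pct": score["alternation_pct"]})
        behavior_df = pd.DataFrame(rows)
        files.append(_write(behavior_df, out / "behavior_summary.csv"))
        results["behavior"] = behavior_df
        seeds[stage] = stable_seed(master, stage)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- stage: stats ----------------------------------------------------
    stage = "stats"
    try:
        seeds[stage] = stable_seed(master, stage)
        stat_rows = []
        control = design.control_group
        for outcome in OUTCOMES:
            for tp in design.timepoints:
                sub = cohort.query(
                    "outcome == @outcome and timepoint == @tp")
                res = anova(sub, dv="value", factors=("group",))
                stat_rows.append({
                    "outcome": outcome, "timepoint": tp,
                    "test": "anova", "comparison": "group",
                    "statistic": res.statistic, "p": res.p_value,
                    "p_adj": np.nan})
                dres = dunnett(sub, control=control, dv="value",
                               seed=stable_seed(master, stage, outcome, tp))
                for _, row in dres.table.iterrows():
                    stat_rows.append({
                        "outcome": outcome, "timepoint": tp,
                        "test": "dunnett", "comparison": row["comparison"],
                        "statistic": row["statistic"], "p": np.nan,
                        "p_adj": row["p_adj"]})
        seized = cohort.query("outcome == 'spontaneous_seizure'")[
            ["animal_id", "group", "value"]].rename(
            columns={"value": "seized"})
        seized["seized"] = seized["seized"].astype(bool)
        inc = incidence_table(seized, groups=design.groups)
        for group in design.groups:
            if group == control:
                continue
            t2 = inc.loc[[control, group],
                         ["seized", "not_seized"]].to_numpy().astype(int)
            fres = fisher_exact(t2)
            stat_rows.append({
                "outcome": "spontaneous_seizure", "timepoint":
                    design.timepoints[-1], "test": "fisher",
                "comparison": f"{group} vs {control}",
                "statistic": fres.statistic, "p": fres.p_value,
                "p_adj": np.nan})
        stages = cohort.query("outcome == 'racine_stage'")
        if len(stages):
            sev = stages.assign(category=stages["value"].astype(int).map(
                lambda s: classify_racine(s)))
            sev_tab = pd.crosstab(sev["group"], sev["category"])
            results["severity"] = sev_tab
            ok = (sev_tab.to_numpy().sum(axis=1) > 0).all() \
                and (sev_tab.to_numpy().sum(axis=0) > 0).all() \
                and sev_tab.shape[0] >= 2 and sev_tab.shape[1] >= 2
            if ok:
                cres = chi_square(sev_tab.to_numpy())
                stat_rows.append({
                    "outcome": "seizure_severity",
                    "timepoint": design.timepoints[-1],
                    "test": "chi-square", "comparison": "group x category",
                    "statistic": cres.statistic, "p": cres.p_value,
                    "p_adj": np.nan})
        stats_df = pd.DataFrame(stat_rows)
        files.append(_write(stats_df, out / "stats_results.csv"))
        files.append(_write(inc.reset_index(), out / "incidence.csv"))
        results["stats"] = stats_df
        results["incidence"] = inc
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- manifest --------------------------------------------------------
    manifest = {
        "package_version": __version__,
        "master_seed": master,
        "stage_seeds": seeds,
        "design": {
            "groups": list(design.groups),
            "n_per_group": (dict(design.n_per_group)
                            if not isinstance(design.n_per_group, int)
                            else design.n_per_group),
            "timepoints": list(design.timepoints),
            "dose_mg_per_kg": dict(design.dose_mg_per_kg),
            "control_group": design.control_group,
        },
        "detector": dataclasses.asdict(config.detector),
        "outputs": {f.name: _sha256(f) for f in sorted(files)},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2,
                                        sort_keys=True))
    results["manifest"] = manifest
    results["manifest_path"] = manifest_path
    return results
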