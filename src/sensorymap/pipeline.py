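"""End-to-end orchestration: generate or load a study, run every analysis
stage, and write a report bundle (CSV/JSON tables plus a manifest with
seeds and output hashes).

Stages
------
synth      generate the synthetic study tables and masks
staircase  re-estimate thresholds from recorded staircase runs
psychofit  psychometric fits, exclusion, pTLR, JNDs, subject aggregation
magnitude  intensity-model fits and 3-/5-bin discriminability
percepts   reference amplitudes, weekly stability series
categorical modality fractions, sunburst counts, dermatome proportions
stability  threshold-charge ANOVA/Tukey, AR(1) trends, lead migration
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from sensorymap import categorical as cat
from sensorymap import magnitude as mg
from sensorymap import percepts as pc
from sensorymap import psychofit as pf
from sensorymap import stability as st
from sensorymap import staircase as sc
from sensorymap import synth

__all__ = ["StudyConfig", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("synth", "staircase", "psychofit", "magnitude", "percepts",
              "categorical", "stability")

# hardware envelope of the stimulators
AMPLITUDE_RANGE_MA = (0.0, 6.0)
FREQUENCY_RANGE_HZ = (1.0, 300.0)
PULSE_WIDTH_RANGE_US = (50.0, 1000.0)


@dataclass
class StudyConfig:
    """Pipeline configuration.

    ``out_dir`` receives the study files and the report bundle.  All
    stimulation parameters in the generated study must sit inside the
    hardware envelope (0-6 mA, 1-300 Hz, 50-1000 us).
    """

    out_dir: Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    gen: synth.StudyGenConfig = field(default_factory=synth.StudyGenConfig)
    n_ptlr_sim: int = 200
    bins: tuple[int, ...] = (3, 5)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if not (AMPLITUDE_RANGE_MA[0] < self.gen.max_amplitude_mA <= AMPLITUDE_RANGE_MA[1]):
            raise ValueError("max amplitude outside the hardware envelope")
        if not (PULSE_WIDTH_RANGE_US[0] <= self.gen.pulse_width_us <= PULSE_WIDTH_RANGE_US[1]):
            raise ValueError("pulse width outside the hardware envelope")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_staircase(tables, out, warnings):
    rows = []
    for (subject, electrode, session), grp in tables["staircase_trials"].groupby(
        ["subject", "electrode", "session"]
    ):
        grp = grp.sort_values("trial")
        rev = np.flatnonzero(grp["reversal_flag"].to_numpy())
        run = sc.StaircaseRun(
            amplitudes=grp["amplitude_mA"].to_numpy(float),
            correct=grp["correct"].to_numpy(bool),
            reversal_indices=rev,
            threshold_estimate=np.nan,
            terminated_normally=rev.size >= 5,
        )
        est = sc.estimate_threshold(run) if rev.size else np.nan
        rows.append(dict(subject=subject, electrode=electrode, session=session,
                         n_trials=len(grp), n_reversals=int(rev.size),
                         threshold_estimate_mA=est,
                         terminated_normally=run.terminated_normally,
                         short_estimate=run.short_estimate))
    df = pd.DataFrame(rows)
    df.to_csv(out / "staircase_estimates.csv", index=False)
    return {"staircase_estimates": df}


def _stage_psychofit(tables, out, warnings, seed, n_sim):
    fit_rows = []
    thresholds = []
    rng = np.random.default_rng([seed, 101])
    for (subject, electrode), grp in tables["detection_trials"].groupby(["subject", "electrode"]):
        agg = grp.groupby("amplitude_mA")["correct"].agg(["sum", "count"]).reset_index()
        data = pf.PsychometricData(agg.to_numpy(float))
        status = pf.exclusion_check(data)
        row = dict(subject=subject, electrode=electrode, task="detection",
                   included=status == "include")
        if status == "include":
            fit = pf.fit_psychometric(data)
            ptlr, info = pf.gof_ptlr(fit, data, n_sim=n_sim, rng=rng)
            row.update(alpha_mA=fit.alpha, beta_per_mA=fit.beta,
                       threshold75_mA=fit.threshold75, deviance=fit.deviance,
                       ptlr=ptlr, converged=fit.converged,
                       ptlr_flagged=info["flagged"])
            if fit.converged and ptlr >= 0.05:
                thresholds.append((subject, electrode, fit.threshold75))
        fit_rows.append(row)

    jnd_rows = []
    for (subject, electrode, std), grp in tables["jnd_trials"].groupby(
        ["subject", "electrode", "standard_mA"]
    ):
        agg = grp.groupby("delta_mA")["correct"].agg(["sum", "count"]).reset_index()
        data = pf.PsychometricData(agg.to_numpy(float), task_kind="jnd", standard_amplitude=std)
        status = pf.exclusion_check(data)
        row = dict(subject=subject, electrode=electrode, standard_mA=std,
                   included=status == "include")
        if status == "include":
            jnd, fit = pf.estimate_jnd(data)
            row.update(jnd_mA=jnd, jnd_uA=1000 * jnd, beta_per_mA=fit.beta,
                       deviance=fit.deviance, converged=fit.converged)
        jnd_rows.append(row)

    fits = pd.DataFrame(fit_rows)
    jnds = pd.DataFrame(jnd_rows)
    agg = pf.aggregate_thresholds(thresholds) if thresholds else pd.DataFrame()
    fits.to_csv(out / "detection_fits.csv", index=False)
    jnds.to_csv(out / "jnd_fits.csv", index=False)
    agg.to_csv(out / "subject_thresholds.csv", index=False)
    return {"detection_fits": fits, "jnd_fits": jnds, "subject_thresholds": agg}


def _stage_magnitude(tables, out, warnings, bins):
    sessions, fit_rows = [], []
    for (subject, electrode), grp in tables["magnitude_trials"].groupby(["subject", "electrode"]):
        sess = mg.MagEstSession(electrode, grp[["block", "amplitude_mA", "rating"]])
        try:
            x, y = mg.preprocess_magnitude(sess)
        except ValueError as e:
            warnings.append(f"magnitude: {e}")
            continue
        sessions.append((electrode, x, y))
        fit = mg.fit_intensity_models(x, y)
        fit_rows.append(dict(subject=subject, electrode=electrode,
                             slope_int=fit.slope_int, intercept=fit.intercept,
                             p_int=fit.p_int, adj_r2_linear=fit.adj_r2_linear,
                             adj_r2_log=fit.adj_r2_log, adj_r2_sigmoid=fit.adj_r2_sigmoid,
                             best_model=fit.best_model))
    fits = pd.DataFrame(fit_rows)
    fits.to_csv(out / "intensity_fits.csv", index=False)
    result = {"intensity_fits": fits}
    for k in bins:
        res = mg.bin_discriminability(sessions, k=k)
        conf = pd.DataFrame(res["confusion"],
                            index=[f"amp_bin_{i + 1}" for i in range(k)],
                            columns=[f"rating_bin_{j + 1}" for j in range(k)])
        conf.to_csv(out / f"confusion_{k}bin.csv")
        summary = pd.DataFrame({
            "bin": np.arange(1, k + 1),
            "per_bin_accuracy": res["per_bin_accuracy"],
        })
        summary["overall_accuracy"] = res["overall_accuracy"]
        summary.to_csv(out / f"binning_{k}bin.csv", index=False)
        result[f"binning_{k}"] = res
    return result


def _stage_percepts(study, out, warnings):
    rows = []
    by_el: dict[tuple[str, str], list] = {}
    for m in study.masks:
        by_el.setdefault((m.subject, m.electrode), []).append(m)
    for (subject, electrode), masks in sorted(by_el.items()):
        try:
            series = pc.weekly_stability(masks)
        except ValueError as e:
            warnings.append(f"percepts {electrode}: {e}")
            continue
        for i, w in enumerate(series.weeks):
            rows.append(dict(
                subject=subject, electrode=electrode, week=int(w),
                centroid_x_mm=series.mean_centroid_mm[i, 0],
                centroid_y_mm=series.mean_centroid_mm[i, 1],
                area_cm2=series.mean_area_cm2[i],
                migration_mm=series.migration_mm[i - 1] if i else np.nan,
                area_change_cm2=series.area_change_cm2[i - 1] if i else np.nan,
            ))
    df = pd.DataFrame(rows)
    df.to_csv(out / "percept_stability.csv", index=False)
    med = (df.dropna(subset=["migration_mm"])
             .groupby("week")[["migration_mm"]].median()
             .join(df.dropna(subset=["area_change_cm2"])
                     .assign(area_change_abs_cm2=lambda d: d["area_change_cm2"].abs())
                     .groupby("week")[["area_change_cm2", "area_change_abs_cm2"]].median()))
    med.to_csv(out / "percept_stability_medians.csv")
    return {"percept_stability": df, "percept_stability_medians": med}


def _stage_categorical(study, tables, out, warnings):
    reports_by_subject: dict[str, list] = {}
    report_rows = tables["reports"]
    for _, r in report_rows.iterrows():
        rep = cat.PerceptReport(descriptors=frozenset(r["descriptors"].split("|")),
                                laterality=r["laterality"])
        reports_by_subject.setdefault(r["subject"], []).append(rep)
    modality_rows, sunbursts = [], {}
    for subject, reps in sorted(reports_by_subject.items()):
        counts = cat.sunburst_counts(reps)
        sunbursts[subject] = counts
        modality_rows.append(dict(subject=subject, n_reports=counts["n_reports"],
                                  **{f"frac_{k}": v for k, v in counts["fractions"].items()}))
    pd.DataFrame(modality_rows).to_csv(out / "modality_summary.csv", index=False)
    (out / "sunburst_counts.json").write_text(json.dumps(sunbursts, indent=1))

    # region assignment from week-1 masks, then dermatome proportions
    region_rows = []
    for m in study.masks:
        if m.week == 1 and m.repetition == 1:
            region_rows.append(dict(electrode=m.electrode,
                                    region=cat.assign_body_region(m)))
    regions = pd.DataFrame(region_rows)
    props = cat.dermatome_proportions(tables["electrodes"], regions)
    props.to_csv(out / "dermatome_proportions.csv")
    return {"modality_summary": pd.DataFrame(modality_rows),
            "dermatome_proportions": props, "sunbursts": sunbursts}


def _stage_stability(tables, out, warnings):
    anova_rows, tukey_frames = [], []
    for subject, grp in tables["threshold_charge"].groupby("subject"):
        groups = {w: g["charge_nC"].to_numpy(float) for w, g in grp.groupby("week")}
        try:
            res = st.anova_by_week(groups)
        except ValueError as e:
            warnings.append(f"stability {subject}: {e}")
            continue
        anova_rows.append(dict(subject=subject, **{k: v for k, v in res.items()
                                                   if k != "dropped_weeks"}))
        tk = st.tukey_pairs(groups)
        tk.insert(0, "subject", subject)
        tukey_frames.append(tk)
    anova = pd.DataFrame(anova_rows)
    tukey = pd.concat(tukey_frames, ignore_index=True) if tukey_frames else pd.DataFrame()
    anova.to_csv(out / "charge_anova.csv", index=False)
    tukey.to_csv(out / "charge_tukey.csv", index=False)

    mig_frames = []
    for (subject, lead), grp in tables["lead_tips"].groupby(["subject", "lead"]):
        grp = grp.sort_values("week")
        track = st.LeadTipTrack(weeks=grp["week"].to_numpy(),
                                tips_px=grp[["tip_x_px", "tip_y_px"]].to_numpy(float),
                                mm_per_px=float(grp["mm_per_px"].iloc[0]))
        df = st.rostrocaudal_migration(track)
        df.insert(0, "lead", lead)
        df.insert(0, "subject", subject)
        mig_frames.append(df)
    mig = pd.concat(mig_frames, ignore_index=True)
    med = mig.groupby(["subject", "week"])["migration_mm"].median().reset_index()
    med = med.rename(columns={"migration_mm": "median_migration_mm"})
    mig.to_csv(out / "lead_migration.csv", index=False)
    med.to_csv(out / "lead_migration_medians.csv", index=False)
    return {"charge_anova": anova, "charge_tukey": tukey,
            "lead_migration": mig, "lead_migration_medians": med}


def run_pipeline(config: StudyConfig) -> dict:
    """Run the requested stages end to end and write the report bundle.

    Returns a dict of in-memory stage outputs; files land under
    ``config.out_dir`` with a ``manifest.json`` recording the seed, the
    package version, and a SHA-256 per output file.
    """
    from sensorymap import __version__

    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    results: dict = {}

    study = synth.generate_study(config.gen, config.seed, out_dir=out / "study")
    results["study"] = study
    tables = study.tables

    if "staircase" in config.stages:
        results.update(_stage_staircase(tables, out, warnings))
    if "psychofit" in config.stages:
        results.update(_stage_psychofit(tables, out, warnings, config.seed, config.n_ptlr_sim))
    if "magnitude" in config.stages:
        results.update(_stage_magnitude(tables, out, warnings, config.bins))
    if "percepts" in config.stages:
        results.update(_stage_percepts(study, out, warnings))
    if "categorical" in config.stages:
        results.update(_stage_categorical(study, tables, out, warnings))
    if "stability" in config.stages:
        results.update(_stage_stability(tables, out, warnings))

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "warnings": warnings,
        "outputs": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results["manifest"] = manifest
    results["warnings"] = warnings
    return results
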