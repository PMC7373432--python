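"""Electrode stability: threshold-charge ANOVA across weeks and lead migration.

Tests, per subject, whether weekly threshold charge (first-phase amplitude x
pulse width, nC) differs across weeks with a one-way ANOVA and Tukey HSD on
week pairs (the generator injects no systematic week effect, so F should be
unremarkable), and summarizes rostro-caudal lead-tip migration per week with
per-subject medians (caudal positive; the generator settles leads caudally,
fastest in week 1).

Reads results/study/; writes charge_anova.csv, charge_tukey.csv,
lead_migration.csv and lead_migration_medians.csv under results/.
"""

from pathlib import Path

import pandas as pd

from sensorymap import stability as st

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"
OUT = ROOT / "results"

if __name__ == "__main__":
    charge = pd.read_csv(STUDY / "threshold_charge.csv")
    anova_rows, tukey_frames = [], []
    for subj, grp in charge.groupby("subject"):
        groups = {w: g["charge_nC"].to_numpy(float) for w, g in grp.groupby("week")}
        res = st.anova_by_week(groups)
        anova_rows.append(dict(subject=subj, F=res["F"], p=res["p"],
                               df_between=res["df_between"], df_within=res["df_within"]))
        tk = st.tukey_pairs(groups)
        tk.insert(0, "subject", subj)
        tukey_frames.append(tk)
    anova = pd.DataFrame(anova_rows)
    anova.to_csv(OUT / "charge_anova.csv", index=False)
    pd.concat(tukey_frames, ignore_index=True).to_csv(OUT / "charge_tukey.csv", index=False)
    print("threshold-charge stability (one-way ANOVA per subject):")
    print(anova.round(3).to_string(index=False))

    tips = pd.read_csv(STUDY / "lead_tips.csv")
    frames = []
    for (subj, lead), grp in tips.groupby(["subject", "lead"]):
        track = st.LeadTipTrack(weeks=grp["week"].to_numpy(),
                                tips_px=grp[["tip_x_px", "tip_y_px"]].to_numpy(float),
                                mm_per_px=float(grp["mm_per_px"].iloc[0]))
        mg = st.rostrocaudal_migration(track)
        mg.insert(0, "lead", lead)
        mg.insert(0, "subject", subj)
        frames.append(mg)
    mig = pd.concat(frames, ignore_index=True)
    mig.to_csv(OUT / "lead_migration.csv", index=False)
    med = (mig.groupby(["subject", "week"])["migration_mm"].median()
              .reset_index().rename(columns={"migration_mm": "median_migration_mm"}))
    med.to_csv(OUT / "lead_migration_medians.csv", index=False)
    print("\nmedian weekly rostro-caudal migration per subject (mm, caudal positive):")
    print(med.round(2).to_string(index=False))
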