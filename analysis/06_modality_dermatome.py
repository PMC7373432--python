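"""Percept quality: modality fractions, sunburst counts, dermatome map.

Classifies every descriptor report as paresthetic, mixed, or naturalistic
(paresthetic set: electrical tingle, pins-and-needles, sharp, tickle),
builds the hierarchical tingle -> mechanical -> movement count table per
subject, assigns each electrode's percept to the body segment holding its
maximal area, and tabulates, per region, the distribution of evoking
electrodes over spinal levels.

Reads results/study/; writes modality_summary.csv, sunburst_counts.json and
dermatome_proportions.csv under results/.
"""

import json
from pathlib import Path

import pandas as pd

from sensorymap import categorical as cat
from sensorymap import synth

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"
OUT = ROOT / "results"
SEED = 1

if __name__ == "__main__":
    reports = pd.read_csv(STUDY / "reports.csv")
    electrodes = pd.read_csv(STUDY / "electrodes.csv")

    rows, sunbursts = [], {}
    for subj, grp in reports.groupby("subject"):
        reps = [cat.PerceptReport(descriptors=frozenset(d.split("|")))
                for d in grp["descriptors"]]
        counts = cat.sunburst_counts(reps)
        sunbursts[subj] = counts
        rows.append(dict(subject=subj, n_reports=counts["n_reports"],
                         **{f"frac_{k}": round(v, 3) for k, v in counts["fractions"].items()}))
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "modality_summary.csv", index=False)
    (OUT / "sunburst_counts.json").write_text(json.dumps(sunbursts, indent=1))
    print("modality fractions per subject (S3 is naturalistic-dominant by design):")
    print(summary.to_string(index=False))

    # regions from the week-1 drawings (regenerated in memory, same seed as 01)
    study = synth.generate_study(synth.StudyGenConfig(write_masks=False), seed=SEED)
    regions = pd.DataFrame([
        dict(electrode=m.electrode, region=cat.assign_body_region(m))
        for m in study.masks if m.week == 1 and m.repetition == 1
    ])
    props = cat.dermatome_proportions(electrodes, regions)
    props.to_csv(OUT / "dermatome_proportions.csv")
    evoked = props.columns[props.notna().any()].tolist()
    print(f"\ndermatome matrix: {len(evoked)} regions evoked "
          f"across levels {list(props.index)}; columns sum to 1 over levels")
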