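"""Generate the synthetic study that all downstream analyses consume.

Simulates four subjects with (2, 5, 14, 14) electrodes and subject-level
mean detection thresholds of (3.75, 1.25, 1.58, 1.94) mA, four weekly
sessions each (two for subject 2): adaptive staircases, constant-stimuli
detection and JND trials, magnitude-estimation blocks, weekly percept
drawings with 10 mm/week injected centroid drift and -5%/week area change,
descriptor reports, threshold-charge records, and lead-tip tracks.

Writes CSV tables and ground_truth.json under results/study/.
"""

from pathlib import Path

from sensorymap import synth

OUT = Path(__file__).resolve().parents[1] / "results" / "study"
SEED = 1

if __name__ == "__main__":
    cfg = synth.StudyGenConfig(write_masks=False)   # masks kept in memory downstream
    study = synth.generate_study(cfg, seed=SEED, out_dir=OUT)
    n_el = len(study.tables["electrodes"])
    print(f"wrote synthetic study to {OUT}")
    print(f"  {n_el} electrodes across {cfg.n_subjects} subjects")
    for name, df in study.tables.items():
        print(f"  {name}: {len(df)} rows")
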