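"""Detection thresholds and just-noticeable differences from the synthetic study.

Fits the cumulative-normal psychometric function (guess rate 0.5, lapse 0)
to each electrode's constant-stimuli 2AFC data, applies the accuracy-band
exclusion rule (<0.6 everywhere or >0.9 everywhere), screens fits with the
parametric-bootstrap pTLR (discard < 0.05), and aggregates 75%-accuracy
thresholds per subject.  JNDs are fit the same way on |test - standard|
at the 2.5 and 4.0 mA standards, where the generator's Weber-like ground
truth is a 4% JND of the standard.

Reads results/study/; writes detection_fits.csv, subject_thresholds.csv,
jnd_fits.csv under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from sensorymap import psychofit as pf

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"
OUT = ROOT / "results"
SEED = 1

if __name__ == "__main__":
    det = pd.read_csv(STUDY / "detection_trials.csv")
    rng = np.random.default_rng([SEED, 101])
    rows, thresholds = [], []
    for (subj, el), grp in det.groupby(["subject", "electrode"]):
        agg = grp.groupby("amplitude_mA")["correct"].agg(["sum", "count"]).reset_index()
        data = pf.PsychometricData(agg.to_numpy(float))
        if pf.exclusion_check(data) == "exclude":
            rows.append(dict(subject=subj, electrode=el, included=False))
            continue
        fit = pf.fit_psychometric(data)
        ptlr, _ = pf.gof_ptlr(fit, data, n_sim=200, rng=rng)
        rows.append(dict(subject=subj, electrode=el, included=True,
                         alpha_mA=fit.alpha, beta_per_mA=fit.beta,
                         threshold75_mA=fit.threshold75, deviance=fit.deviance,
                         ptlr=ptlr))
        if fit.converged and ptlr >= 0.05:
            thresholds.append((subj, el, fit.threshold75))
    fits = pd.DataFrame(rows)
    fits.to_csv(OUT / "detection_fits.csv", index=False)
    agg = pf.aggregate_thresholds(thresholds)
    agg.to_csv(OUT / "subject_thresholds.csv", index=False)
    print("per-subject detection thresholds (mA):")
    print(agg.to_string(index=False))

    jnd = pd.read_csv(STUDY / "jnd_trials.csv")
    jrows = []
    for (subj, el, std), grp in jnd.groupby(["subject", "electrode", "standard_mA"]):
        a = grp.groupby("delta_mA")["correct"].agg(["sum", "count"]).reset_index()
        data = pf.PsychometricData(a.to_numpy(float), task_kind="jnd", standard_amplitude=std)
        if pf.exclusion_check(data) == "exclude":
            continue
        j, fit = pf.estimate_jnd(data)
        jrows.append(dict(subject=subj, electrode=el, standard_mA=std,
                          jnd_uA=1000 * j, beta_per_mA=fit.beta))
    jfits = pd.DataFrame(jrows)
    jfits.to_csv(OUT / "jnd_fits.csv", index=False)
    summary = jfits.groupby(["subject", "standard_mA"])["jnd_uA"].agg(["mean", "std", "count"])
    print("\nmean JND (uA) by subject and standard amplitude "
          "(ground truth: 100 uA at 2.5 mA, 160 uA at 4.0 mA):")
    print(summary.round(1).to_string())
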