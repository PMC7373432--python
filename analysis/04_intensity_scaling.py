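"""Magnitude estimation: is perceived intensity linear in amplitude, and how
many intensity levels are discriminable?

Preprocesses each electrode's magnitude-estimation session (drop the
familiarization block, normalize ratings to their mean), compares linear vs
logarithmic vs logistic amplitude-intensity fits by adjusted R^2, and runs
the binned discriminability analysis at k = 3 and 5 (amplitudes and ratings
max-normalized, equal-width bins, accuracy = matching bin fraction pooled
over all trials).

Reads results/study/; writes intensity_fits.csv, binning_{3,5}bin.csv and
confusion_{3,5}bin.csv under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from sensorymap import magnitude as mg

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "results" / "study"
OUT = ROOT / "results"

if __name__ == "__main__":
    trials = pd.read_csv(STUDY / "magnitude_trials.csv")
    sessions, rows = [], []
    for (subj, el), grp in trials.groupby(["subject", "electrode"]):
        sess = mg.MagEstSession(el, grp[["block", "amplitude_mA", "rating"]])
        x, y = mg.preprocess_magnitude(sess)
        sessions.append((el, x, y))
        fit = mg.fit_intensity_models(x, y)
        rows.append(dict(subject=subj, electrode=el, slope_int=fit.slope_int,
                         p_int=fit.p_int, adj_r2_linear=fit.adj_r2_linear,
                         adj_r2_log=fit.adj_r2_log, adj_r2_sigmoid=fit.adj_r2_sigmoid,
                         best_model=fit.best_model))
    fits = pd.DataFrame(rows)
    fits.to_csv(OUT / "intensity_fits.csv", index=False)
    n_lin = (fits["best_model"] == "linear").sum()
    print(f"{n_lin}/{len(fits)} electrodes best described by a linear "
          f"amplitude-intensity relation; "
          f"{(fits['p_int'] < 0.01).sum()}/{len(fits)} with p_int < 0.01")
    print(f"median normalized-intensity slope: {fits['slope_int'].median():.2f} per mA")

    for k in (3, 5):
        res = mg.bin_discriminability(sessions, k=k)
        pd.DataFrame(res["confusion"]).to_csv(OUT / f"confusion_{k}bin.csv")
        pd.DataFrame({"bin": np.arange(1, k + 1),
                      "per_bin_accuracy": res["per_bin_accuracy"],
                      "overall_accuracy": res["overall_accuracy"]}
                     ).to_csv(OUT / f"binning_{k}bin.csv", index=False)
        per_bin = ", ".join(f"{a:.0%}" for a in res["per_bin_accuracy"])
        print(f"{k}-target discriminability: overall {res['overall_accuracy']:.0%} "
              f"(per amplitude bin: {per_bin})")
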