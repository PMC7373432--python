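"""Free magnitude-estimation analysis: preprocessing, intensity-amplitude
model comparison, and binned discriminability.

Subjects rate perceived intensity on an open numerical scale (0 = nothing
felt) while stimulation amplitude varies randomly within blocks.  The first
block is a familiarization pass and is discarded; the remaining ratings are
normalized to their mean (zeros included) so that electrodes and sessions can
be compared.  The amplitude-intensity relation is then fit with a line, a
logarithm, and a 3-parameter logistic and compared by adjusted R^2; the
binned analysis asks how reliably k = 3 or 5 intensity targets could be
discriminated from the ratings alone.
"""

from __future__ import annotations

import warnings as warns
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit

__all__ = [
    "MagEstSession",
    "IntensityFit",
    "preprocess_magnitude",
    "fit_intensity_models",
    "bin_discriminability",
    "bin_index",
]


@dataclass
class MagEstSession:
    """Raw magnitude-estimation trials for one electrode.

    ``trials`` has columns (block, amplitude_mA, rating); block numbering
    starts at 1 and block 1 is the discarded familiarization block.
    """

    electrode: str
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"block", "amplitude_mA", "rating"}
        if not need.issubset(self.trials.columns):
            raise ValueError(f"trials must have columns {sorted(need)}")
        if 1 not in set(self.trials["block"]):
            raise ValueError("block 1 (familiarization) missing")
        if (self.trials["rating"] < 0).any():
            raise ValueError("ratings cannot be negative")


@dataclass
class IntensityFit:
    slope_int: float        # normalized intensity per mA
    intercept: float
    p_int: float            # two-sided p for zero slope (F-test)
    adj_r2_linear: float
    adj_r2_log: float | None
    adj_r2_sigmoid: float | None
    best_model: str
    warnings: list[str] = field(default_factory=list)


def preprocess_magnitude(session: MagEstSession) -> tuple[np.ndarray, np.ndarray]:
    """Drop block 1 and normalize the remaining ratings to their mean.

    Zero ("not perceived") ratings are included in the mean, so the output
    mean is exactly 1 whenever any nonzero rating exists.  All-zero sessions
    are flagged by raising, since their normalization is undefined.
    """
    kept = session.trials[session.trials["block"] != 1]
    if kept.empty:
        raise ValueError("no blocks beyond the familiarization block")
    ratings = kept["rating"].to_numpy(dtype=float)
    mean = ratings.mean()
    if mean == 0:
        raise ValueError(f"all ratings zero for {session.electrode}; normalization undefined")
    return kept["amplitude_mA"].to_numpy(dtype=float), ratings / mean


def _adj_r2(y, yhat, n_params: int) -> float:
    y = np.asarray(y, float)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n = y.size
    if ss_tot == 0 or n - n_params <= 0:
        return np.nan
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params)


def fit_intensity_models(x, y) -> IntensityFit:
    """Fit linear, logarithmic, and logistic intensity-amplitude models.

    The linear fit supplies the reported slope (``slope_int``) and its
    two-sided F-test p-value for zero slope; the three models are compared
    by adjusted R^2 (each penalized by its own parameter count) and
    ``best_model`` is the argmax, with the linear model winning ties.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct amplitudes")
    warnings: list[str] = []

    ols = sm.OLS(y, sm.add_constant(x)).fit()
    slope, intercept = float(ols.params[1]), float(ols.params[0])
    p_int = float(ols.f_pvalue) if np.isfinite(ols.f_pvalue) else 1.0
    adj_lin = _adj_r2(y, ols.fittedvalues, 2)

    adj_log: float | None = None
    if np.all(x > 0):
        ols_log = sm.OLS(y, sm.add_constant(np.log(x))).fit()
        adj_log = _adj_r2(y, ols_log.fittedvalues, 2)
    else:
        warnings.append("non-positive amplitudes; logarithmic fit skipped")

    def logistic(xv, L, k, x0):
        return L / (1.0 + np.exp(-k * (xv - x0)))

    adj_sig: float | None = None
    try:
        span = max(np.ptp(x), 1e-6)
        p0 = [max(y.max(), 1e-6), 4.0 / span, float(np.median(x))]
        with np.errstate(over="ignore"), warns.catch_warnings():
            warns.simplefilter("ignore")
            popt, _ = curve_fit(logistic, x, y, p0=p0, maxfev=5000)
        adj_sig = _adj_r2(y, logistic(x, *popt), 3)
    except Exception:
        warnings.append("logistic fit did not converge")

    candidates = {"linear": adj_lin}
    if adj_log is not None and np.isfinite(adj_log):
        candidates["logarithmic"] = adj_log
    if adj_sig is not None and np.isfinite(adj_sig):
        candidates["sigmoid"] = adj_sig
    best_val = max(candidates.values())
    best = "linear" if candidates["linear"] >= best_val - 1e-12 else max(
        candidates, key=candidates.get
    )
    return IntensityFit(slope, intercept, p_int, adj_lin, adj_log, adj_sig, best, warnings)


def bin_index(v: np.ndarray, k: int) -> np.ndarray:
    """Equal-width bin index on [0, 1]: [i/k, (i+1)/k), last bin closed at 1."""
    v = np.asarray(v, float)
    if np.any(v < 0) or np.any(v > 1):
        raise ValueError("values must be normalized to [0, 1]")
    return np.minimum(np.floor(v * k).astype(int), k - 1)


def bin_discriminability(
    sessions: list[tuple[str, np.ndarray, np.ndarray]],
    k: int = 3,
    pooling: str = "trials",
):
    """Binned intensity-discriminability analysis over preprocessed sessions.

    Each session is (electrode, amplitudes, ratings) as produced by
    :func:`preprocess_magnitude`.  Per electrode, amplitudes are normalized
    to the electrode's maximum amplitude and ratings to its maximum rating
    (over all its sessions); both are partitioned into ``k`` equal-width
    bins on [0, 1].  Accuracy is the fraction of trials whose rating bin
    matches the amplitude bin.

    Returns a dict with overall accuracy, per-amplitude-bin accuracy, and
    the k-by-k confusion table (rows = amplitude bin, cols = rating bin).
    ``pooling='trials'`` pools all trials across electrodes and subjects;
    ``'electrodes'`` averages per-electrode accuracies.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not sessions:
        raise ValueError("no sessions")
    by_el: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for el, x, y in sessions:
        by_el.setdefault(el, []).append((np.asarray(x, float), np.asarray(y, float)))

    confusion = np.zeros((k, k), dtype=int)
    per_el_acc = {}
    skipped = []
    for el, parts in by_el.items():
        x = np.concatenate([p[0] for p in parts])
        y = np.concatenate([p[1] for p in parts])
        if y.max() == 0:
            skipped.append(el)
            continue
        bx = bin_index(x / x.max(), k)
        by = bin_index(y / y.max(), k)
        for i, j in zip(bx, by):
            confusion[i, j] += 1
        per_el_acc[el] = float(np.mean(bx == by))

    total = confusion.sum()
    if total == 0:
        raise ValueError("no usable trials (all electrodes had zero max rating)")
    if pooling == "trials":
        overall = float(np.trace(confusion) / total)
    elif pooling == "electrodes":
        overall = float(np.mean(list(per_el_acc.values())))
    else:
        raise ValueError("pooling must be 'trials' or 'electrodes'")
    row_sums = confusion.sum(axis=1)
    with np.errstate(invalid="ignore"):
        per_bin = np.where(row_sums > 0, np.diag(confusion) / row_sums, np.nan)
    return {
        "k": k,
        "overall_accuracy": overall,
        "per_bin_accuracy": per_bin,
        "confusion": confusion,
        "per_electrode_accuracy": per_el_acc,
        "skipped_electrodes": skipped,
    }
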