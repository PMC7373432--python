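"""Stability statistics and lead-migration geometry.

Covers the threshold-charge bookkeeping (first-phase amplitude times pulse
width, in nC), the week-wise one-way ANOVA with Tukey HSD follow-up, the
AR(1)-error trend regression used for percept area/centroid time series, and
the downstream arithmetic of X-ray lead tracking: least-squares affine
alignment from landmark pairs, contact-based scale calibration (SCS contacts
are 3 mm long), and rostro-caudal tip migration (caudal positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.stattools import durbin_watson

__all__ = [
    "ThresholdChargeRecord",
    "LeadTipTrack",
    "threshold_charge",
    "anova_by_week",
    "tukey_pairs",
    "ar1_regression",
    "affine_from_landmarks",
    "contact_scale",
    "rostrocaudal_migration",
]

CONTACT_LENGTH_MM = 3.0


@dataclass
class ThresholdChargeRecord:
    electrode: str
    week: int
    amplitude_mA: float
    pulse_width_us: float

    def __post_init__(self) -> None:
        if self.amplitude_mA <= 0 or self.pulse_width_us <= 0:
            raise ValueError("amplitude and pulse width must be positive")

    @property
    def charge_nC(self) -> float:
        return threshold_charge(self.amplitude_mA, self.pulse_width_us)


def threshold_charge(amplitude_mA: float, pulse_width_us: float) -> float:
    """First-phase charge in nC (mA x us = nC)."""
    if amplitude_mA <= 0 or pulse_width_us <= 0:
        raise ValueError("amplitude and pulse width must be positive")
    return float(amplitude_mA) * float(pulse_width_us)


def _clean_groups(groups: dict) -> tuple[dict, list]:
    kept, dropped = {}, []
    for week, vals in groups.items():
        v = np.asarray(vals, float)
        if v.size >= 2:
            kept[week] = v
        else:
            dropped.append(week)
    return kept, dropped


def anova_by_week(groups: dict) -> dict:
    """Classical one-way ANOVA across weeks.

    ``groups`` maps week -> array of values (e.g. per-electrode threshold
    charges).  Weeks with fewer than 2 values are dropped with a warning
    entry.  Returns F, p, degrees of freedom, and the dropped weeks.
    """
    kept, dropped = _clean_groups(groups)
    if len(kept) < 2:
        raise ValueError("need at least two weeks with >= 2 values each")
    arrays = [kept[w] for w in sorted(kept)]
    f, p = stats.f_oneway(*arrays)
    k = len(arrays)
    n = sum(a.size for a in arrays)
    return {"F": float(f), "p": float(p), "df_between": k - 1, "df_within": n - k,
            "dropped_weeks": dropped}


def tukey_pairs(groups: dict) -> pd.DataFrame:
    """Tukey HSD on all week pairs (Tukey-Kramer for unbalanced weeks).

    Returns a DataFrame with one row per week pair: mean difference and the
    studentized-range adjusted p-value.
    """
    kept, _ = _clean_groups(groups)
    weeks = sorted(kept)
    if len(weeks) < 2:
        raise ValueError("need at least two weeks")
    res = stats.tukey_hsd(*[kept[w] for w in weeks])
    rows = []
    for i, wi in enumerate(weeks):
        for j, wj in enumerate(weeks):
            if i < j:
                rows.append(dict(week_a=wi, week_b=wj,
                                 mean_diff=float(kept[wi].mean() - kept[wj].mean()),
                                 p_adj=float(res.pvalue[i, j])))
    return pd.DataFrame(rows)


def ar1_regression(y, t=None) -> dict:
    """Linear trend regression with AR(1) errors (iterated feasible GLS).

    Fits y = b0 + beta_t * t with errors e_i = rho * e_{i-1} + u_i via
    statsmodels GLSAR with iterative Cochrane-Orcutt updates.  Returns the
    trend coefficient, its two-sided p-value, the estimated error
    autocorrelation, and the Durbin-Watson statistic of the OLS residuals
    as a first-order autocorrelation diagnostic.  |rho| >= 1 is flagged
    non-stationary.
    """
    y = np.asarray(y, float)
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 time points")
    t = np.arange(n, dtype=float) if t is None else np.asarray(t, float)
    X = sm.add_constant(t)

    ols = sm.OLS(y, X).fit()
    dw = float(durbin_watson(ols.resid))
    model = sm.GLSAR(y, X, rho=1)
    res = model.iterative_fit(maxiter=50, rtol=1e-8)
    rho = float(np.atleast_1d(model.rho)[0])
    return {
        "beta_t": float(res.params[1]),
        "intercept": float(res.params[0]),
        "p": float(res.pvalues[1]),
        "rho": rho,
        "nonstationary": bool(abs(rho) >= 1.0),
        "durbin_watson": dw,
        "beta_t_ols": float(ols.params[1]),
    }


def affine_from_landmarks(source, target) -> dict:
    """Least-squares 2D affine transform mapping source to target landmarks.

    ``source`` and ``target`` are (n, 2) pixel coordinates with n >= 3
    non-collinear points.  Returns the 2x2 matrix ``A``, translation ``b``
    (target ~ source @ A.T + b), and the residual RMS.
    """
    src = np.asarray(source, float)
    tgt = np.asarray(target, float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 2 or src.shape[0] < 3:
        raise ValueError("need matching (n>=3, 2) landmark arrays")
    design = np.column_stack([src, np.ones(src.shape[0])])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("landmarks are collinear; affine transform is rank-deficient")
    coef, *_ = np.linalg.lstsq(design, tgt, rcond=None)   # (3, 2)
    A = coef[:2].T
    b = coef[2]
    resid = design @ coef - tgt
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return {"A": A, "b": b, "residual_rms": rms}


def apply_affine(transform: dict, points) -> np.ndarray:
    pts = np.asarray(points, float)
    return pts @ transform["A"].T + transform["b"]


def contact_scale(p0, p1, contact_length_mm: float = CONTACT_LENGTH_MM) -> float:
    """mm-per-pixel scale from the endpoints of one imaged SCS contact."""
    d = float(np.linalg.norm(np.asarray(p1, float) - np.asarray(p0, float)))
    if d == 0:
        raise ValueError("contact endpoints coincide")
    return contact_length_mm / d


@dataclass
class LeadTipTrack:
    """Weekly rostral-tip coordinates of one lead in the aligned image frame.

    ``axis`` is the unit image-frame direction pointing caudally, so
    projections onto it are positive for caudal migration.
    """

    weeks: np.ndarray
    tips_px: np.ndarray          # (n_weeks, 2)
    mm_per_px: float
    axis: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.weeks = np.asarray(self.weeks, int)
        self.tips_px = np.asarray(self.tips_px, float)
        if self.mm_per_px <= 0:
            raise ValueError("scale must be positive")
        a = np.asarray(self.axis, float)
        n = np.linalg.norm(a)
        if n == 0:
            raise ValueError("axis must be nonzero")
        self.axis = tuple(a / n)
        order = np.argsort(self.weeks)
        self.weeks = self.weeks[order]
        self.tips_px = self.tips_px[order]


def rostrocaudal_migration(track: LeadTipTrack) -> pd.DataFrame:
    """Signed week-to-week tip migration along the rostro-caudal axis, mm.

    Positive values are caudal.  Missing weeks leave a gap flag on the
    spanning pair rather than interpolating.
    """
    if track.weeks.size < 2:
        raise ValueError("need at least two weeks of tip coordinates")
    disp = np.diff(track.tips_px, axis=0) @ np.asarray(track.axis)
    rows = []
    for i in range(track.weeks.size - 1):
        rows.append(dict(week=int(track.weeks[i + 1]),
                         migration_mm=float(disp[i] * track.mm_per_px),
                         gap=bool(track.weeks[i + 1] - track.weeks[i] != 1)))
    return pd.DataFrame(rows)


def subject_median_migration(tracks: dict[str, LeadTipTrack]) -> pd.DataFrame:
    """Per-week median migration across a subject's leads."""
    frames = []
    for lead, tr in tracks.items():
        df = rostrocaudal_migration(tr)
        df["lead"] = lead
        frames.append(df)
    allw = pd.concat(frames, ignore_index=True)
    med = allw.groupby("week")["migration_mm"].median().reset_index()
    med = med.rename(columns={"migration_mm": "median_migration_mm"})
    return med
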