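"""Maximum-likelihood cumulative-normal psychometric fitting for 2AFC tasks.

The observer model is

    Psi(x) = gamma + (1 - gamma - lam) * Phi(beta * (x - alpha))

with guess rate ``gamma`` (0.5 for two-alternative forced choice), lapse rate
``lam`` (held at 0), location ``alpha`` (mA) and slope ``beta = 1/sigma``
(per mA).  Detection thresholds and just-noticeable differences are both read
off the fitted curve at the 75% accuracy level; with gamma=0.5 and lam=0 that
level is exactly ``alpha``.

Goodness of fit uses a parametric bootstrap of the deviance (the transformed
likelihood ratio against the saturated model): pTLR is the fraction of
simulated deviances at least as large as the observed one, so values near 0
flag a model that fits worse than sampling noise allows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

__all__ = [
    "PsychometricData",
    "PsychometricFit",
    "psi",
    "fit_psychometric",
    "threshold_at",
    "estimate_jnd",
    "exclusion_check",
    "gof_ptlr",
    "aggregate_thresholds",
]

_EPS = 1e-12


def psi(
    x,
    alpha: float,
    beta: float,
    gamma: float = 0.5,
    lam: float = 0.0,
):
    """Cumulative-normal psychometric function with guess and lapse rates."""
    return gamma + (1.0 - gamma - lam) * ndtr(beta * (np.asarray(x, dtype=float) - alpha))


@dataclass
class PsychometricData:
    """Aggregated binomial outcomes of a 2AFC task, one row per stimulus level.

    Parameters
    ----------
    levels : array-like of shape (n, 3)
        Columns are (amplitude mA, n_correct, n_total).  For JND tasks the
        amplitude column holds ``|test - standard|``.
    task_kind : {"detection", "jnd"}
    standard_amplitude : float, optional
        Standard amplitude in mA; required for JND tasks.
    """

    levels: np.ndarray
    task_kind: str = "detection"
    standard_amplitude: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.levels, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("levels must be (n, 3): amplitude, n_correct, n_total")
        if np.any(arr[:, 1] < 0) or np.any(arr[:, 1] > arr[:, 2]):
            raise ValueError("need 0 <= n_correct <= n_total at every level")
        if np.any(arr[:, 0] < 0) or not np.all(np.isfinite(arr)):
            raise ValueError("amplitudes must be finite and non-negative")
        # repeated identical amplitudes are merged into one binomial level
        amps, inv = np.unique(arr[:, 0], return_inverse=True)
        merged = np.zeros((amps.size, 3))
        merged[:, 0] = amps
        np.add.at(merged[:, 1], inv, arr[:, 1])
        np.add.at(merged[:, 2], inv, arr[:, 2])
        self.levels = merged[merged[:, 2] > 0]
        if self.task_kind not in ("detection", "jnd"):
            raise ValueError(f"unknown task_kind {self.task_kind!r}")

    @property
    def amplitudes(self) -> np.ndarray:
        return self.levels[:, 0]

    @property
    def n_correct(self) -> np.ndarray:
        return self.levels[:, 1]

    @property
    def n_total(self) -> np.ndarray:
        return self.levels[:, 2]

    @property
    def accuracies(self) -> np.ndarray:
        return self.levels[:, 1] / self.levels[:, 2]


@dataclass
class PsychometricFit:
    alpha: float
    beta: float
    gamma: float
    lam: float
    loglik: float
    deviance: float
    threshold75: float
    converged: bool
    ptlr: float | None = None
    n_levels: int = 0
    warnings: list[str] = field(default_factory=list)


def _binom_loglik(p, k, n) -> float:
    """Binomial log-likelihood up to the data-only combinatorial constant."""
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))


def _saturated_loglik(k, n) -> float:
    p = k / n
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log(np.where(k > 0, p, 1.0)), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log(np.where(n > k, 1.0 - p, 1.0)), 0.0)
    return float(np.sum(t1 + t2))


def _neg_loglik(params, x, k, n, gamma, lam) -> float:
    alpha, log_beta = params
    return -_binom_loglik(psi(x, alpha, np.exp(log_beta), gamma, lam), k, n)


def fit_psychometric(
    data: PsychometricData,
    gamma: float = 0.5,
    lam: float = 0.0,
    *,
    start: tuple[float, float] | None = None,
    multistart: bool = True,
) -> PsychometricFit:
    """Fit (alpha, beta) by maximum likelihood with gamma and lam held fixed.

    Optimizes over (alpha, log beta) with a coarse grid seed followed by
    Nelder-Mead refinement from the best grid points.  Degenerate data
    (accuracies all at the guess floor or all at ceiling) yield a fit flagged
    ``converged=False``.

    Parameters
    ----------
    start : (alpha, beta), optional
        Warm start; when given and ``multistart=False`` only this start is
        refined (used by the parametric bootstrap, where the generating
        parameters are a near-optimal seed).
    """
    x, k, n = data.amplitudes, data.n_correct, data.n_total
    if x.size < 2:
        raise ValueError("need at least 2 levels with trials")
    acc = k / n
    warnings: list[str] = []
    degenerate = np.all(acc >= 1.0 - _EPS) or np.all(acc <= gamma + _EPS) or np.ptp(acc) == 0

    starts: list[np.ndarray] = []
    if start is not None:
        starts.append(np.array([start[0], np.log(start[1])]))
    if multistart or not starts:
        span = max(np.ptp(x), 1e-3)
        alpha_grid = np.linspace(x.min() - 0.25 * span, x.max() + 0.25 * span, 13)
        beta_grid = np.log(np.array([0.25, 1.0, 4.0, 16.0]) / span)
        grid = [np.array([a, lb]) for a in alpha_grid for lb in beta_grid]
        grid.sort(key=lambda p: _neg_loglik(p, x, k, n, gamma, lam))
        starts.extend(grid[:3])

    best = None
    for s in starts:
        res = minimize(
            _neg_loglik,
            s,
            args=(x, k, n, gamma, lam),
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-10, "maxiter": 600},
        )
        if best is None or res.fun < best.fun:
            best = res

    alpha_hat, log_beta_hat = best.x
    beta_hat = float(np.exp(log_beta_hat))
    ll = -best.fun
    dev = 2.0 * (_saturated_loglik(k, n) - ll)
    converged = bool(best.success) and not degenerate
    if degenerate:
        warnings.append("degenerate accuracies; location not identifiable")
    fit = PsychometricFit(
        alpha=float(alpha_hat),
        beta=beta_hat,
        gamma=gamma,
        lam=lam,
        loglik=ll,
        deviance=max(dev, 0.0),
        threshold75=np.nan,
        converged=converged,
        n_levels=int(x.size),
        warnings=warnings,
    )
    fit.threshold75 = threshold_at(fit, 0.75)
    return fit


def threshold_at(fit: PsychometricFit, p: float = 0.75) -> float:
    """Stimulus amplitude at which the fitted curve reaches accuracy ``p``.

    Requires gamma <= p <= 1 - lam; with gamma=0.5, lam=0 and p=0.75 this is
    exactly ``alpha``.
    """
    if not (fit.gamma <= p <= 1.0 - fit.lam):
        raise ValueError(f"p={p} outside attainable range [{fit.gamma}, {1 - fit.lam}]")
    q = (p - fit.gamma) / (1.0 - fit.gamma - fit.lam)
    return float(fit.alpha + ndtri(q) / fit.beta)


def estimate_jnd(data: PsychometricData, **fit_kwargs) -> tuple[float, PsychometricFit]:
    """JND: the amplitude difference |test - standard| discriminated at 75%.

    ``data`` must be a JND task whose amplitude column already holds |delta|
    (trials pooled over whether the test fell above or below the standard,
    with "correct" meaning the truly-higher window was chosen).
    """
    if data.task_kind != "jnd":
        raise ValueError("estimate_jnd expects task_kind='jnd'")
    if data.standard_amplitude is None:
        raise ValueError("JND data needs a standard_amplitude")
    fit = fit_psychometric(data, **fit_kwargs)
    return threshold_at(fit, 0.75), fit


def exclusion_check(data: PsychometricData) -> str:
    """Task-level inclusion rule on per-level accuracies.

    A task is excluded when every level's accuracy is below 0.6 (observer
    never clearly detects) or every level is above 0.9 (no dynamic range).
    """
    acc = data.accuracies
    if acc.max() < 0.6 or acc.min() > 0.9:
        return "exclude"
    return "include"


def gof_ptlr(
    fit: PsychometricFit,
    data: PsychometricData,
    n_sim: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict]:
    """Parametric-bootstrap goodness of fit (probability of the transformed
    likelihood ratio).

    Simulates ``n_sim`` datasets from the fitted curve at the observed levels
    and trial counts, refits each, and returns the fraction of simulated
    deviances >= the observed deviance.  High values mean the observed misfit
    is unremarkable; values below 0.05 flag an unacceptable fit.

    Returns (ptlr, info) where info records refit failures (>10% failures
    sets ``info["flagged"]``).
    """
    if not fit.converged:
        raise ValueError("gof_ptlr needs a converged fit")
    rng = np.random.default_rng(rng)
    x, n = data.amplitudes, data.n_total.astype(int)
    p = psi(x, fit.alpha, fit.beta, fit.gamma, fit.lam)
    n_fail = 0
    devs = np.empty(n_sim)
    for i in range(n_sim):
        k_sim = rng.binomial(n, p)
        sim = PsychometricData(np.column_stack([x, k_sim, n]), task_kind=data.task_kind,
                               standard_amplitude=data.standard_amplitude)
        try:
            refit = fit_psychometric(
                sim, fit.gamma, fit.lam, start=(fit.alpha, fit.beta), multistart=False
            )
            devs[i] = refit.deviance
        except Exception:
            devs[i] = np.nan
            n_fail += 1
    ok = np.isfinite(devs)
    ptlr = float(np.mean(devs[ok] >= fit.deviance - 1e-9)) if ok.any() else np.nan
    info = {"n_sim": n_sim, "n_failed": n_fail, "flagged": n_fail > 0.1 * n_sim}
    return ptlr, info


def aggregate_thresholds(per_electrode) -> "pd.DataFrame":
    """Per-subject mean +/- SD of electrode thresholds.

    ``per_electrode`` is an iterable of (subject, electrode, threshold_mA)
    or a DataFrame with those columns.  Thresholds measured for the same
    electrode on different days are averaged into one electrode value first;
    the subject mean and sample SD are then taken over electrodes.
    """
    import pandas as pd

    df = per_electrode if hasattr(per_electrode, "groupby") else pd.DataFrame(
        per_electrode, columns=["subject", "electrode", "threshold_mA"]
    )
    per_el = df.groupby(["subject", "electrode"], sort=True)["threshold_mA"].mean()
    out = per_el.groupby("subject").agg(
        mean_threshold_mA="mean", sd_threshold_mA=lambda s: s.std(ddof=1), n_electrodes="count"
    )
    return out.reset_index()
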