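"""Synthetic-study generation with known ground truth.

Every downstream analysis in this package can be exercised without any real
data: this module simulates 2AFC observers with cumulative-normal
psychometric functions (guess rate 0.5), linear amplitude-to-intensity
raters, weekly-drifting percept drawings on the calibrated arm template,
descriptor-combination reports, electrode metadata and lead-tip tracks, and
writes them in exactly the file formats the pipeline consumes, alongside a
ground-truth JSON.

Default study conditions mirror the source study: four subjects with
(2, 5, 14, 14) analyzable electrodes, subject-level mean detection
thresholds (3.75, 1.25, 1.58, 1.94) mA, four weekly sessions (two for
subject 2), stimulation bounded by the 6 mA hardware ceiling.

All randomness flows through numpy Generators; per-electrode substreams are
derived from the study seed by fixed integer offsets so that identical
(config, seed) pairs produce byte-identical studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from sensorymap import percepts as pc
from sensorymap.psychofit import psi
from sensorymap import staircase as sc

__all__ = [
    "ObserverParams",
    "MagnitudeParams",
    "PerceptDriftParams",
    "DescriptorProfile",
    "StudyGenConfig",
    "SyntheticStudy",
    "simulate_2afc_trial",
    "simulate_magnitude_rating",
    "generate_percept_series",
    "generate_study",
    "DESCRIPTORS",
    "PARESTHETIC_SET",
]

# Table-of-descriptors vocabulary, by modality column
DESCRIPTORS = {
    "mechanical": ("touch", "pressure", "sharp"),
    "tingle": ("electrical", "tickle", "itch", "pins_and_needles"),
    "movement": ("vibration", "across_skin", "body_limb_joint"),
    "temperature": ("temperature",),
}
# descriptors whose presence makes a sensation paresthetic
PARESTHETIC_SET = frozenset({"electrical", "pins_and_needles", "sharp", "tickle"})


@dataclass
class ObserverParams:
    """Ground-truth cumulative-normal 2AFC observer.

    mu : location (detection/JND threshold region), mA
    sigma : psychometric spread, mA
    gamma : guess rate (0.5 for 2AFC)
    lam : lapse rate (fits hold it at 0; configurable for robustness tests)
    """

    mu: float
    sigma: float
    gamma: float = 0.5
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not (0 <= self.gamma < 1):
            raise ValueError("gamma must be in [0, 1)")
        if not (0 <= self.lam < 0.5):
            raise ValueError("lam must be in [0, 0.5)")

    def p_correct(self, amplitude):
        return psi(amplitude, self.mu, 1.0 / self.sigma, self.gamma, self.lam)


@dataclass
class MagnitudeParams:
    """Ground-truth linear intensity rater: rating = intercept + slope*amp + noise.

    Ratings are clipped at zero and are exactly 0 below ``floor`` (no
    sensation perceived).  Noise is additive Gaussian truncated at 0 by the
    clip; ``noise_model='lognormal'`` multiplies the clean rating by a
    lognormal factor instead.
    """

    slope: float
    intercept: float = 0.0
    noise_sd: float = 0.0
    floor: float = 0.0
    noise_model: str = "gaussian"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_model not in ("gaussian", "lognormal"):
            raise ValueError("noise_model must be 'gaussian' or 'lognormal'")


@dataclass
class PerceptDriftParams:
    """Ground truth for a weekly-drifting drawn percept.

    base_segment : template segment seeding the percept location
    semi_axes_mm : ellipse semi-axes of the drawn region, mm
    centroid_drift_mm_per_week : weekly displacement of the true centroid
    area_change_frac_per_week : multiplicative weekly area change (e.g. -0.1)
    jitter_mm : SD of within-week repetition scatter of the center
    drift_direction : unit (row, col) direction of drift; default proximal
    """

    base_segment: str = "palm"
    semi_axes_mm: tuple[float, float] = (18.0, 11.0)
    centroid_drift_mm_per_week: float = 10.0
    area_change_frac_per_week: float = -0.05
    jitter_mm: float = 2.0
    drift_direction: tuple[float, float] = (-1.0, 0.0)

    def __post_init__(self) -> None:
        if self.area_change_frac_per_week <= -1:
            raise ValueError("area cannot shrink by 100% or more per week")
        d = np.hypot(*self.drift_direction)
        if d == 0:
            raise ValueError("drift_direction must be nonzero")
        self.drift_direction = (self.drift_direction[0] / d, self.drift_direction[1] / d)


@dataclass
class DescriptorProfile:
    """Probabilities over descriptor combinations (frozensets of tokens)."""

    probabilities: dict[frozenset, float]

    def __post_init__(self) -> None:
        vocab = {t for toks in DESCRIPTORS.values() for t in toks}
        for combo in self.probabilities:
            unknown = set(combo) - vocab
            if unknown:
                raise ValueError(f"unknown descriptor token(s): {sorted(unknown)}")
        total = sum(self.probabilities.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"combination probabilities sum to {total}, not 1")

    def sample(self, rng: np.random.Generator) -> frozenset:
        combos = sorted(self.probabilities, key=lambda c: sorted(c))
        p = np.array([self.probabilities[c] for c in combos])
        return combos[rng.choice(len(combos), p=p)]


# ---------------------------------------------------------------------------
# elementary simulators

def simulate_2afc_trial(obs: ObserverParams, amplitude: float, rng: np.random.Generator) -> bool:
    """One 2AFC trial: correct with probability Psi(amplitude)."""
    amplitude = float(amplitude)
    if not np.isfinite(amplitude) or amplitude < 0:
        raise ValueError("amplitude must be finite and non-negative")
    return bool(rng.random() < obs.p_correct(amplitude))


def simulate_magnitude_rating(mp: MagnitudeParams, amplitude: float, rng: np.random.Generator) -> float:
    """One magnitude-estimation rating; 0 below the perception floor, never negative."""
    amplitude = float(amplitude)
    if not np.isfinite(amplitude) or amplitude < 0:
        raise ValueError("amplitude must be finite and non-negative")
    if amplitude < mp.floor:
        return 0.0
    clean = mp.intercept + mp.slope * amplitude
    if mp.noise_sd == 0:
        return max(0.0, clean)
    if mp.noise_model == "gaussian":
        return max(0.0, clean + rng.normal(0.0, mp.noise_sd))
    return max(0.0, clean * rng.lognormal(0.0, mp.noise_sd))


def _ellipse_pixels(shape, center_rc, semi_axes_px) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    a, b = semi_axes_px
    return ((rr - center_rc[0]) / a) ** 2 + ((cc - center_rc[1]) / b) ** 2 <= 1.0


def generate_percept_series(
    dp: PerceptDriftParams,
    weeks: int,
    reps_per_week: int,
    rng: np.random.Generator,
    template: pc.CalibratedTemplate | None = None,
    **mask_meta,
) -> list[pc.PerceptMask]:
    """Weekly-drifting elliptical percept drawings on the template.

    The true center starts at the centroid of ``base_segment`` and moves by
    ``centroid_drift_mm_per_week`` along ``drift_direction`` each week; each
    repetition jitters the center by an isotropic Gaussian of SD
    ``jitter_mm``.  The ellipse axes shrink/grow so that area changes by the
    requested multiplicative fraction per week.  Pixels falling outside the
    limb template are clipped off and the mask flagged.
    """
    if weeks < 2 or reps_per_week < 1:
        raise ValueError("need weeks >= 2 and reps_per_week >= 1")
    template = template or pc.build_hand_template()
    s = template.mm_per_px
    seg = template.segment_mask(dp.base_segment)
    rows, cols = np.nonzero(seg)
    base = np.array([rows.mean(), cols.mean()])
    drift_px = np.array(dp.drift_direction) * dp.centroid_drift_mm_per_week / s
    inside = template.labels > 0

    masks: list[pc.PerceptMask] = []
    for w in range(1, weeks + 1):
        axes_scale = np.sqrt((1.0 + dp.area_change_frac_per_week) ** (w - 1))
        axes_px = (
            max(1.0, dp.semi_axes_mm[0] * axes_scale / s),
            max(1.0, dp.semi_axes_mm[1] * axes_scale / s),
        )
        center_w = base + drift_px * (w - 1)
        for r in range(1, reps_per_week + 1):
            center = center_w + rng.normal(0.0, dp.jitter_mm / s, size=2)
            px = _ellipse_pixels(template.shape, center, axes_px)
            clipped = bool(np.any(px & ~inside))
            px &= inside
            if not px.any():
                raise ValueError("drift pushed the percept entirely off the template")
            masks.append(
                pc.PerceptMask(pixels=px, template=template, week=w, repetition=r,
                               clipped=clipped, **mask_meta)
            )
    return masks


# ---------------------------------------------------------------------------
# whole-study generation

_SUBJECT_THRESHOLDS_MA = (3.75, 1.25, 1.58, 1.94)   # subject-level mean detection thresholds
_SPINAL_LEVELS = ("C5", "C6", "C7", "C8", "T1")


@dataclass
class StudyGenConfig:
    """Conditions for a synthetic study; defaults are the study conditions."""

    n_subjects: int = 4
    electrodes_per_subject: tuple[int, ...] = (2, 5, 14, 14)
    weeks_per_subject: tuple[int, ...] = (4, 2, 4, 4)
    subject_mean_threshold_mA: tuple[float, ...] = _SUBJECT_THRESHOLDS_MA
    sigma_frac: float = 0.2            # psychometric spread as a fraction of mu
    n_staircases_per_electrode: int = 2
    constant_stim_levels: int = 6
    trials_per_level: int = 40
    magnitude_blocks: int = 6          # block 1 is later discarded by preprocessing
    magnitude_levels: int = 8
    reps_per_week: int = 3
    n_reports_per_electrode: int = 20
    max_amplitude_mA: float = 6.0
    pulse_width_us: float = 200.0
    drift: PerceptDriftParams = field(default_factory=PerceptDriftParams)
    write_masks: bool = True

    def __post_init__(self) -> None:
        for name in ("electrodes_per_subject", "weeks_per_subject", "subject_mean_threshold_mA"):
            if len(getattr(self, name)) != self.n_subjects:
                raise ValueError(f"{name} must have one entry per subject")


@dataclass
class SyntheticStudy:
    path: Path
    config: StudyGenConfig
    ground_truth: dict
    tables: dict[str, pd.DataFrame]
    template: pc.CalibratedTemplate


def _rng_for(seed: int, *offsets: int) -> np.random.Generator:
    return np.random.default_rng([int(seed)] + [int(o) for o in offsets])


def _default_descriptor_profile(subject_idx: int, rng: np.random.Generator) -> DescriptorProfile:
    """Subject-flavored mixture over descriptor combinations.

    Subject 3 (index 2) is naturalistic-dominant (mostly pure vibration);
    the others are paresthetic/mixed-dominant, echoing the qualitative
    pattern of the source study without reproducing its counts.
    """
    if subject_idx == 2:
        combos = {
            frozenset({"vibration"}): 0.55,
            frozenset({"touch"}): 0.10,
            frozenset({"pressure"}): 0.12,
            frozenset({"electrical", "vibration"}): 0.15,
            frozenset({"electrical"}): 0.03,
            frozenset({"touch", "pressure"}): 0.05,
        }
    else:
        combos = {
            frozenset({"electrical"}): 0.20,
            frozenset({"electrical", "pressure"}): 0.30,
            frozenset({"electrical", "pressure", "vibration"}): 0.20,
            frozenset({"pins_and_needles"}): 0.10,
            frozenset({"sharp", "vibration"}): 0.08,
            frozenset({"pressure"}): 0.07,
            frozenset({"touch"}): 0.05,
        }
    return DescriptorProfile(combos)


def generate_study(config: StudyGenConfig, seed: int, out_dir: str | Path | None = None) -> SyntheticStudy:
    """Generate a full synthetic study; optionally write it to ``out_dir``.

    Emits (as CSV/PNG+JSON, the formats the pipeline consumes):
    ``electrodes.csv``, ``staircase_trials.csv``, ``detection_trials.csv``,
    ``jnd_trials.csv``, ``magnitude_trials.csv``, ``reports.csv``,
    ``threshold_charge.csv``, ``lead_tips.csv``, percept masks under
    ``masks/``, and ``ground_truth.json``.
    """
    cfg = config
    template = pc.build_hand_template()
    gt: dict = {"seed": int(seed), "subjects": {}}
    rows_el, rows_stair, rows_det, rows_jnd, rows_mag = [], [], [], [], []
    rows_rep, rows_charge, rows_tips = [], [], []
    all_masks: list[pc.PerceptMask] = []

    for si in range(cfg.n_subjects):
        subject = f"S{si + 1}"
        weeks = cfg.weeks_per_subject[si]
        mu_mean = cfg.subject_mean_threshold_mA[si]
        profile = _default_descriptor_profile(si, _rng_for(seed, si, 900))
        gt_sub: dict = {"electrodes": {}, "weeks": weeks}

        # lead-tip tracks: caudal settling, largest move in week 1
        for lead in range(3):
            rng = _rng_for(seed, si, 800 + lead)
            mm_per_px = 0.1
            x, y = 200.0 + 50 * lead, 100.0
            for w in range(1, weeks + 1):
                dy_mm = (8.0 if w == 1 else 2.0) * abs(rng.normal(1.0, 0.3))
                y += dy_mm / mm_per_px   # +y = caudal in the aligned frame
                rows_tips.append(dict(subject=subject, lead=f"L{lead + 1}", week=w,
                                      tip_x_px=round(x, 2), tip_y_px=round(y, 2),
                                      mm_per_px=mm_per_px))

        for ei in range(cfg.electrodes_per_subject[si]):
            electrode = f"{subject}E{ei + 1:02d}"
            rng = _rng_for(seed, si, ei)
            mu = float(np.clip(mu_mean * rng.lognormal(0.0, 0.15), 0.3, 5.0))
            obs = ObserverParams(mu=mu, sigma=cfg.sigma_frac * mu)
            mp = MagnitudeParams(
                slope=float(rng.uniform(0.8, 2.0)), intercept=float(-0.5 * mu),
                noise_sd=0.3, floor=0.8 * mu,
            )
            level = _SPINAL_LEVELS[int(rng.integers(1, 4))]
            lead = f"L{ei % 3 + 1}"
            rows_el.append(dict(subject=subject, electrode=electrode, lead=lead,
                                contact=ei % 8 + 1, spinal_level=level, laterality="ipsi"))
            gt_sub["electrodes"][electrode] = {
                "mu_mA": obs.mu, "sigma_mA": obs.sigma,
                "mag_slope": mp.slope, "mag_intercept": mp.intercept,
                "mag_noise_sd": mp.noise_sd, "mag_floor_mA": mp.floor,
                "spinal_level": level,
            }

            # adaptive staircases
            for si_run in range(cfg.n_staircases_per_electrode):
                rng_st = _rng_for(seed, si, ei, 10 + si_run)
                stc = sc.StaircaseConfig(
                    start_amplitude=min(1.5 * mu, cfg.max_amplitude_mA),
                    max_amplitude=cfg.max_amplitude_mA,
                )
                run = sc.run_staircase(
                    lambda a, r: simulate_2afc_trial(obs, a, r), stc, rng_st
                )
                rev = set(run.reversal_indices.tolist())
                for t, (a, c) in enumerate(zip(run.amplitudes, run.correct)):
                    rows_stair.append(dict(subject=subject, electrode=electrode,
                                           session=si_run + 1, trial=t,
                                           amplitude_mA=round(float(a), 6),
                                           correct=int(c), reversal_flag=int(t in rev)))

            # constant-stimuli detection trials
            rng_det = _rng_for(seed, si, ei, 20)
            det_levels = np.linspace(max(0.05, mu - 2 * obs.sigma),
                                     min(cfg.max_amplitude_mA, mu + 2 * obs.sigma),
                                     cfg.constant_stim_levels)
            for a in det_levels:
                for _ in range(cfg.trials_per_level):
                    rows_det.append(dict(subject=subject, electrode=electrode, session=1,
                                         amplitude_mA=round(float(a), 6),
                                         correct=int(simulate_2afc_trial(obs, a, rng_det))))

            # JND trials at the two standard amplitudes (higher standard, larger JND:
            # Weber-like ground truth, jnd_sigma proportional to the standard)
            rng_jnd = _rng_for(seed, si, ei, 30)
            for std in (2.5, 4.0):
                jnd_obs = ObserverParams(mu=0.04 * std, sigma=0.015 * std)
                deltas = np.linspace(0.01, 0.12, 8) * std
                for d in deltas:
                    for _ in range(cfg.trials_per_level):
                        corr = simulate_2afc_trial(jnd_obs, d, rng_jnd)
                        rows_jnd.append(dict(subject=subject, electrode=electrode,
                                             standard_mA=std, delta_mA=round(float(d), 6),
                                             correct=int(corr)))
            gt_sub["electrodes"][electrode]["jnd_mu_mA"] = {
                "2.5": 0.04 * 2.5, "4.0": 0.04 * 4.0}

            # magnitude-estimation blocks
            rng_mag = _rng_for(seed, si, ei, 40)
            amps = np.linspace(mu, cfg.max_amplitude_mA, cfg.magnitude_levels)
            for block in range(1, cfg.magnitude_blocks + 1):
                for a in rng_mag.permutation(amps):
                    rows_mag.append(dict(subject=subject, electrode=electrode, block=block,
                                         amplitude_mA=round(float(a), 6),
                                         rating=round(simulate_magnitude_rating(mp, a, rng_mag), 6)))

            # descriptor reports
            rng_rep = _rng_for(seed, si, ei, 50)
            for t in range(cfg.n_reports_per_electrode):
                combo = profile.sample(rng_rep)
                rows_rep.append(dict(
                    subject=subject, electrode=electrode, trial=t + 1,
                    descriptors="|".join(sorted(combo)),
                    laterality="ipsi",
                    naturalness_vas=round(float(rng_rep.uniform(0, 10)), 2),
                    temperature_vas=0.0,
                    depth=["surface", "below", "both", "diffuse"][int(rng_rep.integers(4))],
                ))

            # weekly threshold-charge record (small week effects around ground truth)
            rng_ch = _rng_for(seed, si, ei, 60)
            for w in range(1, weeks + 1):
                amp_w = mu * (1.0 + rng_ch.normal(0.0, 0.08))
                rows_charge.append(dict(subject=subject, electrode=electrode, week=w,
                                        amplitude_mA=round(float(amp_w), 6),
                                        pulse_width_us=cfg.pulse_width_us,
                                        charge_nC=round(float(amp_w) * cfg.pulse_width_us, 6)))

            # weekly percept drawings at the reference amplitude
            if weeks >= 2:
                rng_pm = _rng_for(seed, si, ei, 70)
                seg = pc.SEGMENTS[int(rng_pm.integers(0, 4))]   # hand segments only
                dp = PerceptDriftParams(
                    base_segment=seg,
                    semi_axes_mm=cfg.drift.semi_axes_mm,
                    centroid_drift_mm_per_week=cfg.drift.centroid_drift_mm_per_week,
                    area_change_frac_per_week=cfg.drift.area_change_frac_per_week,
                    jitter_mm=cfg.drift.jitter_mm,
                    drift_direction=cfg.drift.drift_direction,
                )
                masks = generate_percept_series(
                    dp, weeks, cfg.reps_per_week, rng_pm, template,
                    subject=subject, electrode=electrode, amplitude_mA=round(1.2 * mu, 4),
                )
                all_masks.extend(masks)
                gt_sub["electrodes"][electrode]["percept"] = {
                    "base_segment": seg,
                    "centroid_drift_mm_per_week": dp.centroid_drift_mm_per_week,
                    "area_change_frac_per_week": dp.area_change_frac_per_week,
                }

        gt["subjects"][subject] = gt_sub

    tables = {
        "electrodes": pd.DataFrame(rows_el),
        "staircase_trials": pd.DataFrame(rows_stair),
        "detection_trials": pd.DataFrame(rows_det),
        "jnd_trials": pd.DataFrame(rows_jnd),
        "magnitude_trials": pd.DataFrame(rows_mag),
        "reports": pd.DataFrame(rows_rep),
        "threshold_charge": pd.DataFrame(rows_charge),
        "lead_tips": pd.DataFrame(rows_tips),
    }

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out_path / f"{name}.csv", index=False)
        (out_path / "ground_truth.json").write_text(json.dumps(gt, indent=1, sort_keys=True))
        if cfg.write_masks:
            mask_dir = out_path / "masks"
            mask_dir.mkdir(exist_ok=True)
            for m in all_masks:
                pc.save_mask_png(
                    m, mask_dir / f"{m.subject}_{m.electrode}_w{m.week}_r{m.repetition}.png"
                )

    study = SyntheticStudy(path=out_path or Path("."), config=cfg, ground_truth=gt,
                           tables=tables, template=template)
    study.masks = all_masks
    return study


def load_ground_truth(study_dir: str | Path) -> dict:
    return json.loads((Path(study_dir) / "ground_truth.json").read_text())
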