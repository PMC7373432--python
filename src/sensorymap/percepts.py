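"""Spatial analytics on drawn percept masks.

Subjects outline each evoked sensation on a calibrated arm/hand template.
The template raster carries body-segment labels (thumb, D2-D3, D4-D5, wrist,
forearm, elbow, upper arm, palm) and two independent physical calibrations:
distances are scaled so that the template hand length equals 189 mm (middle
fingertip to wrist) and areas so that the palm region measures 75 cm^2 —
each constant applied only to its own quantity.

Weekly stability of a percept is summarized per electrode at a reference
amplitude: the weekly mean centroid and mean area, the Euclidean migration of
the mean centroid between consecutive weeks, and the change in mean area
between consecutive weeks (signed and absolute).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "SEGMENTS",
    "CalibratedTemplate",
    "PerceptMask",
    "StabilitySeries",
    "build_hand_template",
    "mask_area_cm2",
    "mask_centroid_mm",
    "overlap_fraction",
    "select_reference_amplitude",
    "weekly_stability",
    "area_amplitude_slope",
]

# distal-first order; also the deterministic tie-break order for region assignment
SEGMENTS = ("thumb", "d2_d3", "d4_d5", "palm", "wrist", "forearm", "elbow", "upper_arm")

HAND_LENGTH_MM = 189.0
PALM_AREA_CM2 = 75.0


@dataclass
class CalibratedTemplate:
    """Labeled body-segment raster with physical calibration.

    ``labels`` holds 0 outside the limb and ``1 + SEGMENTS.index(name)``
    inside segment ``name``.  ``mm_per_px`` converts pixel distances to mm
    (hand-length calibration); ``cm2_per_px`` converts pixel counts to cm^2
    (palm-area calibration).
    """

    labels: np.ndarray
    mm_per_px: float
    cm2_per_px: float
    template_id: str = "synthetic-arm-v1"

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0 or self.cm2_per_px <= 0:
            raise ValueError("calibration factors must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def segment_mask(self, name: str) -> np.ndarray:
        return self.labels == (1 + SEGMENTS.index(name))


@dataclass
class PerceptMask:
    """Binary raster of one drawn percept on a calibrated template."""

    pixels: np.ndarray
    template: CalibratedTemplate
    subject: str = ""
    electrode: str = ""
    amplitude_mA: float = np.nan
    week: int = 0
    repetition: int = 0
    laterality: str = "ipsi"
    clipped: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.shape != self.template.shape:
            raise ValueError("mask grid does not match its template")

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


def build_hand_template(
    height_px: int = 420, width_px: int = 180, mm_per_px: float = 0.5
) -> CalibratedTemplate:
    """Construct the synthetic arm template used for simulation and tests.

    A stylized upper limb laid out proximal (row 0) to distal: upper arm,
    elbow, forearm, wrist, then a hand block split into palm and three
    digit segments.  Hand length (palm top to fingertip) is forced to
    HAND_LENGTH_MM by construction at the requested resolution, and the
    area scale is set so the palm segment measures PALM_AREA_CM2.
    """
    labels = np.zeros((height_px, width_px), dtype=np.uint8)
    hand_px = int(round(HAND_LENGTH_MM / mm_per_px))
    if hand_px + 40 > height_px:
        raise ValueError("template too short for the hand at this resolution")

    col0, col1 = int(0.15 * width_px), int(0.85 * width_px)
    hand_top = height_px - hand_px          # wrist crease row
    fingers_top = hand_top + int(0.45 * hand_px)

    def seg(name: str) -> int:
        return 1 + SEGMENTS.index(name)

    arm_len = hand_top
    labels[: int(0.4 * arm_len), col0:col1] = seg("upper_arm")
    labels[int(0.4 * arm_len): int(0.5 * arm_len), col0:col1] = seg("elbow")
    labels[int(0.5 * arm_len): arm_len - 20, col0:col1] = seg("forearm")
    labels[arm_len - 20: arm_len, col0:col1] = seg("wrist")
    # hand: proximal palm block then digit columns
    labels[hand_top:fingers_top, col0:col1] = seg("palm")
    w = col1 - col0
    labels[fingers_top:, col0: col0 + w // 4] = seg("thumb")
    labels[fingers_top:, col0 + w // 4: col0 + (5 * w) // 8] = seg("d2_d3")
    labels[fingers_top:, col0 + (5 * w) // 8: col1] = seg("d4_d5")

    palm_px = int((labels == seg("palm")).sum())
    cm2_per_px = PALM_AREA_CM2 / palm_px
    return CalibratedTemplate(labels=labels, mm_per_px=mm_per_px, cm2_per_px=cm2_per_px)


def mask_area_cm2(mask: PerceptMask) -> float:
    """Percept area: pixel count times the palm-calibrated per-pixel area."""
    n = mask.n_pixels
    if n == 0:
        raise ValueError("empty mask has no area")
    return n * mask.template.cm2_per_px


def mask_centroid_mm(mask: PerceptMask) -> tuple[float, float]:
    """Unweighted centroid of member-pixel centers, in hand-length-calibrated mm."""
    if mask.n_pixels == 0:
        raise ValueError("empty mask has no centroid")
    rows, cols = np.nonzero(mask.pixels)
    s = mask.template.mm_per_px
    return (float(cols.mean() * s), float(rows.mean() * s))


def overlap_fraction(a: PerceptMask, b: PerceptMask) -> float:
    """|a intersect b| / min(|a|, |b|).

    The min denominator makes containment score 1.0, matching the display
    rule that keeps only the more focal of two heavily overlapping percepts.
    """
    if a.template is not b.template and a.template.shape != b.template.shape:
        raise ValueError("masks are on different templates")
    na, nb = a.n_pixels, b.n_pixels
    if na == 0 or nb == 0:
        raise ValueError("empty mask")
    inter = int(np.logical_and(a.pixels, b.pixels).sum())
    return inter / min(na, nb)


def select_reference_amplitude(trials) -> float:
    """Reference amplitude for stability analysis.

    Among tested amplitudes, keep those covering the maximal number of
    distinct weeks (at least 2); return the minimum of those.  ``trials`` is
    an iterable of (amplitude_mA, week).

    Raises
    ------
    ValueError
        If no amplitude was tested in >= 2 distinct weeks (electrode
        excluded from stability analysis).
    """
    weeks_by_amp: dict[float, set] = {}
    for amp, week in trials:
        weeks_by_amp.setdefault(float(amp), set()).add(week)
    best = max((len(w) for w in weeks_by_amp.values()), default=0)
    if best < 2:
        raise ValueError("no amplitude tested in at least two weeks; electrode excluded")
    return min(a for a, w in weeks_by_amp.items() if len(w) == best)


@dataclass
class StabilitySeries:
    """Weekly mean centroid/area for one electrode and week-to-week changes."""

    weeks: np.ndarray                 # sorted distinct week labels
    mean_centroid_mm: np.ndarray      # (n_weeks, 2)
    mean_area_cm2: np.ndarray         # (n_weeks,)
    migration_mm: np.ndarray          # (n_weeks-1,) consecutive-pair centroid distance
    area_change_cm2: np.ndarray       # (n_weeks-1,) signed
    gaps: list[tuple[int, int]] = field(default_factory=list)  # non-consecutive pairs

    @property
    def area_change_abs_cm2(self) -> np.ndarray:
        return np.abs(self.area_change_cm2)


def weekly_stability(masks: list[PerceptMask]) -> StabilitySeries:
    """Summarize per-week percept stability from repeated drawings.

    Centroids and areas are averaged over repetitions within each week;
    migration is the Euclidean distance between consecutive weekly mean
    centroids and area change the difference of consecutive weekly mean
    areas (week k minus week k-1).  Non-consecutive week pairs are still
    differenced but recorded in ``gaps``.
    """
    if not masks:
        raise ValueError("no masks")
    by_week: dict[int, list[PerceptMask]] = {}
    for m in masks:
        by_week.setdefault(int(m.week), []).append(m)
    weeks = np.array(sorted(by_week), dtype=int)
    if weeks.size < 2:
        raise ValueError("need masks from at least two weeks")

    cents = np.array(
        [np.mean([mask_centroid_mm(m) for m in by_week[w]], axis=0) for w in weeks]
    )
    areas = np.array([np.mean([mask_area_cm2(m) for m in by_week[w]]) for w in weeks])
    migration = np.linalg.norm(np.diff(cents, axis=0), axis=1)
    area_change = np.diff(areas)
    gaps = [
        (int(weeks[i]), int(weeks[i + 1]))
        for i in range(weeks.size - 1)
        if weeks[i + 1] - weeks[i] != 1
    ]
    return StabilitySeries(weeks, cents, areas, migration, area_change, gaps)


def area_amplitude_slope(trials) -> tuple[float, float]:
    """OLS slope of percept area on stimulation amplitude and its two-sided p.

    ``trials`` is an iterable of (amplitude_mA, area_cm2).  Used with the
    intensity slope to classify electrodes as modulating intensity only
    (p_area > 0.05) versus intensity and area.
    """
    arr = np.asarray(list(trials), dtype=float)
    if np.unique(arr[:, 0]).size < 3:
        raise ValueError("need at least 3 distinct amplitudes")
    if np.ptp(arr[:, 1]) == 0:   # constant area: zero slope, no evidence against it
        return 0.0, 1.0
    res = stats.linregress(arr[:, 0], arr[:, 1])
    return float(res.slope), float(res.pvalue)


# ---------------------------------------------------------------------------
# PNG + JSON sidecar I/O (8-bit PNG, nonzero = inside the percept)

def save_mask_png(mask: PerceptMask, png_path: str | Path) -> None:
    from PIL import Image

    png_path = Path(png_path)
    Image.fromarray((mask.pixels * 255).astype(np.uint8)).save(png_path)
    sidecar = {
        "subject": mask.subject,
        "electrode": mask.electrode,
        "amplitude_mA": None if np.isnan(mask.amplitude_mA) else mask.amplitude_mA,
        "week": mask.week,
        "repetition": mask.repetition,
        "laterality": mask.laterality,
        "template_id": mask.template.template_id,
        "mm_per_px": mask.template.mm_per_px,
        "clipped": mask.clipped,
    }
    png_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_mask_png(png_path: str | Path, template: CalibratedTemplate) -> PerceptMask:
    from PIL import Image

    png_path = Path(png_path)
    pixels = np.asarray(Image.open(png_path)) > 0
    meta = json.loads(png_path.with_suffix(".json").read_text())
    if meta.get("template_id") != template.template_id:
        raise ValueError("mask was drawn on a different template")
    amp = meta.get("amplitude_mA")
    return PerceptMask(
        pixels=pixels,
        template=template,
        subject=meta.get("subject", ""),
        electrode=meta.get("electrode", ""),
        amplitude_mA=np.nan if amp is None else float(amp),
        week=int(meta.get("week", 0)),
        repetition=int(meta.get("repetition", 0)),
        laterality=meta.get("laterality", "ipsi"),
        clipped=bool(meta.get("clipped", False)),
    )
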