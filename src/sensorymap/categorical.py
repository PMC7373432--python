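"""Percept-report categorization: modality classes, sunburst count tables,
body-region assignment, and dermatome-proportion matrices.

Reports use a fixed descriptor vocabulary grouped by modality column
(mechanical: touch/pressure/sharp; tingle: electrical/tickle/itch/
pins-and-needles; movement: vibration/across-skin/body-limb-joint;
temperature).  A sensation containing any of {electrical, pins_and_needles,
sharp, tickle} is paresthetic; paresthetic content plus any mechanical,
movement, or temperature descriptor makes it mixed; no paresthetic content
makes it naturalistic.  Note the asymmetry inherited from the
classification rule: 'sharp' sits in the mechanical column of the
vocabulary but counts as paresthetic, while 'itch' sits in the tingle
column but does not (a switch lets it be moved).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sensorymap.percepts import SEGMENTS, CalibratedTemplate, PerceptMask
from sensorymap.synth import DESCRIPTORS, PARESTHETIC_SET

__all__ = [
    "PerceptReport",
    "classify_modality",
    "sunburst_counts",
    "assign_body_region",
    "dermatome_proportions",
]

_VOCAB = {t for toks in DESCRIPTORS.values() for t in toks}
_TOKEN_MODALITY = {t: mod for mod, toks in DESCRIPTORS.items() for t in toks}


@dataclass
class PerceptReport:
    """One trial's perceptual report."""

    descriptors: frozenset
    laterality: str = "ipsi"
    naturalness_vas: float | None = None
    temperature_vas: float = 0.0
    depth: str | None = None
    intensity_vas: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.descriptors = frozenset(self.descriptors)
        unknown = set(self.descriptors) - _VOCAB
        if unknown:
            raise ValueError(f"unknown descriptor token(s): {sorted(unknown)}")
        if not self.descriptors:
            raise ValueError("a perceived sensation needs at least one descriptor")
        for name, v in [("naturalness_vas", self.naturalness_vas)]:
            if v is not None and not (0 <= v <= 10):
                raise ValueError(f"{name} must be within 0-10")


def classify_modality(report: PerceptReport, itch_is_paresthetic: bool = False) -> str:
    """Classify a report as 'paresthetic', 'mixed', or 'naturalistic'.

    The three classes are exhaustive and mutually exclusive: any paresthetic
    descriptor plus any non-paresthetic descriptor -> mixed; only
    paresthetic descriptors -> paresthetic; no paresthetic descriptor ->
    naturalistic.  Temperature descriptors count as non-paresthetic content.
    """
    pset = PARESTHETIC_SET | ({"itch"} if itch_is_paresthetic else set())
    has_par = bool(report.descriptors & pset)
    has_nonpar = bool(report.descriptors - pset)
    if has_par and has_nonpar:
        return "mixed"
    if has_par:
        return "paresthetic"
    return "naturalistic"


def sunburst_counts(reports: list[PerceptReport], itch_is_paresthetic: bool = False) -> dict:
    """Hierarchical descriptor counts: tingle -> mechanical -> movement.

    The inner level counts reports carrying each tingle descriptor, the
    middle level splits each of those by co-occurring mechanical descriptor
    and the outer level by co-occurring movement descriptor, so child totals
    never exceed their parent's count.  Also returns the
    paresthetic/mixed/naturalistic fractions over all reports.
    """
    n = len(reports)
    classes = pd.Series([classify_modality(r, itch_is_paresthetic) for r in reports])
    fractions = {
        c: float((classes == c).mean()) if n else 0.0
        for c in ("paresthetic", "mixed", "naturalistic")
    }

    tree: dict = {}
    for tingle in DESCRIPTORS["tingle"]:
        with_t = [r for r in reports if tingle in r.descriptors]
        if not with_t:
            continue
        node = {"count": len(with_t), "children": {}}
        for mech in DESCRIPTORS["mechanical"]:
            with_m = [r for r in with_t if mech in r.descriptors]
            if not with_m:
                continue
            child = {"count": len(with_m), "children": {}}
            for mov in DESCRIPTORS["movement"]:
                c = sum(1 for r in with_m if mov in r.descriptors)
                if c:
                    child["children"][mov] = {"count": c}
            node["children"][mech] = child
        tree[tingle] = node
    return {"n_reports": n, "fractions": fractions, "tingle": tree}


def assign_body_region(mask: PerceptMask, template: CalibratedTemplate | None = None) -> str:
    """Body segment containing the maximal area of the percept.

    Ties break deterministically in distal-first segment order.  A mask
    entirely outside labeled regions is unassignable and raises.
    """
    template = template or mask.template
    if mask.n_pixels == 0:
        raise ValueError("empty mask")
    inside = template.labels[mask.pixels]
    counts = np.bincount(inside, minlength=len(SEGMENTS) + 1)
    counts[0] = 0   # unlabeled background never wins
    if counts.sum() == 0:
        raise ValueError("mask lies entirely outside labeled regions")
    # argmax on ties returns the lowest index = most distal segment
    return SEGMENTS[int(np.argmax(counts[1:]))]


def dermatome_proportions(
    electrodes: pd.DataFrame, percept_regions: pd.DataFrame
) -> pd.DataFrame:
    """Per-region distribution over spinal levels of the evoking electrodes.

    ``electrodes`` needs columns (electrode, spinal_level, laterality);
    only electrodes evoking ipsilateral percepts are included (bilateral- or
    contralateral-only electrodes are excluded).  ``percept_regions`` needs
    (electrode, region).  Returns a levels-by-regions DataFrame whose
    columns each sum to 1 over the represented levels; regions never evoked
    are all-NaN columns, distinguishable from zero.
    """
    el = electrodes.copy()
    if "laterality" in el.columns:
        el = el[el["laterality"] == "ipsi"]
    el = el.dropna(subset=["spinal_level"])
    merged = percept_regions.merge(el[["electrode", "spinal_level"]], on="electrode", how="inner")

    levels = sorted(el["spinal_level"].unique())
    out = pd.DataFrame(np.nan, index=levels, columns=list(SEGMENTS))
    for region, grp in merged.groupby("region"):
        counts = grp["spinal_level"].value_counts()
        out[region] = 0.0
        out.loc[counts.index, region] = counts / counts.sum()
    out.index.name = "spinal_level"
    return out
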