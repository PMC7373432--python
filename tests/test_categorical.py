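"""Modality classification, sunburst nesting, regions, dermatome matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sensorymap import categorical as cat
from sensorymap.percepts import SEGMENTS, PerceptMask
from sensorymap.synth import DESCRIPTORS

ALL_TOKENS = sorted(t for toks in DESCRIPTORS.values() for t in toks)


def report(*tokens):
    return cat.PerceptReport(descriptors=frozenset(tokens))


class TestClassify:
    @pytest.mark.parametrize(
        "tokens, expected",
        [
            (("vibration",), "naturalistic"),
            (("electrical",), "paresthetic"),
            (("pressure", "electrical"), "mixed"),
            (("sharp",), "paresthetic"),          # sharp counts as paresthetic
            (("itch",), "naturalistic"),          # itch does not, by default
            (("touch", "pressure"), "naturalistic"),
            (("tickle", "temperature"), "mixed"),  # temperature is non-paresthetic content
        ],
    )
    def test_rules(self, tokens, expected):
        assert cat.classify_modality(report(*tokens)) == expected

    def test_itch_switch(self):
        assert cat.classify_modality(report("itch"), itch_is_paresthetic=True) == "paresthetic"

    def test_unknown_token_rejected_by_name(self):
        with pytest.raises(ValueError, match="wobble"):
            report("wobble")

    @given(st.sets(st.sampled_from(ALL_TOKENS), min_size=1, max_size=5))
    @settings(max_examples=100, deadline=None)
    def test_classes_partition_any_report(self, tokens):
        cls = cat.classify_modality(report(*tokens))
        assert cls in ("paresthetic", "mixed", "naturalistic")


class TestSunburst:
    def test_all_touch_reports(self):
        reps = [report("touch")] * 10
        counts = cat.sunburst_counts(reps)
        assert counts["fractions"]["naturalistic"] == 1.0
        assert counts["tingle"] == {}

    def test_constructed_fractions(self):
        reps = ([report("electrical")] * 4
                + [report("electrical", "pressure")] * 4
                + [report("touch")] * 2)
        counts = cat.sunburst_counts(reps)
        assert counts["fractions"] == {"paresthetic": 0.4, "mixed": 0.4, "naturalistic": 0.2}

    def test_nesting_ratios(self):
        """Child counts track co-occurrence: tingle > tingle+mech > +movement."""
        reps = ([report("electrical", "sharp", "vibration")] * 3
                + [report("electrical", "sharp")] * 2
                + [report("electrical")] * 5)
        counts = cat.sunburst_counts(reps)
        node = counts["tingle"]["electrical"]
        assert node["count"] == 10
        assert node["children"]["sharp"]["count"] == 5
        assert node["children"]["sharp"]["children"]["vibration"]["count"] == 3

    @given(st.lists(st.sets(st.sampled_from(ALL_TOKENS), min_size=1, max_size=4),
                    min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_children_never_exceed_parents(self, combos):
        counts = cat.sunburst_counts([report(*c) for c in combos])
        for tnode in counts["tingle"].values():
            assert tnode["count"] <= counts["n_reports"]
            for mnode in tnode["children"].values():
                assert mnode["count"] <= tnode["count"]
                for leaf in mnode["children"].values():
                    assert leaf["count"] <= mnode["count"]


class TestBodyRegion:
    def _mask(self, template, pixel_list):
        px = np.zeros(template.shape, bool)
        for r, c in pixel_list:
            px[r, c] = True
        return PerceptMask(pixels=px, template=template)

    def test_entirely_within_one_segment(self, template):
        rows, cols = np.nonzero(template.segment_mask("thumb"))
        m = self._mask(template, list(zip(rows[:6], cols[:6])))
        assert cat.assign_body_region(m) == "thumb"

    def test_maximal_area_rule(self, template):
        fr, fc = np.nonzero(template.segment_mask("forearm"))
        wr, wc = np.nonzero(template.segment_mask("wrist"))
        pix = list(zip(fr[:6], fc[:6])) + list(zip(wr[:4], wc[:4]))   # 60/40 split
        assert cat.assign_body_region(self._mask(template, pix)) == "forearm"

    def test_exact_tie_goes_distal_first(self, template):
        wr, wc = np.nonzero(template.segment_mask("wrist"))
        fr, fc = np.nonzero(template.segment_mask("forearm"))
        pix = list(zip(wr[:5], wc[:5])) + list(zip(fr[:5], fc[:5]))
        assert cat.assign_body_region(self._mask(template, pix)) == "wrist"
        assert SEGMENTS.index("wrist") < SEGMENTS.index("forearm")

    def test_outside_labeled_regions_flagged(self, template):
        m = self._mask(template, [(0, 0)])   # background corner
        with pytest.raises(ValueError):
            cat.assign_body_region(m)


class TestDermatome:
    def _electrodes(self):
        return pd.DataFrame([
            {"electrode": "e1", "spinal_level": "C6", "laterality": "ipsi"},
            {"electrode": "e2", "spinal_level": "C7", "laterality": "ipsi"},
            {"electrode": "e3", "spinal_level": "C7", "laterality": "contra"},
        ])

    def test_single_electrode_regions(self):
        regions = pd.DataFrame([
            {"electrode": "e1", "region": "thumb"},
            {"electrode": "e2", "region": "d2_d3"},
        ])
        props = cat.dermatome_proportions(self._electrodes(), regions)
        assert props.loc["C6", "thumb"] == 1.0
        assert props.loc["C7", "d2_d3"] == 1.0
        assert props.loc["C7", "thumb"] == 0.0

    def test_columns_sum_to_one_over_levels(self):
        regions = pd.DataFrame([
            {"electrode": "e1", "region": "palm"},
            {"electrode": "e2", "region": "palm"},
        ])
        props = cat.dermatome_proportions(self._electrodes(), regions)
        assert props["palm"].sum() == pytest.approx(1.0)

    def test_never_evoked_region_distinguishable_from_zero(self):
        regions = pd.DataFrame([{"electrode": "e1", "region": "thumb"}])
        props = cat.dermatome_proportions(self._electrodes(), regions)
        assert props["elbow"].isna().all()       # never evoked
        assert props.loc["C7", "thumb"] == 0.0   # evoked, but not from C7

    def test_contralateral_electrode_excluded(self):
        regions = pd.DataFrame([
            {"electrode": "e2", "region": "palm"},
            {"electrode": "e3", "region": "palm"},   # contra: must not count
        ])
        props = cat.dermatome_proportions(self._electrodes(), regions)
        assert props.loc["C7", "palm"] == 1.0
        assert props["palm"].sum() == pytest.approx(1.0)
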