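"""Percept-mask spatial operations against brute-force pixel oracles."""

import numpy as np
import pytest

from sensorymap import percepts as pc
from sensorymap import synth


def make_mask(template, pixel_list, **meta):
    px = np.zeros(template.shape, bool)
    for r, c in pixel_list:
        px[r, c] = True
    return pc.PerceptMask(pixels=px, template=template, **meta)


class TestAreaCentroid:
    def test_palm_region_calibrates_to_75_cm2(self, template):
        palm = pc.PerceptMask(pixels=template.segment_mask("palm"), template=template)
        assert pc.mask_area_cm2(palm) == pytest.approx(75.0, rel=1e-9)

    def test_area_additive_over_disjoint_union(self, template):
        a = make_mask(template, [(10, 10), (10, 11)])
        b = make_mask(template, [(50, 50), (51, 50), (52, 50)])
        u = pc.PerceptMask(pixels=a.pixels | b.pixels, template=template)
        assert pc.mask_area_cm2(u) == pytest.approx(
            pc.mask_area_cm2(a) + pc.mask_area_cm2(b), rel=1e-12
        )

    def test_single_pixel_centroid(self, template):
        m = make_mask(template, [(20, 30)])
        s = template.mm_per_px
        assert pc.mask_centroid_mm(m) == pytest.approx((30 * s, 20 * s))

    def test_symmetric_square_centroid(self, template):
        pix = [(r, c) for r in range(10, 15) for c in range(20, 25)]
        m = make_mask(template, pix)
        s = template.mm_per_px
        assert pc.mask_centroid_mm(m) == pytest.approx((22 * s, 12 * s))

    def test_translation_shifts_centroid_by_pythagoras(self, template):
        pix = [(r, c) for r in range(10, 14) for c in range(10, 14)]
        a = make_mask(template, pix)
        b = make_mask(template, [(r + 3, c + 4) for r, c in pix])
        ca, cb = np.array(pc.mask_centroid_mm(a)), np.array(pc.mask_centroid_mm(b))
        assert np.linalg.norm(cb - ca) == pytest.approx(5 * template.mm_per_px, rel=1e-9)

    def test_empty_mask_errors(self, template):
        m = pc.PerceptMask(pixels=np.zeros(template.shape, bool), template=template)
        with pytest.raises(ValueError):
            pc.mask_area_cm2(m)
        with pytest.raises(ValueError):
            pc.mask_centroid_mm(m)


class TestOverlap:
    def test_identical_and_disjoint(self, template):
        a = make_mask(template, [(10, 10), (10, 11)])
        b = make_mask(template, [(40, 40)])
        assert pc.overlap_fraction(a, a) == 1.0
        assert pc.overlap_fraction(a, b) == 0.0

    def test_containment_scores_one(self, template):
        small = make_mask(template, [(10, 10), (10, 11)])
        big = make_mask(template, [(10, c) for c in range(10, 20)])
        assert pc.overlap_fraction(small, big) == 1.0
        assert pc.overlap_fraction(big, small) == 1.0   # symmetric

    def test_partial_overlap(self, template):
        a = make_mask(template, [(10, c) for c in range(10, 14)])   # 4 px
        b = make_mask(template, [(10, c) for c in range(12, 18)])   # 6 px, 2 shared
        assert pc.overlap_fraction(a, b) == pytest.approx(2 / 4)


class TestReferenceAmplitude:
    def test_coverage_beats_magnitude(self):
        trials = [(2.0, w) for w in (1, 2, 3, 4)] + [(1.5, 1), (1.5, 2)]
        assert pc.select_reference_amplitude(trials) == 2.0

    def test_minimum_breaks_coverage_ties(self):
        trials = [(a, w) for a in (2.0, 3.0) for w in (1, 2, 3, 4)]
        assert pc.select_reference_amplitude(trials) == 2.0

    def test_single_week_amplitudes_excluded(self):
        with pytest.raises(ValueError):
            pc.select_reference_amplitude([(1.0, 1), (2.0, 2), (3.0, 3)])


class TestWeeklyStability:
    def test_brute_force_oracle_on_random_series(self, template):
        """Module output equals direct recomputation from raw pixel lists."""
        rng = np.random.default_rng(31)
        for _ in range(10):
            dp = synth.PerceptDriftParams(
                centroid_drift_mm_per_week=float(rng.uniform(0, 8)),
                jitter_mm=float(rng.uniform(0, 3)),
                area_change_frac_per_week=float(rng.uniform(-0.15, 0.1)),
            )
            masks = synth.generate_percept_series(dp, 3, 2, rng, template)
            series = pc.weekly_stability(masks)

            s, a_px = template.mm_per_px, template.cm2_per_px
            cents, areas = [], []
            for w in (1, 2, 3):
                wk = [m for m in masks if m.week == w]
                cs = []
                for m in wk:
                    rows, cols = np.nonzero(m.pixels)
                    cs.append((cols.mean() * s, rows.mean() * s))
                cents.append(np.mean(cs, axis=0))
                areas.append(np.mean([m.pixels.sum() * a_px for m in wk]))
            np.testing.assert_allclose(series.mean_centroid_mm, cents, rtol=1e-12)
            np.testing.assert_allclose(series.mean_area_cm2, areas, rtol=1e-12)
            np.testing.assert_allclose(
                series.migration_mm,
                [np.linalg.norm(cents[1] - cents[0]), np.linalg.norm(cents[2] - cents[1])],
                rtol=1e-12,
            )

    def test_recovers_injected_drift(self, template):
        dp = synth.PerceptDriftParams(centroid_drift_mm_per_week=5.0, jitter_mm=0.0,
                                      area_change_frac_per_week=0.0)
        masks = synth.generate_percept_series(dp, 4, 3, np.random.default_rng(2), template)
        series = pc.weekly_stability(masks)
        np.testing.assert_allclose(series.migration_mm, 5.0, atol=template.mm_per_px)
        np.testing.assert_allclose(series.area_change_cm2, 0.0,
                                   atol=3 * template.cm2_per_px)

    def test_missing_week_recorded_as_gap(self, template):
        pix = [(10, 10), (10, 11)]
        masks = [make_mask(template, pix, week=1), make_mask(template, pix, week=3)]
        series = pc.weekly_stability(masks)
        assert series.gaps == [(1, 3)]


class TestAreaAmplitudeSlope:
    def test_constant_area(self):
        slope, p = pc.area_amplitude_slope([(1.0, 2.0), (2.0, 2.0), (3.0, 2.0), (4.0, 2.0)])
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_noise_free_slope_exact(self):
        amps = np.linspace(1.0, 5.0, 6)
        slope, p = pc.area_amplitude_slope(list(zip(amps, 0.25 * amps + 1.0)))
        assert slope == pytest.approx(0.25, rel=1e-12)
        assert p < 1e-8

    def test_intensity_only_classification(self):
        """Flat area + steep intensity slope: the p_area > 0.05 rule says
        the electrode modulates intensity without growing the percept."""
        rng = np.random.default_rng(3)
        amps = np.tile(np.linspace(1.0, 5.0, 6), 4)
        area = 4.0 + 0.01 * amps + rng.normal(0, 0.8, amps.size)
        slope, p_area = pc.area_amplitude_slope(list(zip(amps, area)))
        assert p_area > 0.05
        from sensorymap import magnitude as mg
        fit = mg.fit_intensity_models(amps, 1.33 * amps + rng.normal(0, 0.3, amps.size))
        assert fit.p_int < 0.01


class TestMaskIO:
    def test_png_sidecar_round_trip(self, template, tmp_path):
        dp = synth.PerceptDriftParams()
        m = synth.generate_percept_series(dp, 2, 1, np.random.default_rng(1), template,
                                          subject="S1", electrode="S1E01",
                                          amplitude_mA=1.5)[0]
        pc.save_mask_png(m, tmp_path / "m.png")
        back = pc.load_mask_png(tmp_path / "m.png", template)
        np.testing.assert_array_equal(back.pixels, m.pixels)
        assert back.subject == "S1" and back.week == m.week
        assert back.amplitude_mA == pytest.approx(1.5)
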