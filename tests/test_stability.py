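"""Threshold charge, week ANOVA + Tukey, AR(1) trends, lead geometry."""

import numpy as np
import pandas as pd
import pytest

from sensorymap import stability as st


class TestThresholdCharge:
    def test_product_in_nc(self):
        assert st.threshold_charge(2.0, 200.0) == 400.0
        assert st.threshold_charge(1.0, 1.0) == 1.0

    def test_linearity(self):
        assert st.threshold_charge(4.0, 150.0) == 2 * st.threshold_charge(2.0, 150.0)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            st.threshold_charge(0.0, 200.0)


def hand_anova(groups):
    """Independent sum-of-squares one-way ANOVA oracle."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    dfb = len(groups) - 1
    dfw = allv.size - len(groups)
    return (ssb / dfb) / (ssw / dfw)


class TestAnova:
    def test_matches_sum_of_squares_oracle(self):
        groups = {1: [1, 2, 3], 2: [2, 3, 4], 3: [7, 8, 9]}
        res = st.anova_by_week(groups)
        assert res["F"] == pytest.approx(hand_anova(list(groups.values())), abs=1e-9)

    def test_random_instances_match_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            groups = {w: rng.normal(w, 1.0, rng.integers(3, 8)) for w in range(1, 5)}
            res = st.anova_by_week(groups)
            assert res["F"] == pytest.approx(hand_anova(list(groups.values())), abs=1e-9)

    def test_identical_groups_give_zero_f(self):
        res = st.anova_by_week({1: [1.0, 2.0, 3.0], 2: [1.0, 2.0, 3.0]})
        assert res["F"] == pytest.approx(0.0, abs=1e-12)

    def test_type_one_error_calibrated(self):
        """Null rejection rate at alpha=0.05 is ~5% over 2000 simulations."""
        rng = np.random.default_rng(77)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            groups = {w: rng.normal(0, 1, 6) for w in range(4)}
            rejections += st.anova_by_week(groups)["p"] < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.015)

    def test_small_weeks_dropped_with_warning(self):
        res = st.anova_by_week({1: [1.0, 2.0], 2: [2.0, 3.0], 3: [5.0]})
        assert res["dropped_weeks"] == [3]


class TestTukey:
    def test_adjusted_p_at_least_unadjusted(self):
        from scipy import stats as sps
        rng = np.random.default_rng(9)
        groups = {w: rng.normal(0.3 * w, 1.0, 8) for w in range(1, 5)}
        tk = st.tukey_pairs(groups)
        for _, row in tk.iterrows():
            raw = sps.ttest_ind(groups[row["week_a"]], groups[row["week_b"]]).pvalue
            assert row["p_adj"] >= raw - 1e-12

    def test_detects_shifted_week(self):
        rng = np.random.default_rng(10)
        groups = {1: rng.normal(0, 0.5, 10), 2: rng.normal(0, 0.5, 10),
                  3: rng.normal(5, 0.5, 10)}
        tk = st.tukey_pairs(groups)
        sig = tk[tk["p_adj"] < 0.01]
        assert set(map(tuple, sig[["week_a", "week_b"]].values)) == {(1, 3), (2, 3)}


class TestAR1:
    def test_white_noise_reduces_to_ols(self):
        rng = np.random.default_rng(2)
        y = 0.5 * np.arange(500) + rng.normal(0, 1, 500)
        res = st.ar1_regression(y)
        assert abs(res["beta_t"] - res["beta_t_ols"]) < 1e-3
        assert abs(res["rho"]) < 0.1
        assert not res["nonstationary"]

    def test_exact_line(self):
        res = st.ar1_regression(2.0 * np.arange(10) + 1.0)
        assert res["beta_t"] == pytest.approx(2.0, abs=1e-9)
        assert res["p"] < 1e-20

    def test_recovery_under_ar1_noise(self):
        """beta recovered within +/-0.03 and rho within +/-0.1 (medians, n=200)."""
        betas, rhos = [], []
        for s in range(100):
            rng = np.random.default_rng([11, s])
            n = 200
            e = np.zeros(n)
            u = rng.normal(0, 1, n)
            for i in range(1, n):
                e[i] = 0.5 * e[i - 1] + u[i]
            res = st.ar1_regression(-0.2 * np.arange(n) + e)
            betas.append(res["beta_t"])
            rhos.append(res["rho"])
        assert abs(np.median(betas) - (-0.2)) < 0.03
        assert abs(np.median(rhos) - 0.5) < 0.1

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            st.ar1_regression([1.0, 2.0, 3.0])


class TestAffine:
    def test_identity(self):
        pts = np.array([[0, 0], [10, 0], [0, 10], [7, 3]], float)
        tr = st.affine_from_landmarks(pts, pts)
        np.testing.assert_allclose(tr["A"], np.eye(2), atol=1e-12)
        np.testing.assert_allclose(tr["b"], 0, atol=1e-12)
        assert tr["residual_rms"] == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation(self):
        pts = np.array([[0, 0], [10, 0], [0, 10]], float)
        tr = st.affine_from_landmarks(pts, pts + [3.0, -4.0])
        np.testing.assert_allclose(tr["A"], np.eye(2), atol=1e-12)
        np.testing.assert_allclose(tr["b"], [3.0, -4.0], atol=1e-12)

    def test_random_affine_recovered_vs_normal_equations(self):
        rng = np.random.default_rng(6)
        A_true = rng.normal(0, 1, (2, 2)) + np.eye(2)
        b_true = rng.normal(0, 5, 2)
        src = rng.uniform(0, 100, (6, 2))
        tgt = src @ A_true.T + b_true
        tr = st.affine_from_landmarks(src, tgt)
        np.testing.assert_allclose(tr["A"], A_true, atol=1e-9)
        np.testing.assert_allclose(tr["b"], b_true, atol=1e-9)
        # independent closed-form oracle via the normal equations
        D = np.column_stack([src, np.ones(6)])
        coef = np.linalg.solve(D.T @ D, D.T @ tgt)
        np.testing.assert_allclose(tr["A"], coef[:2].T, atol=1e-9)

    def test_collinear_landmarks_rejected(self):
        pts = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], float)
        with pytest.raises(ValueError):
            st.affine_from_landmarks(pts, pts)


class TestLeadGeometry:
    def test_contact_scale(self):
        assert st.contact_scale((0, 0), (0, 30)) == pytest.approx(0.1)
        assert st.contact_scale((0, 0), (3, 0)) == pytest.approx(1.0)
        assert st.contact_scale((0, 0), (0, 60)) == pytest.approx(0.05)

    def test_caudal_positive_migration(self):
        track = st.LeadTipTrack(weeks=[1, 2], tips_px=[[100, 200], [100, 250]],
                                mm_per_px=0.1)
        out = st.rostrocaudal_migration(track)
        assert out.loc[0, "migration_mm"] == pytest.approx(5.0)

    def test_no_movement(self):
        track = st.LeadTipTrack(weeks=[1, 2, 3], tips_px=[[5, 5]] * 3, mm_per_px=0.2)
        out = st.rostrocaudal_migration(track)
        np.testing.assert_allclose(out["migration_mm"], 0.0)

    def test_subject_median_across_leads(self):
        tracks = {
            f"L{i}": st.LeadTipTrack(weeks=[1, 2], tips_px=[[0, 0], [0, d / 0.1]],
                                     mm_per_px=0.1)
            for i, d in enumerate([2.0, -1.0, 4.0])
        }
        med = st.subject_median_migration(tracks)
        assert med.loc[0, "median_migration_mm"] == pytest.approx(2.0)
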