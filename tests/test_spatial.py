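"""Cross-K estimation, the AUC mixing score, and Mixture/Separative grouping."""

import numpy as np
import pytest

import roicell as rc
from roicell.errors import InsufficientPointsError, ParameterError


def _pattern(points_pos, points_neg, radius=100.0):
    points = np.vstack([points_pos, points_neg])
    marks = np.array(
        ["positive"] * len(points_pos) + ["negative"] * len(points_neg)
    )
    return rc.MarkedPointPattern(
        points=points, marks=marks, window_center=(0.0, 0.0), window_radius=radius
    )


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_uncorrected_estimator(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(5, 100, size=2)
        pat = rc.make_pattern(
            rc.PatternFixtureSpec(n_positive=int(n1), n_negative=int(n2), seed=seed)
        )
        fast = rc.cross_k(pat, edge_correction="none")
        slow = rc.brute_force_cross_k(pat)
        np.testing.assert_allclose(fast.k_obs, slow.k_obs, rtol=1e-9)
        assert fast.auc == pytest.approx(slow.auc, rel=1e-9)

    def test_two_point_step_closed_form(self):
        d = 10.0
        pat = _pattern([(0.0, 0.0)], [(d, 0.0)], radius=50.0)
        res = rc.brute_force_cross_k(pat, r_max=20.0, n_r=200)
        area = np.pi * 50.0**2
        expected = np.where(res.radii >= d, area, 0.0)
        np.testing.assert_allclose(res.k_obs, expected)

    def test_empty_mark_raises_naming_it(self):
        pat = _pattern([(0.0, 0.0), (1.0, 1.0)], [(2.0, 2.0)], radius=10.0)
        pat = rc.MarkedPointPattern(
            points=pat.points[:2],
            marks=np.array(["positive", "positive"]),
            window_center=(0, 0),
            window_radius=10.0,
        )
        with pytest.raises(InsufficientPointsError, match="negative"):
            rc.brute_force_cross_k(pat)


class TestCrossK:
    def test_reference_curve_is_poisson(self):
        pat = rc.make_pattern(rc.PatternFixtureSpec(seed=0))
        res = rc.cross_k(pat)
        np.testing.assert_array_equal(res.k_ref, np.pi * res.radii**2)
        assert res.radii[0] > 0
        assert res.radii[-1] == pytest.approx(pat.window_radius / 4)
        assert (np.diff(res.radii) > 0).all()

    def test_csr_mean_auc_near_zero(self):
        aucs = np.array(
            [
                rc.cross_k(
                    rc.make_pattern(rc.PatternFixtureSpec(regime="csr", seed=s))
                ).auc
                for s in range(30)
            ]
        )
        se = aucs.std(ddof=1) / np.sqrt(len(aucs))
        assert abs(aucs.mean()) <= 3 * se

    @pytest.mark.parametrize(
        "regime,sign", [("attraction", 1.0), ("segregation", -1.0)]
    )
    def test_mixing_regimes_auc_sign(self, regime, sign):
        hits = 0
        for s in range(30):
            pat = rc.make_pattern(rc.PatternFixtureSpec(regime=regime, seed=s))
            if sign * rc.cross_k(pat).auc > 0:
                hits += 1
        assert hits >= 29

    def test_mark_swap_symmetry_translation(self):
        pat = rc.make_pattern(
            rc.PatternFixtureSpec(n_positive=150, n_negative=150, seed=8)
        )
        fwd = rc.cross_k(pat, edge_correction="translation")
        rev = rc.cross_k(
            pat,
            edge_correction="translation",
            mark_from="negative",
            mark_to="positive",
        )
        assert fwd.auc == pytest.approx(rev.auc, rel=1e-9)

    def test_border_equals_bruteforce_for_interior_pattern(self):
        # All points within half the window radius: no boundary losses, so
        # the reduced-sample estimator coincides with the raw pair count.
        rng = np.random.default_rng(3)
        R = 100.0
        pos = rc.synthetic._uniform_disc(rng, 60, R / 2)
        neg = rc.synthetic._uniform_disc(rng, 60, R / 2)
        pat = _pattern(pos, neg, radius=R)
        border = rc.cross_k(pat, edge_correction="border", r_max=R / 4)
        brute = rc.brute_force_cross_k(pat, r_max=R / 4)
        np.testing.assert_allclose(border.k_obs, brute.k_obs, rtol=1e-2)

    def test_auc_invariant_to_rotation_and_translation(self):
        pat = rc.make_pattern(
            rc.PatternFixtureSpec(n_positive=100, n_negative=100, seed=4)
        )
        base = rc.cross_k(pat).auc
        theta = 0.7
        rot = pat.points @ np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        rotated = rc.MarkedPointPattern(
            points=rot,
            marks=pat.marks,
            window_center=(0, 0),
            window_radius=pat.window_radius,
        )
        assert rc.cross_k(rotated).auc == pytest.approx(base, rel=1e-9)
        # pure translation together with the window keeps distances intact
        moved = rc.MarkedPointPattern(
            points=pat.points + np.array([5.0, 5.0]),
            marks=pat.marks,
            window_center=(5.0, 5.0),
            window_radius=pat.window_radius,
        )
        assert rc.cross_k(moved).auc == pytest.approx(base, rel=1e-9)

    def test_insufficient_points_and_rmax_errors(self):
        pat = rc.make_pattern(rc.PatternFixtureSpec(n_positive=1, seed=0))
        with pytest.raises(InsufficientPointsError, match="positive"):
            rc.cross_k(pat)
        good = rc.make_pattern(rc.PatternFixtureSpec(seed=0))
        with pytest.raises(ParameterError):
            rc.cross_k(good, r_max=good.window_radius * 2)


class TestClassifyMixing:
    def test_top_n_rule(self):
        groups = rc.classify_mixing(
            {"a": 0.5, "b": 0.1, "c": -0.2}, rule={"top_n": 1}
        )
        assert groups == {"a": "Mixture", "b": "Separative", "c": "Separative"}

    def test_threshold_rule(self):
        groups = rc.classify_mixing(
            {"a": 0.5, "b": 0.1, "c": -0.2}, rule={"threshold": 0}
        )
        assert groups == {"a": "Mixture", "b": "Mixture", "c": "Separative"}

    def test_tie_broken_by_roi_id(self):
        groups = rc.classify_mixing({"b": 1.0, "a": 1.0}, rule={"top_n": 1})
        assert groups["a"] == "Mixture"

    def test_top_n_too_large_raises(self):
        with pytest.raises(ParameterError):
            rc.classify_mixing({"a": 1.0}, rule={"top_n": 2})

    def test_recovers_generator_regimes_7_of_26(self):
        results = {}
        truth = {}
        for i in range(26):
            regime = "attraction" if i < 7 else "segregation"
            truth[f"roi{i:02d}"] = "Mixture" if regime == "attraction" else "Separative"
            pat = rc.make_pattern(
                rc.PatternFixtureSpec(
                    regime=regime, n_positive=150, n_negative=150, seed=100 + i
                )
            )
            results[f"roi{i:02d}"] = rc.cross_k(pat)
        groups = rc.classify_mixing(results, rule={"top_n": 7})
        assert groups == truth
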