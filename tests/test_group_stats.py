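import numpy as np
import pytest
from scipy import stats as sps

import oracles
from facetwear.group_stats import (
    cliffs_method,
    compare_groups,
    dual_significance,
    pairwise_t3,
    trimmed_stats,
    variability_profile,
    wy_omnibus,
)


class TestTrimmedStats:
    def test_hand_computed_example(self):
        tm, wv, h = trimmed_stats(np.arange(1, 11), trim=0.15)
        assert tm == pytest.approx(5.5)       # mean of 2..9
        assert h == 8

    def test_symmetric_sample_equals_mean(self):
        x = np.array([-3.0, -1.0, 0.0, 1.0, 3.0])
        tm, _, _ = trimmed_stats(x, 0.2)
        assert tm == pytest.approx(x.mean())

    def test_zero_trim_is_ordinary_moments(self, rng):
        x = rng.normal(size=20)
        tm, wv, h = trimmed_stats(x, 0.0)
        assert tm == pytest.approx(x.mean())
        assert wv == pytest.approx(x.var(ddof=1))
        assert h == 20

    def test_matches_oracle_trimmed_mean(self, rng):
        for n in (7, 11, 26):
            x = rng.normal(size=n)
            tm, _, _ = trimmed_stats(x, 0.15)
            assert tm == pytest.approx(oracles.trimmed_mean(x, 0.15))

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            trimmed_stats([1.0, 2.0, 3.0], 0.15)


class TestWyOmnibus:
    def test_four_groups_nu1_is_three(self, rng):
        groups = [rng.normal(0, s, n)
                  for s, n in zip((1, 2, 1.5, 3), (7, 6, 7, 6))]
        Ft, nu1, nu2, p = wy_omnibus(groups, 0.15)
        assert nu1 == 3
        assert nu2 > 0 and 0 <= p <= 1

    def test_two_groups_equals_squared_welch_t(self, rng):
        x, y = rng.normal(0, 1, 9), rng.normal(1, 3, 14)
        Ft, _, nu2, p = wy_omnibus([x, y], trim=0.0)
        t, p_w = sps.ttest_ind(x, y, equal_var=False)
        assert Ft == pytest.approx(t**2, rel=1e-9)
        assert p == pytest.approx(p_w, rel=1e-9)

    def test_group_order_invariance(self, rng):
        groups = [rng.normal(m, s, n)
                  for m, s, n in zip((0, 1, 2, 0.5), (1, 2, 1, 3),
                                     (7, 6, 7, 6))]
        a = wy_omnibus(groups, 0.15)
        b = wy_omnibus(groups[::-1], 0.15)
        assert a[0] == pytest.approx(b[0], rel=1e-12)

    def test_joint_affine_invariance(self, rng):
        groups = [rng.normal(m, s, n)
                  for m, s, n in zip((0, 1, 2, 0.5), (1, 2, 1, 3),
                                     (7, 6, 7, 6))]
        a = wy_omnibus(groups, 0.15)
        shifted = [3.0 * g - 7.0 for g in groups]
        b = wy_omnibus(shifted, 0.15)
        assert a[0] == pytest.approx(b[0], rel=1e-9)
        assert a[3] == pytest.approx(b[3], rel=1e-9)

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(20240215)
        n_sim, alpha = 4000, 0.05
        rej = 0
        for _ in range(n_sim):
            gs = [rng.normal(0, s, n)
                  for s, n in zip((1, 2, 1.5, 3), (7, 6, 7, 6))]
            rej += wy_omnibus(gs, 0.15)[3] <= alpha
        assert 0.035 <= rej / n_sim <= 0.07


class TestPairwise:
    def test_six_pairs_for_four_groups(self, rng):
        groups = [rng.normal(0, 1, 7) for _ in range(4)]
        rows = pairwise_t3(groups, 0.15)
        assert len(rows) == 6

    def test_identical_large_samples_not_significant(self, rng):
        x = rng.normal(0, 1, 200)
        rows = pairwise_t3([x, x.copy() + rng.normal(0, 1e-6, 200)], 0.15)
        assert rows[0]["p_adj"] > 0.9

    def test_huge_shift_detected(self, rng):
        hits = 0
        for _ in range(50):
            base = [rng.normal(0, 1, 7) for _ in range(3)]
            shifted = rng.normal(10, 1, 7)
            rows = pairwise_t3(base + [shifted], 0.15,
                               labels=list("ABCD"))
            row = [r for r in rows if r["pair"] == ("A", "D")][0]
            hits += row["p_adj"] < 0.001
        assert hits >= 49

    def test_adjusted_p_not_below_raw(self, rng):
        groups = [rng.normal(m, 1, 8) for m in (0, 0.5, 1, 2)]
        for row in pairwise_t3(groups, 0.15):
            assert row["p_adj"] >= row["p_raw"] - 1e-12


class TestCliff:
    def test_complete_separation(self):
        res = cliffs_method([1, 2, 3], [4, 5, 6])
        assert res["delta"] == -1.0
        assert res["flag"] is not None
        assert res["p"] <= 0.1

    def test_identical_multisets(self):
        res = cliffs_method([1, 2, 3], [1, 2, 3])
        assert res["delta"] == 0.0

    def test_hand_enumerated(self):
        res = cliffs_method([1, 3], [2, 4])
        assert res["delta"] == pytest.approx(-0.5)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(200):
            x = rng.integers(0, 8, rng.integers(2, 9)).astype(float)
            y = rng.integers(0, 8, rng.integers(2, 9)).astype(float)
            assert cliffs_method(x, y)["delta"] == pytest.approx(
                oracles.cliff_delta(x, y), abs=1e-12)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 2, 6)
        assert cliffs_method(x, y)["delta"] == -cliffs_method(y, x)["delta"]

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(0.5, 2, 6)
        a = cliffs_method(x, y)
        b = cliffs_method(np.exp(x), np.exp(y))
        assert a["delta"] == b["delta"]
        assert a["p"] == pytest.approx(b["p"], rel=1e-12)

    def test_ci_inside_bounds(self, rng):
        for _ in range(50):
            x, y = rng.normal(0, 1, 7), rng.normal(0.4, 1.5, 6)
            res = cliffs_method(x, y)
            lo, hi = res["ci"]
            assert -1 <= lo <= res["delta"] <= hi <= 1


class TestDualSignificance:
    @pytest.mark.parametrize("p1,p2,alpha,expected", [
        (0.03, 0.04, 0.05, True),
        (0.03, 0.06, 0.05, False),
        (0.05, 0.05, 0.05, True),      # boundary: <= rule
        (0.051, 0.01, 0.05, False),
    ])
    def test_rule(self, p1, p2, alpha, expected):
        assert dual_significance(p1, p2, alpha) is expected

    def test_intersection_never_more_liberal(self, rng):
        # type-I error of the dual rule is bounded by each test alone
        n_sim = 800
        hits_dual = hits_pw = hits_cm = 0
        for _ in range(n_sim):
            x, y = rng.normal(0, 1, 7), rng.normal(0, 2, 6)
            p_pw = pairwise_t3([x, y], 0.15)[0]["p_adj"]
            p_cm = cliffs_method(x, y)["p"]
            hits_pw += p_pw <= 0.05
            hits_cm += p_cm <= 0.05
            hits_dual += dual_significance(p_pw, p_cm)
        assert hits_dual <= min(hits_pw, hits_cm)


class TestVariabilityProfile:
    def test_hand_computed_quartiles(self):
        prof = variability_profile({"g": [1, 2, 3, 4, 5]})["g"]
        assert prof["median"] == 3
        assert prof["q1"] == 2 and prof["q3"] == 4
        assert prof["iqr"] == 2

    def test_degenerate_group(self):
        prof = variability_profile({"g": [7.0, 7.0, 7.0]})["g"]
        assert prof["iqr"] == 0
        assert prof["whisker_low"] == prof["whisker_high"] == 7.0

    def test_whiskers_exclude_extremes(self):
        vals = [1, 2, 3, 4, 5, 100]
        prof = variability_profile({"g": vals})["g"]
        assert prof["whisker_high"] < 100


class TestCompareGroups:
    def test_full_protocol_shape(self, rng):
        data = {g: rng.normal(m, 1, n)
                for g, m, n in zip("ABCD", (0, 0, 2, 4), (7, 6, 7, 6))}
        res = compare_groups(data, variable="x")
        assert res.nu1 == 3
        assert len(res.pairwise) == 6
        assert len(res.cliff) == 6
        assert set(res.dual_significant) == {
            (a, b) for i, a in enumerate("ABCD") for b in list("ABCD")[i + 1:]}
        # strongly separated pair should be dual significant
        assert res.dual_significant[("A", "D")]
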