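import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from recseq.enrich import FullSiteProfile
from recseq.stats import (
    InsufficientReplicatesError,
    asymmetry_test,
    bonferroni,
    embed_feature_matrix,
    feature_matrix,
    mann_whitney_exact,
    per_position_test,
    profile_test,
)
from recseq.targets import LOXP, Side


def make_full_profile(log2_r):
    """FullSiteProfile over loxP's 26 positions from given log2 r values."""
    log2_r = np.asarray(log2_r, dtype=float)
    assert log2_r.size == 26
    labels = [str(i) for i in range(17, 4, -1)] + [f"{i}′" for i in range(5, 18)]
    positions = list(range(17, 4, -1)) + list(range(5, 18))
    sides = [Side.LEFT] * 13 + [Side.RIGHT] * 13
    return FullSiteProfile(
        site=LOXP,
        labels=labels,
        positions=positions,
        sides=sides,
        canonical=LOXP.left_half + LOXP.right_half,
        r=np.exp2(log2_r),
        e=np.ones((26, 4)),
    )


class TestPerPositionTest:
    def test_identical_groups_not_significant(self):
        g = np.array([[0.5, 1.0], [0.5, 1.0], [0.5, 1.0]])
        res = per_position_test(g, g.copy())
        assert np.all(res.t == 0.0)
        assert np.all(res.p_raw == 1.0)
        assert not res.significant.any()

    def test_large_shift_significant_after_bonferroni(self):
        # closed-form oracle: pooled t with group s.d. 0.1, delta 1, n=3
        a = np.array([[-0.1], [0.0], [0.1]])
        b = a + 1.0
        sp = 0.1  # pooled s.d. equals the common within-group s.d.
        t_oracle = 1.0 / (sp * math.sqrt(2 / 3))
        p_oracle = 2 * sps.t.sf(t_oracle, df=4)
        res = per_position_test(b, a, family_size=26)
        assert abs(res.t[0]) == pytest.approx(t_oracle)
        assert res.p_raw[0] == pytest.approx(p_oracle, rel=1e-9)
        assert p_oracle < 1e-3
        assert res.significant[0]

    def test_bonferroni_multiplies_and_caps(self):
        assert bonferroni(0.01, 26) == pytest.approx(0.26)
        assert bonferroni(0.2, 26) == 1.0
        res = per_position_test(
            np.array([[0.0], [0.02], [-0.02]]),
            np.array([[0.1], [0.12], [0.08]]),
            family_size=26,
        )
        if res.p_raw[0] * 26 < 1:
            assert res.p_adjusted[0] == pytest.approx(res.p_raw[0] * 26)

    def test_insufficient_replicates(self):
        with pytest.raises(InsufficientReplicatesError):
            per_position_test(np.array([[1.0, 2.0]]), np.array([[1.0, 2.0], [2.0, 3.0]]))

    def test_replicate_order_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(4, 26)), rng.normal(size=(5, 26))
        r1 = per_position_test(a, b)
        r2 = per_position_test(a[::-1], b[[3, 1, 0, 2, 4]])
        assert r1.p_raw == pytest.approx(r2.p_raw)


def mwu_enumeration_oracle(x, y):
    """Independent rank-based enumeration of the two-sided MWU p-value."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(group_x, group_y):
        u = 0.0
        for xi in group_x:
            for yj in group_y:
                u += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
        return u

    center = len(x) * len(y) / 2
    obs = abs(u_of(x, y) - center)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        gx = [pooled[i] for i in combo]
        gy = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if abs(u_of(gx, gy) - center) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        u, p = mann_whitney_exact([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments as extreme

    def test_identical_groups_p_one(self):
        u, p = mann_whitney_exact([1.0, 2.0], [1.0, 2.0])
        assert p == 1.0

    @given(
        st.lists(st.integers(0, 8), min_size=2, max_size=5),
        st.lists(st.integers(0, 8), min_size=2, max_size=5),
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_enumeration_oracle_with_ties(self, x, y):
        _, p = mann_whitney_exact(x, y)
        assert p == pytest.approx(mwu_enumeration_oracle(x, y))

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            x = rng.normal(size=4)
            y = rng.normal(size=5)
            _, p = mann_whitney_exact(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert p == pytest.approx(float(ref.pvalue))

    def test_scale_invariance(self):
        x, y = [0.1, 0.5, 0.9], [0.2, 0.4, 1.5]
        u1, p1 = mann_whitney_exact(x, y)
        u2, p2 = mann_whitney_exact([2 * v for v in x], [2 * v for v in y])
        assert (u1, p1) == (u2, p2)

    def test_asymptotic_close_to_exact_at_pooled_12(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(loc=rng.uniform(0, 1.5), size=6)
            _, p_exact = mann_whitney_exact(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            assert abs(p_exact - float(ref.pvalue)) < 0.02


class TestProfileTest:
    def test_identical_groups(self):
        g = np.array([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6]])
        res = profile_test(g, g.copy())
        assert res.p_raw == 1.0
        assert res.method == "exact"

    def test_bonferroni_over_variants(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(2, 3))
        b = rng.normal(loc=3.0, size=(2, 3))
        res = profile_test(a, b, n_variants_in_family=14)
        assert res.p_adjusted == pytest.approx(min(1.0, res.p_raw * 14))

    def test_asymptotic_path_for_large_profiles(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(3, 26))
        b = rng.normal(size=(3, 26))
        res = profile_test(a, b)
        assert res.method == "asymptotic"
        assert 0.0 <= res.p_raw <= 1.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            profile_test(np.empty((0, 3)), np.ones((2, 3)))


class TestAsymmetry:
    def test_mirror_symmetric_profile(self):
        left = np.linspace(0.2, 2.0, 13)
        profile = make_full_profile(np.concatenate([left[::-1], left]))
        res = asymmetry_test(profile)
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_offset_degenerate(self):
        left = np.linspace(0.2, 2.0, 13)
        profile = make_full_profile(np.concatenate([(left + 0.5)[::-1], left]))
        res = asymmetry_test(profile)
        assert res.degenerate and res.p == 0.0 and res.warnings

    def test_power_for_three_sigma_effect(self):
        # Monte-Carlo power oracle: 13 pairs, effect 3x the noise s.d.
        rng = np.random.default_rng(8)
        sd, effect = 0.1, 0.3
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            left = rng.normal(0.5, sd, size=13)  # innermost-first pairs
            right = left + effect + rng.normal(0, sd, size=13)
            log2 = np.concatenate([left[::-1], right])  # full-site order
            res = asymmetry_test(make_full_profile(log2))
            if res.p <= 0.05:
                hits += 1
        assert hits / n_sim > 0.95

    def test_pairing_requires_equal_halves(self):
        prof = make_full_profile(np.zeros(26))
        prof.sides = [Side.LEFT] * 12 + [Side.RIGHT] * 14
        with pytest.raises(ValueError):
            asymmetry_test(prof)


class TestFeatureMatrix:
    def test_shape_and_no_missing_cells(self):
        profs = [make_full_profile(np.random.default_rng(i).normal(size=26))
                 for i in range(3)]
        m = feature_matrix({"wt": profs})
        assert m.shape == (3, 26)
        assert not m.isna().any().any()
        assert list(m.columns) == profs[0].labels

    def test_duplicated_replicates_identical_rows(self):
        p = make_full_profile(np.linspace(-1, 1, 26))
        m = feature_matrix([("a", p), ("b", p)])
        assert m.loc["a"].equals(m.loc["b"])

    def test_euclidean_distances_match_brute_force(self):
        rng = np.random.default_rng(4)
        profs = [make_full_profile(rng.normal(size=26)) for _ in range(4)]
        m = feature_matrix([(f"r{i}", p) for i, p in enumerate(profs)])
        arr = m.to_numpy()
        for i in range(4):
            for j in range(4):
                brute = math.sqrt(sum((arr[i, k] - arr[j, k]) ** 2 for k in range(26)))
                assert np.linalg.norm(arr[i] - arr[j]) == pytest.approx(brute)

    def test_inconsistent_position_sets_error(self):
        p = make_full_profile(np.zeros(26))
        q = make_full_profile(np.zeros(26))
        q.labels = list(q.labels)
        q.labels[0] = "18"
        with pytest.raises(ValueError):
            feature_matrix([("a", p), ("b", q)])

    def test_embedding_is_seeded_and_2d(self):
        rng = np.random.default_rng(6)
        profs = [make_full_profile(rng.normal(size=26)) for _ in range(6)]
        m = feature_matrix([(f"r{i}", p) for i, p in enumerate(profs)])
        e1 = embed_feature_matrix(m, seed=0)
        e2 = embed_feature_matrix(m, seed=0)
        assert e1.shape == (6, 2)
        assert e1 == pytest.approx(e2)


class TestTypeICalibration:
    def test_null_per_position_rate_after_bonferroni(self):
        rng = np.random.default_rng(123)
        n_sim, flagged, total = 500, 0, 0
        for _ in range(n_sim):
            a = rng.normal(0, 0.2, size=(3, 26))
            b = rng.normal(0, 0.2, size=(3, 26))
            res = per_position_test(a, b)
            flagged += int(res.significant.sum())
            total += 26
        assert flagged / total <= 0.05
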