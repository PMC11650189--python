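"""Group inference: GLM power and calibration, effect-size identity, BH-FDR
against a brute-force oracle, cluster permutation, clinical correlations,
paired t tests and network shares."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import fcgrad as fg
from fcgrad.synthdata import NetworkPartition, SubjectRecord


def make_subjects(n_case, n_control, rng, single_sex=False):
    subs = []
    for g, n in (("case", n_case), ("control", n_control)):
        for i in range(n):
            subs.append(
                SubjectRecord(
                    id=f"{g}{i}", group=g, age=float(rng.uniform(10, 30)),
                    sex="M" if (single_sex or rng.random() < 0.5) else "F",
                    fd=0.1,
                )
            )
    return subs


class TestGlmCompare:
    def test_planted_shift_detected(self, rng):
        detected = 0
        for rep in range(40):
            subs = make_subjects(50, 50, rng)
            y = rng.standard_normal((100, 5))
            y[:50, 2] += 1.0  # +1 SD shift at node 2 in cases
            stat = fg.glm_compare(y, subs)
            detected += stat.t[2] > 0 and stat.p[2] < 0.05
        assert detected >= 38  # >= 95% power at d = 1, n = 50/group

    def test_cohens_d_identity(self, rng):
        subs = make_subjects(12, 15, rng)
        y = rng.standard_normal((27, 8))
        stat = fg.glm_compare(y, subs)
        assert np.allclose(np.abs(stat.d), np.abs(stat.t) * np.sqrt(1 / 12 + 1 / 15))
        assert np.all(np.sign(stat.d) == np.sign(stat.t))

    def test_z_is_signed_normal_quantile(self, rng):
        subs = make_subjects(10, 10, rng)
        y = rng.standard_normal((20, 6))
        stat = fg.glm_compare(y, subs)
        expected = np.sign(stat.t) * stats.norm.isf(stat.p / 2)
        assert np.allclose(stat.z, expected)

    def test_identical_y_gives_zero_t(self, rng):
        subs = make_subjects(5, 5, rng)
        y = np.tile(np.arange(4.0), (10, 1)) * 0 + 3.0
        stat = fg.glm_compare(y, subs)
        assert np.all(stat.t == 0)

    def test_strong_age_effect_does_not_inflate_group_fp(self, rng):
        fps = []
        for rep in range(50):
            subs = make_subjects(20, 20, rng)
            age = np.array([s.age for s in subs])
            y = rng.standard_normal((40, 20)) + 0.5 * age[:, None]
            stat = fg.glm_compare(y, subs)
            fps.append(np.mean(stat.p < 0.05))
        assert abs(np.mean(fps) - 0.05) < 0.03

    def test_small_group_rejected(self, rng):
        subs = make_subjects(2, 10, rng)
        with pytest.raises(ValueError):
            fg.glm_compare(np.zeros((12, 3)), subs)


class TestInteraction:
    def test_null_interaction_calibrated(self, rng):
        rejections = []
        for rep in range(60):
            subs = make_subjects(20, 20, rng)
            p = fg.interaction_test(rng.standard_normal((40, 10)), subs)
            rejections.append(np.mean(p < 0.05))
        assert abs(np.mean(rejections) - 0.05) < 0.035

    def test_male_only_effect_detected(self, rng):
        hits = 0
        for rep in range(20):
            subs = make_subjects(100, 100, rng)
            male_case = np.array(
                [s.group == "case" and s.sex == "M" for s in subs], dtype=float
            )
            y = rng.standard_normal((200, 1)) + male_case[:, None] * 1.0
            p = fg.interaction_test(y, subs)
            hits += p[0] < 0.05
        assert hits >= 16  # power > 0.8 at d = 1, n = 100/group

    def test_single_sex_cohort_rejected(self, rng):
        subs = make_subjects(5, 5, rng, single_sex=True)
        with pytest.raises(ValueError):
            fg.interaction_test(np.zeros((10, 2)), subs)


def bh_oracle(p, q):
    """Brute force: largest k with p_(k) <= k q / m; reject the k smallest."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_star]] = True
    return mask


class TestFdrBh:
    def test_hand_computed_example(self):
        mask = fg.fdr_bh(np.array([0.001, 0.02, 0.8]), q=0.05)
        assert list(mask) == [True, True, False]

    def test_all_ones_none_pass(self):
        assert not fg.fdr_bh(np.ones(5)).any()

    def test_single_small_p_passes(self):
        assert fg.fdr_bh(np.array([0.04]), q=0.05)[0]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=10))
    def test_matches_brute_force_oracle(self, p):
        assert list(fg.fdr_bh(np.array(p), q=0.05)) == list(bh_oracle(p, 0.05))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fg.fdr_bh(np.array([]))


def chain_adjacency(n):
    adj = np.zeros((n, n), dtype=int)
    idx = np.arange(n - 1)
    adj[idx, idx + 1] = adj[idx + 1, idx] = 1
    return adj


class TestClusterCorrect:
    def test_planted_contiguous_cluster_detected(self, rng):
        hits = 0
        for rep in range(10):
            subs = make_subjects(50, 50, rng)
            y = rng.standard_normal((100, 40))
            y[:50, 10:20] += 1.5  # planted 10-node contiguous effect
            stat = fg.glm_compare(y, subs)
            res = fg.cluster_correct(stat, y, subs, chain_adjacency(40),
                                     n_perm=200, seed=rep)
            hits += any(
                c.cluster_p < 0.05 and len(set(c.nodes) & set(range(10, 20))) >= 5
                for c in res
            )
        assert hits >= 9

    def test_empty_when_nothing_supra_threshold(self, rng):
        subs = make_subjects(10, 10, rng)
        y = rng.standard_normal((20, 15))
        stat = fg.glm_compare(y, subs)
        res = fg.cluster_correct(stat, y, subs, chain_adjacency(15),
                                 voxel_p=1e-12, n_perm=100, seed=0)
        assert res == []

    def test_low_n_perm_refused_in_strict_mode(self, rng):
        subs = make_subjects(5, 5, rng)
        y = rng.standard_normal((10, 5))
        stat = fg.glm_compare(y, subs)
        with pytest.raises(ValueError):
            fg.cluster_correct(stat, y, subs, chain_adjacency(5), n_perm=50, seed=0)


class TestClinicalCorr:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        r, p = fg.clinical_corr(x, 2 * x)
        assert r == pytest.approx(1.0)

    def test_near_perfect_negative(self, rng):
        x = np.arange(20.0)
        r, _ = fg.clinical_corr(x, -x + rng.normal(0, 0.01, 20))
        assert r == pytest.approx(-1.0, abs=0.01)

    def test_independent_near_zero(self, rng):
        r, _ = fg.clinical_corr(rng.standard_normal(1000), rng.standard_normal(1000))
        assert abs(r) < 0.1

    def test_missing_values_dropped(self):
        x = np.array([1.0, 2, 3, 4, np.nan])
        y = np.array([2.0, 4, 6, 8, 1.0])
        r, _ = fg.clinical_corr(x, y)
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            fg.clinical_corr(np.ones(5), np.arange(5.0))


class TestPairedTtest:
    def test_identical_vectors(self):
        t, p, d = fg.paired_ttest(np.arange(5.0), np.arange(5.0))
        assert t == 0.0 and p == 1.0 and d == 0.0

    def test_power_matches_closed_form(self, rng):
        # diff ~ N(1, 1), n = 15: exact power from the noncentral t
        n, ncp = 15, np.sqrt(15)
        tcrit = stats.t.ppf(0.975, n - 1)
        theory = stats.nct.sf(tcrit, n - 1, ncp) + stats.nct.cdf(-tcrit, n - 1, ncp)
        hits = 0
        reps = 400
        for _ in range(reps):
            post = rng.standard_normal(n)
            pre = post + rng.normal(1, 1, n)
            _, p, _ = fg.paired_ttest(pre, post)
            hits += p < 0.05
        se = np.sqrt(theory * (1 - theory) / reps)
        assert abs(hits / reps - theory) < 4 * se + 0.01

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fg.paired_ttest(np.array([1.0, 2.0]), np.array([2.0, 3.0]))


class TestNetworkShare:
    def test_single_network_full_share(self):
        part = NetworkPartition(labels=["DMN"] * 4 + ["SMN"] * 4)
        mask = np.array([True, True, False, False] + [False] * 4)
        signs = np.ones(8)
        out = fg.network_share(mask, signs, part)
        assert out["increase"]["DMN"] == 1.0
        assert out["increase"]["SMN"] == 0.0

    def test_two_one_split(self):
        part = NetworkPartition(labels=["DMN"] * 4 + ["SMN"] * 4)
        mask = np.array([True, True, False, False, True, False, False, False])
        out = fg.network_share(mask, np.ones(8), part)
        assert out["increase"]["DMN"] == pytest.approx(2 / 3)
        assert out["increase"]["SMN"] == pytest.approx(1 / 3)

    def test_empty_mask_flagged(self):
        part = NetworkPartition(labels=["DMN"] * 5)
        out = fg.network_share(np.zeros(5, bool), np.ones(5), part)
        assert out["increase"]["_empty"] == 1.0
        assert out["increase"]["DMN"] == 0.0
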