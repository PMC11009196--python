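import numpy as np
import pytest

from frailtykit import auc_covariance, auc_weighted, placement_components
from frailtykit import test_auc_equality as auc_equality
from frailtykit import test_auc_equality_joint as auc_equality_joint
from frailtykit.errors import (AlignmentError, DegenerateComparisonError,
                               UndefinedAUCError)


# ---------------------------------------------------------------- oracles
def auc_double_sum(scores, outcome, weights):
    """Brute-force weighted AUC over all event x non-event pairs."""
    s = np.asarray(scores, float)
    y = np.asarray(outcome)
    w = np.asarray(weights, float)
    num = den = 0.0
    for i in np.flatnonzero(y == 1):
        for j in np.flatnonzero(y == 0):
            psi = 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
            num += w[i] * w[j] * psi
            den += w[i] * w[j]
    return num / den


def placements_enumerated(scores, outcome, weights):
    """Definitional per-observation placements (event side, non-event side)."""
    s = np.asarray(scores, float)
    y = np.asarray(outcome)
    w = np.asarray(weights, float)
    ev, ne = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    wn, we = w[ne].sum(), w[ev].sum()
    v10 = np.array([
        sum(w[j] * (1.0 if s[i] > s[j] else 0.5 if s[i] == s[j] else 0.0)
            for j in ne) / wn
        for i in ev])
    v01 = np.array([
        sum(w[i] * (1.0 if s[i] > s[j] else 0.5 if s[i] == s[j] else 0.0)
            for i in ev) / we
        for j in ne])
    return v10, v01


def delong_cov_definitional(score_sets, outcome, weights):
    """Placement-covariance assembly, straight from the definitions."""
    y = np.asarray(outcome)
    w = np.asarray(weights, float)
    w = w / w.mean()
    ev, ne = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    m_w, n_w = w[ev].sum(), w[ne].sum()
    k = len(score_sets)
    V10 = np.array([placements_enumerated(s, y, w)[0] for s in score_sets])
    V01 = np.array([placements_enumerated(s, y, w)[1] for s in score_sets])
    aucs10 = (V10 * w[ev]).sum(axis=1) / m_w
    aucs01 = (V01 * w[ne]).sum(axis=1) / n_w
    d10 = m_w - (w[ev] ** 2).sum() / m_w
    d01 = n_w - (w[ne] ** 2).sum() / n_w
    S10 = np.zeros((k, k))
    S01 = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            S10[a, b] = ((V10[a] - aucs10[a]) * (V10[b] - aucs10[b])
                         * w[ev]).sum() / d10
            S01[a, b] = ((V01[a] - aucs01[a]) * (V01[b] - aucs01[b])
                         * w[ne]).sum() / d01
    return S10 / m_w + S01 / n_w


def random_instance(rng, max_n=12, with_ties=True, with_weights=True):
    n = rng.integers(5, max_n + 1)
    while True:
        y = rng.integers(0, 2, n)
        if 2 <= y.sum() <= n - 2:
            break
    if with_ties:
        s = rng.integers(0, 4, n).astype(float)  # heavy ties
    else:
        s = rng.standard_normal(n)
    w = rng.uniform(0.2, 3.0, n) if with_weights else np.ones(n)
    return s, y, w


# ------------------------------------------------------------------ tests
class TestWeightedAUC:
    def test_perfect_separation(self):
        y = np.array([1, 1, 0, 0])
        res = auc_weighted([5.0, 4.0, 1.0, 0.0], y, [1, 2, 1, 2])
        assert res.auc == 1.0
        assert res.n_events == 2 and res.n_nonevents == 2

    def test_constant_scores_give_half(self):
        res = auc_weighted(np.ones(6), [1, 0, 1, 0, 0, 1], np.ones(6))
        assert res.auc == pytest.approx(0.5)

    def test_eight_observation_weighted_tied_instance(self):
        s = np.array([3.0, 1.0, 2.0, 2.0, 0.0, 2.0, 1.0, 3.0])
        y = np.array([1, 0, 1, 0, 0, 1, 1, 0])
        w = np.array([1.0, 2.0, 0.5, 1.5, 1.0, 2.0, 0.5, 3.0])
        res = auc_weighted(s, y, w)
        assert res.auc == pytest.approx(auc_double_sum(s, y, w))

    def test_matches_double_sum_on_1000_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            s, y, w = random_instance(rng)
            assert auc_weighted(s, y, w).auc == pytest.approx(
                auc_double_sum(s, y, w), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            auc_weighted([1.0, 2.0], [1, 1], [1.0, 1.0])

    def test_ci_within_unit_interval(self):
        rng = np.random.default_rng(5)
        s, y, w = random_instance(rng, max_n=10)
        res = auc_weighted(s, y, w)
        assert 0.0 <= res.ci95[0] <= res.auc <= res.ci95[1] <= 1.0


class TestPlacements:
    def test_perfect_separation_placements_are_one(self):
        v10, v01 = placement_components([4.0, 3.0, 1.0, 0.0], [1, 1, 0, 0])
        assert np.allclose(v10, 1.0)
        assert np.allclose(v01, 1.0)

    def test_unit_weights_match_midrank_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            s, y, _ = random_instance(rng, with_weights=False)
            v10, v01 = placement_components(s, y)
            o10, o01 = placements_enumerated(s, y, np.ones(len(s)))
            assert np.allclose(v10, o10)
            assert np.allclose(1.0 - v01, 1.0 - o01)

    def test_weighted_placement_mean_equals_auc(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            s, y, w = random_instance(rng)
            v10, v01 = placement_components(s, y, w)
            wn = w / w.mean()
            auc = auc_weighted(s, y, w).auc
            assert np.average(v10, weights=wn[y == 1]) == pytest.approx(auc)
            assert np.average(v01, weights=wn[y == 0]) == pytest.approx(auc)


class TestCovariance:
    def test_identical_scores_zero_difference_variance(self):
        rng = np.random.default_rng(3)
        s, y, w = random_instance(rng, max_n=10)
        cov = auc_covariance([s, s], y, w)
        var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
        assert var_diff == pytest.approx(0.0, abs=1e-15)

    def test_classical_unweighted_variance_on_small_instance(self):
        rng = np.random.default_rng(19)
        for _ in range(30):
            s, y, w = random_instance(rng, with_weights=False)
            got = auc_covariance([s], y, w)[0, 0]
            want = delong_cov_definitional([s], y, w)[0, 0]
            assert got == pytest.approx(want, abs=1e-12)

    def test_matches_definitional_weighted_covariance(self):
        rng = np.random.default_rng(29)
        for _ in range(30):
            s1, y, w = random_instance(rng)
            s2 = s1 + rng.standard_normal(len(s1))
            got = auc_covariance([s1, s2], y, w)
            want = delong_cov_definitional([s1, s2], y, w)
            assert np.allclose(got, want, atol=1e-12)
            assert np.allclose(got, got.T)
            assert np.min(np.linalg.eigvalsh(got)) > -1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            auc_covariance([[1.0, 2.0, 3.0], [1.0, 2.0]], [1, 0, 1])

    def test_variance_tracks_bootstrap(self):
        # 2,000-replicate bootstrap oracle on one fixed simulated pair
        rng = np.random.default_rng(2024)
        n = 2000
        u = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1.5 + u)))).astype(int)
        s1 = u + rng.standard_normal(n)
        s2 = 0.7 * u + rng.standard_normal(n)
        w = rng.uniform(0.5, 2.0, n)
        cov = auc_covariance([s1, s2], y, w)
        var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
        boots = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if 0 < y[idx].sum() < n:
                a1 = auc_weighted(s1[idx], y[idx], w[idx]).auc
                a2 = auc_weighted(s2[idx], y[idx], w[idx]).auc
                boots.append(a1 - a2)
        boot_var = np.var(boots, ddof=1)
        assert abs(var_diff - boot_var) / boot_var < 0.15


class TestEqualityTest:
    def test_identical_scores_degenerate_to_p_one(self):
        s = np.array([3.0, 1.0, 2.0, 0.0, 4.0])
        y = np.array([1, 0, 1, 0, 1])
        cmp_res = auc_equality(s, s, y)
        assert cmp_res.chi2 == 0.0 and cmp_res.p_value == 1.0

    def test_zero_variance_unequal_aucs_is_error(self):
        # both scores separate perfectly but in opposite directions, so the
        # placements are constant (zero variance) while the AUCs differ
        y = np.array([1, 1, 0, 0])
        with pytest.raises(DegenerateComparisonError):
            auc_equality([2.0, 2.0, 1.0, 1.0], [1.0, 1.0, 2.0, 2.0], y)

    def test_scale_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(31)
        n = 300
        s1 = rng.standard_normal(n)
        s2 = rng.standard_normal(n)
        y = (rng.random(n) < 0.3).astype(int)
        w = rng.uniform(0.5, 2, n)
        base = auc_equality(s1, s2, y, w)
        mono = auc_equality(np.exp(s1), np.tanh(s2) + 5, y, w)
        assert mono.auc_a == pytest.approx(base.auc_a)
        assert mono.chi2 == pytest.approx(base.chi2)

    def test_complement_symmetry_under_joint_negation(self):
        rng = np.random.default_rng(37)
        n = 200
        s1, s2 = rng.standard_normal(n), rng.standard_normal(n)
        y = (rng.random(n) < 0.4).astype(int)
        base = auc_equality(s1, s2, y)
        neg = auc_equality(-s1, -s2, y)
        assert neg.auc_a == pytest.approx(1.0 - base.auc_a)
        assert neg.auc_b == pytest.approx(1.0 - base.auc_b)
        assert neg.chi2 == pytest.approx(base.chi2, rel=1e-9)

    def test_weight_homogeneity(self):
        rng = np.random.default_rng(41)
        n = 150
        s1, s2 = rng.standard_normal(n), rng.standard_normal(n)
        y = (rng.random(n) < 0.4).astype(int)
        w = rng.uniform(0.5, 2, n)
        a = auc_equality(s1, s2, y, w)
        b = auc_equality(s1, s2, y, 7.3 * w)
        assert a.auc_a == pytest.approx(b.auc_a)
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-9)

    def test_type_one_error_at_nominal_level(self):
        # null: two equally informative, correlated scores
        rng = np.random.default_rng(99)
        n, reps = 400, 2000
        rejections = 0
        for _ in range(reps):
            u = rng.standard_normal(n)
            y = (rng.random(n) < 1 / (1 + np.exp(-(-1.5 + u)))).astype(int)
            if not 0 < y.sum() < n:
                continue
            s1 = u + rng.standard_normal(n)
            s2 = u + rng.standard_normal(n)
            if auc_equality(s1, s2, y).p_value < 0.05:
                rejections += 1
        rate = rejections / reps
        assert abs(rate - 0.05) < 0.015

    def test_power_increases_with_n(self):
        rng = np.random.default_rng(55)
        rates = []
        for n in (80, 250, 800):
            rej = 0
            reps = 200
            for _ in range(reps):
                u = rng.standard_normal(n)
                y = (rng.random(n) < 1 / (1 + np.exp(-(-1 + u)))).astype(int)
                if not 1 < y.sum() < n - 1:
                    continue
                s1 = u + 2.0 * rng.standard_normal(n)  # mildly informative
                s2 = rng.standard_normal(n)            # noise
                if auc_equality(s1, s2, y).p_value < 0.05:
                    rej += 1
            rates.append(rej / reps)
        assert rates[0] < rates[1] < rates[2]

    def test_joint_test_reduces_to_pairwise(self):
        rng = np.random.default_rng(61)
        n = 300
        s1, s2 = rng.standard_normal(n), rng.standard_normal(n)
        y = (rng.random(n) < 0.3).astype(int)
        pair = auc_equality(s1, s2, y)
        chi2, df, p = auc_equality_joint([s1, s2], y)
        assert df == 1
        assert chi2 == pytest.approx(pair.chi2, rel=1e-9)
        assert p == pytest.approx(pair.p_value, rel=1e-9)
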