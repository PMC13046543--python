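import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dynetfnc import stats, synthdata as sd, tdfnc


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p = stats.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_value(self):
        # pooled t for [1,2,3] vs [4,5,6]: mean diff -3, s_p=1, se=1*sqrt(2/3)
        t, p = stats.two_sample_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3 / np.sqrt(2.0 / 3.0), abs=1e-9)  # -3.674...
        from scipy.stats import t as tdist

        assert p == pytest.approx(2 * tdist.sf(abs(t), 4), abs=1e-12)

    def test_antisymmetry(self):
        t1, p1 = stats.two_sample_t([1, 2, 4], [2, 5, 6])
        t2, p2 = stats.two_sample_t([2, 5, 6], [1, 2, 4])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            stats.two_sample_t([1.0], [2.0, 3.0])


class TestMannWhitney:
    def test_enumeration_example(self):
        U, p = stats.mann_whitney_u([1, 2], [3, 4])
        assert U == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_multisets(self):
        U, p = stats.mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert U == pytest.approx(9 / 2)
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self):
        """Exact p equals brute-force enumeration over all group assignments
        for every tie-free a, b with combined n <= 8."""
        rng = np.random.default_rng(0)
        for n1, n2 in [(2, 2), (3, 3), (2, 5), (4, 4), (3, 5)]:
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            a, b = pooled[:n1], pooled[n1:]
            U_obs, p_obs = stats.mann_whitney_u(a, b)
            # enumeration oracle: U statistic for every split of the ranks
            ranks = np.argsort(np.argsort(np.concatenate([a, b]))) + 1
            all_idx = set(range(n1 + n2))
            us = []
            for comb in itertools.combinations(range(n1 + n2), n1):
                r1 = ranks[list(comb)].sum()
                us.append(r1 - n1 * (n1 + 1) / 2)
            us = np.array(us)
            u_lo = min(U_obs, n1 * n2 - U_obs)
            p_exact = (np.sum(us <= u_lo) + np.sum(us >= n1 * n2 - u_lo)) / us.size
            assert p_obs == pytest.approx(min(1.0, p_exact), abs=1e-12)

    def test_exact_and_normal_branches_agree(self):
        rng = np.random.default_rng(1)
        diffs = []
        for _ in range(20):
            a = rng.standard_normal(10)
            b = rng.standard_normal(10) + 0.5
            _, p_exact = stats.mann_whitney_u(a, b, exact_max_n=20)
            _, p_norm = stats.mann_whitney_u(a, b, exact_max_n=0)
            diffs.append(abs(p_exact - p_norm))
        assert max(diffs) < 0.02

    def test_agrees_with_scipy(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(2)
        a = rng.standard_normal(8)
        b = rng.standard_normal(6) + 1
        U, p = stats.mann_whitney_u(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert U == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestFdrBH:
    def test_hand_computed_example(self):
        q, rej = stats.fdr_bh([0.01, 0.02, 0.03], alpha=0.05)
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03])
        assert rej.all()

    def test_single_p_passthrough(self):
        q, rej = stats.fdr_bh([0.04])
        assert q[0] == pytest.approx(0.04)
        assert rej[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.fdr_bh([0.5, 1.5])

    def test_q_at_least_p_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q, _ = stats.fdr_bh(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_matches_brute_force_step_up_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(3, 40))
            alpha = 0.05
            q, rej = stats.fdr_bh(p, alpha)
            # brute force: largest k with p_(k) <= k*alpha/m
            m = p.size
            ps = np.sort(p)
            ks = np.flatnonzero(ps <= (np.arange(1, m + 1) * alpha / m))
            n_rej = (ks[-1] + 1) if ks.size else 0
            assert rej.sum() == n_rej
            sm_rej, sm_q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
            np.testing.assert_allclose(q, sm_q, atol=1e-12)
            # statsmodels rejects at q <= alpha; ours at q < alpha — compare on
            # the brute-force count instead of flags
            assert rej.sum() == n_rej

    def test_realized_fdr_controlled_under_uniform_null(self):
        rng = np.random.default_rng(2)
        fdp = []
        for _ in range(100):
            p = rng.uniform(size=500)
            _, rej = stats.fdr_bh(p, alpha=0.05)
            fdp.append(rej.mean() > 0)  # all nulls: FDP is 1 if anything rejected
        margin = 2 * np.sqrt(0.05 * 0.95 / 100)
        assert np.mean(fdp) <= 0.05 + margin


def _simulate_groups(seed, delta=0.0, n_per_group=12, snr=5.0):
    covs = sd.generate_state_covariances(4, 3, rho=0.3, seed=2)
    covs_ts = [c.copy() for c in covs]
    if delta:
        C = covs_ts[1]
        C[0, 1] = C[1, 0] = np.clip(C[0, 1] + delta, -0.9, 0.9)
        covs_ts[1] = sd._nearest_unit_spd(C)
    rng = np.random.default_rng(seed)
    wfnc, groups, true_win = {}, {}, {}
    for m in range(2 * n_per_group):
        grp = "TS" if m < n_per_group else "N"
        cv = covs_ts if grp == "TS" else covs
        tc, seq = sd.generate_state_timecourses(192, cv, 40, seed=int(rng.integers(2**31)))
        tc = tc + rng.normal(0, np.sqrt(tc.var() / snr), tc.shape)
        wf = tdfnc.sliding_window_fnc(tc, 18, 1)
        sid = f"s{m:02d}"
        wfnc[sid], groups[sid] = wf, grp
        true_win[sid] = np.array(
            [np.bincount(seq[s : s + 18]).argmax() for s in wf.window_start_indices]
        )
    return wfnc, groups, true_win


class TestCompareStateFnc:
    def test_default_min_windows_is_10(self):
        import inspect

        sig = inspect.signature(stats.compare_state_fnc)
        assert sig.parameters["min_windows"].default == 10

    def test_planted_state_effect_detected(self):
        from scipy.optimize import linear_sum_assignment

        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            wfnc, groups, true_win = _simulate_groups(300 + rep, delta=0.5)
            model = tdfnc.cluster_states(wfnc, k=3, seed=rep)
            conf = np.zeros((3, 3))
            for sid in wfnc:
                for a, t in zip(model.assignments[sid], true_win[sid]):
                    conf[a, t - 1] += 1
            ri, ci = linear_sum_assignment(-conf)
            cl = ri[list(ci).index(1)]  # cluster matched to planted state 2
            results, _ = stats.compare_state_fnc(model, wfnc, groups)
            if cl in results:
                res = results[cl]
                hits += bool(res.significant[res.edges.index((0, 1))])
        assert hits / n_rep >= 0.8

    def test_null_is_calibrated(self):
        rejections = edges = 0
        for rep in range(8):
            wfnc, groups, _ = _simulate_groups(900 + rep, delta=0.0)
            model = tdfnc.cluster_states(wfnc, k=3, seed=rep)
            results, _ = stats.compare_state_fnc(model, wfnc, groups)
            for res in results.values():
                rejections += res.significant.sum()
                edges += res.significant.size
        se = 2 * np.sqrt(0.05 / edges)
        assert rejections / edges <= 0.05 + se

    def test_small_state_skipped_with_reason(self):
        wfnc, groups, _ = _simulate_groups(5, delta=0.0, n_per_group=3)
        model = tdfnc.cluster_states(wfnc, k=3, seed=0)
        # absurd membership rule: no subject can qualify
        results, skipped = stats.compare_state_fnc(model, wfnc, groups, min_windows=1000)
        assert not results
        assert all("need 2 per group" in reason for reason in skipped.values())

    def test_q_never_below_p(self):
        wfnc, groups, _ = _simulate_groups(7, delta=0.3)
        model = tdfnc.cluster_states(wfnc, k=2, seed=1)
        results, _ = stats.compare_state_fnc(model, wfnc, groups)
        for res in results.values():
            assert np.all(res.q_fdr >= res.p_raw - 1e-12)
            np.testing.assert_array_equal(res.significant, res.q_fdr < res.alpha)


class TestCorrelateClinical:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        c = stats.correlate_clinical(x, 2 * x + 1)
        assert c.r == pytest.approx(1.0)

    def test_planted_clinical_correlation_power(self):
        rng = np.random.default_rng(0)
        hits = 0
        est = []
        n_rep = 100
        for _ in range(n_rep):
            x = rng.standard_normal(12)
            y = 0.7 * (x - x.mean()) / x.std() + np.sqrt(1 - 0.49) * rng.standard_normal(12)
            c = stats.correlate_clinical(x, y)
            est.append(c.r)
            hits += c.p < 0.05
        assert hits / n_rep >= 0.6
        assert abs(np.mean(est) - 0.7) < 0.25

    def test_permutation_null_calibrated(self):
        rng = np.random.default_rng(1)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            x = rng.standard_normal(12)
            y = rng.permutation(x)
            hits += stats.correlate_clinical(x, y).p < 0.05
        assert hits / n_rep <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            stats.correlate_clinical(np.ones(5), np.arange(5.0))


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
@settings(max_examples=50, deadline=None)
def test_bh_properties_hold_for_arbitrary_p(p):
    q, rej = stats.fdr_bh(p, alpha=0.05)
    assert np.all(q >= np.asarray(p) - 1e-12)
    assert np.all((q >= 0) & (q <= 1))
    np.testing.assert_array_equal(rej, q < 0.05)
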