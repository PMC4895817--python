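import numpy as np
import pytest

from curebag import ImproperNullFit, score_and_variance, split_candidates
from curebag.splitting import NodeWorkspace


def double_loop_uv(time, event, risk, omega, z):
    """Literal double-summation of the score and robust variance displays."""
    m = len(time)

    def s0(t):
        return sum(risk[j] for j in range(m) if time[j] >= t)

    def rbar(t):
        return sum(risk[j] * z[j] for j in range(m) if time[j] >= t) / s0(t)

    U = sum(event[i] * omega[i] * (z[i] - rbar(time[i])) for i in range(m))
    V = 0.0
    for i in range(m):
        lead = event[i] * omega[i] * (z[i] - rbar(time[i]))
        inner = sum(
            omega[l] * risk[i] / s0(time[l]) * (z[i] - rbar(time[l]))
            for l in range(m)
            if event[l] and time[i] >= time[l]
        )
        V += (lead - inner) ** 2
    return U, V


def workspace_omega_in_row_order(ws):
    om = np.empty(ws.m)
    om[ws.order] = ws.omega
    return om


class TestScoreAndVariance:
    def test_constant_membership_is_degenerate(self, three_event_data):
        st = score_and_variance(three_event_data, [1, 1, 1])
        assert st.U == pytest.approx(0.0)
        assert st.S == 0.0 and st.degenerate

    def test_logrank_hand_example(self, three_event_data):
        st = score_and_variance(three_event_data, [1, 0, 0], criterion="logrank")
        assert st.U == pytest.approx(2 / 3)
        assert st.K == 3

    def test_matches_double_loop_oracle(self, random_dataset):
        rng = np.random.default_rng(1)
        for rep in range(20):
            ds = random_dataset(
                n=int(rng.integers(6, 21)), m1=1, seed=rep, tie_decimals=1
            )
            fit = ImproperNullFit.fit(ds)
            z = rng.integers(0, 2, ds.n).astype(float)
            for crit in ("logrank", "pseudoR2"):
                st = score_and_variance(ds, z, fit, criterion=crit)
                ws = NodeWorkspace(ds.time, ds.event, fit.risk_scores, crit)
                U, V = double_loop_uv(
                    ds.time, ds.event, fit.risk_scores,
                    workspace_omega_in_row_order(ws), z,
                )
                assert st.U == pytest.approx(U, abs=1e-10)
                assert st.V == pytest.approx(V, abs=1e-10)

    def test_huge_theta_recovers_adjusted_logrank(self, random_dataset):
        for seed in range(5):
            ds = random_dataset(n=40, m1=1, seed=seed)
            fit = ImproperNullFit.fit(ds)
            z = np.random.default_rng(seed).integers(0, 2, ds.n)
            a = score_and_variance(ds, z, fit, "pseudoR2", theta_override=1e12)
            b = score_and_variance(ds, z, fit, "logrank")
            assert a.U == pytest.approx(b.U, abs=1e-6)
            assert a.V == pytest.approx(b.V, abs=1e-6)
            assert a.S == pytest.approx(b.S, abs=1e-6)

    def test_label_swap_leaves_s_invariant(self, random_dataset):
        ds = random_dataset(n=30, seed=11)
        fit = ImproperNullFit.fit(ds)
        z = np.random.default_rng(0).integers(0, 2, ds.n)
        a = score_and_variance(ds, z, fit)
        b = score_and_variance(ds, 1 - z, fit)
        assert b.U == pytest.approx(-a.U, abs=1e-12)
        assert b.S == pytest.approx(a.S, abs=1e-12)

    def test_s_bounded_unit_interval(self, random_dataset):
        for seed in range(10):
            ds = random_dataset(n=15, seed=seed, censor_frac=0.2)
            fit = ImproperNullFit.fit(ds)
            z = np.random.default_rng(seed).integers(0, 2, ds.n)
            st = score_and_variance(ds, z, fit)
            assert 0.0 <= st.S <= 1.0

    def test_no_censoring_matches_plain_logrank_chi2(self):
        """With omega = 1 and unit risk scores, U^2/V is a robust log-rank
        statistic; check U (O-E) against lifelines' log-rank machinery."""
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(3)
        n = 60
        t = rng.exponential(1, n)
        d = np.ones(n, dtype=int)
        z = rng.integers(0, 2, n)
        ws = NodeWorkspace(t, d, np.ones(n), "logrank")
        st = ws.score(z.astype(float))
        ref = logrank_test(t[z == 1], t[z == 0], d[z == 1], d[z == 0])
        assert st.U**2 / st.V == pytest.approx(ref.test_statistic, rel=0.15)


class TestSplitCandidates:
    def test_binary_column_single_candidate(self):
        cands = split_candidates(np.array([0.0, 1.0, 0.0, 1.0]))
        assert len(cands) == 1
        thr, member = cands[0]
        assert thr == pytest.approx(0.5)
        np.testing.assert_array_equal(member, [1, 0, 1, 0])

    def test_constant_column_empty(self):
        assert split_candidates(np.full(5, 3.0)) == []

    def test_midpoint_rule(self):
        cands = split_candidates(np.array([1.0, 2.0, 4.0]))
        assert [thr for thr, _ in cands] == pytest.approx([1.5, 3.0])

    def test_threshold_cap(self):
        x = np.arange(100, dtype=float)
        cands = split_candidates(x, max_thresholds=32)
        assert len(cands) <= 32

    def test_child_size_constraints_drop_candidates(self):
        x = np.array([0.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        ev = np.array([1, 1, 1, 1, 1, 1])
        assert split_candidates(x, ev, min_node=2) == []
        assert len(split_candidates(x, ev, min_node=1)) == 1

    def test_monotone_transform_invariance(self, random_dataset):
        ds = random_dataset(n=25, m1=0, seed=8)
        fit = ImproperNullFit.fit(ds)
        rng = np.random.default_rng(8)
        x = rng.normal(size=ds.n)
        stats = {}
        for transform in (lambda v: v, np.exp, lambda v: v**3):
            memberships = [m for _, m in split_candidates(transform(x))]
            stats[transform] = [
                score_and_variance(ds, m, fit).S for m in memberships
            ]
        base = stats[list(stats)[0]]
        for other in list(stats.values())[1:]:
            assert other == pytest.approx(base, abs=1e-12)
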