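import itertools

import numpy as np
import pytest
from scipy import stats

from curebag import (
    ScenarioConfig,
    calibrate_censoring,
    correlated_noise,
    leaf_gamma,
    scenario_config,
    simulate_scenario,
)


class TestLeafGamma:
    @pytest.mark.parametrize(
        "pattern,leaf,gamma",
        [
            ((0, 0, 0, 0), 1, 0.6),
            ((0, 1, 1, 1), 2, 1.8),
            ((1, 0, 0, 1), 3, 0.45),
            ((1, 1, 1, 0), 4, 0.35),
            ((1, 1, 1, 1), 5, 2.0),
        ],
    )
    def test_mapping(self, pattern, leaf, gamma):
        assert leaf_gamma(*pattern) == (leaf, gamma)

    def test_partition_is_exhaustive_and_disjoint(self):
        counts = {k: 0 for k in range(1, 6)}
        for pattern in itertools.product((0, 1), repeat=4):
            leaf, _ = leaf_gamma(*pattern)
            counts[leaf] += 1
        assert sum(counts.values()) == 16
        assert all(v > 0 for v in counts.values())


class TestSimulateScenario:
    def test_reference_group_nonsusceptible_fraction(self):
        cfg = ScenarioConfig(n=50_000, plateau=0.25, censor_target=0.1, n_noise=1, seed=0)
        sim = simulate_scenario(cfg, censoring_rate=0.38)
        g1 = sim.dataset.confounders[:, 0]
        frac = (~sim.truth.susceptible[g1 == 0]).mean()
        assert frac == pytest.approx(0.25, abs=0.01)

    def test_nonsusceptible_rows_always_censored(self):
        cfg = ScenarioConfig(n=5000, plateau=0.4, censor_target=0.2, n_noise=1, seed=1)
        sim = simulate_scenario(cfg, censoring_rate=0.6)
        ns = ~sim.truth.susceptible.to_numpy()
        assert np.all(sim.dataset.event[ns] == 0)
        assert np.all(np.isinf(sim.truth.true_time[ns]))
        assert np.all(np.isfinite(sim.dataset.time))

    def test_small_theta_limit_is_exponential(self):
        """As theta' -> 0 (plateau -> 1) the conditional susceptible event
        time tends to Exponential(lambda0 e^g): the bounded hazard
        theta'(1 - e^{-lambda0 t e^g}) is then proportional to the
        exponential CDF."""
        cfg = ScenarioConfig(n=50_000, plateau=0.9999, censor_target=0.0, n_noise=1, seed=2)
        sim = simulate_scenario(cfg, censoring_rate=0.0)
        leaf5 = (sim.truth.leaf == 5) & sim.truth.susceptible
        t = sim.truth.true_time[leaf5]
        ks = stats.kstest(t, "expon", args=(0, 1 / np.exp(2.0)))
        assert ks.pvalue > 0.01

    def test_conditional_distribution_matches_closed_form(self):
        """Susceptible leaf-5 event times follow
        F(t) = (1 - exp(-theta'(1 - e^{-lambda0 t e^{g5}}))) / (1 - exp(-theta'))."""
        cfg = ScenarioConfig(n=100_000, plateau=0.25, censor_target=0.0, n_noise=1, seed=3)
        sim = simulate_scenario(cfg, censoring_rate=0.0)
        theta = cfg.theta
        for g1_val in (0, 1):
            sel = (
                (sim.truth.leaf == 5)
                & sim.truth.susceptible
                & (sim.dataset.confounders[:, 0] == g1_val)
            )
            t = np.sort(sim.truth.true_time[sel].to_numpy())
            tp = theta * cfg.exp_alpha**g1_val

            def cdf(x):
                return (1 - np.exp(-tp * (1 - np.exp(-x * np.exp(2.0))))) / (
                    1 - np.exp(-tp)
                )

            ks = stats.kstest(t, cdf)
            assert ks.pvalue > 0.01

    def test_km_plateau_near_marginal_cure_fraction(self):
        from lifelines import KaplanMeierFitter

        cfg = ScenarioConfig(n=20_000, plateau=0.25, censor_target=0.10, n_noise=1, seed=4)
        sim = simulate_scenario(cfg, censoring_rate=0.3792)
        kmf = KaplanMeierFitter().fit(sim.dataset.time, sim.dataset.event)
        marginal = (~sim.truth.susceptible).mean()
        tail = kmf.survival_function_.iloc[:, 0].to_numpy()[-1]
        assert tail == pytest.approx(marginal, abs=0.05)


class TestCalibrateCensoring:
    def test_zero_target_no_censoring_of_susceptibles(self):
        cfg = ScenarioConfig(n=2000, plateau=0.25, censor_target=0.0, n_noise=1, seed=5)
        assert calibrate_censoring(cfg) == 0.0
        sim = simulate_scenario(cfg, censoring_rate=0.0)
        sus = sim.truth.susceptible.to_numpy()
        assert np.all(sim.dataset.event[sus] == 1)

    def test_rate_reproduces_target(self):
        cfg = ScenarioConfig(n=100_000, plateau=0.25, censor_target=0.10, n_noise=1, seed=6)
        rate = calibrate_censoring(cfg)
        sim = simulate_scenario(cfg, censoring_rate=rate)
        sus = sim.truth.susceptible.to_numpy()
        realized = (sim.dataset.event[sus] == 0).mean()
        assert realized == pytest.approx(0.10, abs=0.005)

    def test_time_scale_equivariance(self):
        cfg1 = ScenarioConfig(n=10, plateau=0.25, censor_target=0.10, n_noise=1)
        cfg2 = ScenarioConfig(n=10, plateau=0.25, censor_target=0.10, n_noise=1, lambda0=2.0)
        assert calibrate_censoring(cfg2) == pytest.approx(
            2 * calibrate_censoring(cfg1), rel=1e-6
        )


class TestCorrelatedNoise:
    def test_single_block_zero_correlation_is_iid(self):
        rng = np.random.default_rng(0)
        cols = correlated_noise([4], 50_000, rng, corr_range=(0.0, 0.0))
        corr = np.corrcoef(cols.T)
        off = corr[np.triu_indices(4, 1)]
        np.testing.assert_allclose(off, 0.0, atol=0.02)
        np.testing.assert_allclose(cols.mean(axis=0), 0.5, atol=0.01)

    def test_latent_correlation_materializes(self):
        rng = np.random.default_rng(1)
        cols = correlated_noise([2], 100_000, rng, corr_range=(0.3, 0.3))
        emp = np.corrcoef(cols.T)[0, 1]
        # binary correlation after median thresholding: (2/pi) arcsin(rho)
        expected = 2 / np.pi * np.arcsin(0.3)
        assert emp == pytest.approx(expected, abs=0.03)

    def test_cross_block_independence(self):
        rng = np.random.default_rng(2)
        cols = correlated_noise([3, 3], 100_000, rng, corr_range=(0.3, 0.3))
        cross = np.corrcoef(cols.T)[:3, 3:]
        np.testing.assert_allclose(cross, 0.0, atol=0.02)

    def test_scenario_with_correlated_blocks(self):
        cfg = ScenarioConfig(
            n=500, plateau=0.25, censor_target=0.10, n_noise=20,
            correlated=[4, 4, 4, 4, 4], seed=7,
        )
        sim = simulate_scenario(cfg, censoring_rate=0.3792)
        assert sim.dataset.m2 == 24  # G2..G5 + 20 correlated noise columns


class TestScenarioTable:
    @pytest.mark.parametrize(
        "num,n,plateau,cens",
        [(1, 250, 0.25, 0.10), (4, 250, 0.50, 0.25), (5, 500, 0.25, 0.10), (8, 500, 0.50, 0.25)],
    )
    def test_presets(self, num, n, plateau, cens):
        cfg = scenario_config(num)
        assert (cfg.n, cfg.plateau, cfg.censor_target) == (n, plateau, cens)
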