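import numpy as np
import pytest

from curebag import ScenarioConfig, SurvivalDataset, simulate_scenario


@pytest.fixture
def three_event_data():
    """Times (1,2,3), all events, one binary candidate, no confounders."""
    return SurvivalDataset(
        time=[1.0, 2.0, 3.0],
        event=[1, 1, 1],
        confounders=np.empty((3, 0)),
        candidates=np.array([[1.0], [0.0], [0.0]]),
        candidate_names=["x"],
    )


@pytest.fixture
def random_dataset():
    """Factory for random right-censored datasets with confounders."""

    def make(n=30, m1=1, m2=2, seed=0, tie_decimals=None, censor_frac=0.4):
        rng = np.random.default_rng(seed)
        z1 = rng.normal(0, 0.5, (n, m1)) if m1 else np.empty((n, 0))
        z2 = rng.integers(0, 2, (n, m2)).astype(float)
        t = rng.exponential(1.0, n)
        if tie_decimals is not None:
            t = np.round(t, tie_decimals) + 10.0 ** (-tie_decimals - 2)
        d = (rng.random(n) > censor_frac).astype(int)
        if d.sum() == 0:
            d[0] = 1
        return SurvivalDataset(
            time=t, event=d, confounders=z1, candidates=z2,
            candidate_names=[f"x{j}" for j in range(m2)],
        )

    return make


@pytest.fixture(scope="session")
def scenario1a():
    """One scenario-1a replicate (n=250, 10 noise variables) with the
    censoring rate fixed at its calibrated value for speed."""
    cfg = ScenarioConfig(n=250, plateau=0.25, censor_target=0.10, n_noise=10, seed=42)
    return simulate_scenario(cfg, censoring_rate=0.3792)
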