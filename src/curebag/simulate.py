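"""Synthetic data generator: an improper survival tree with a cured fraction.

Rows are generated from the bounded-cumulative-hazard model

    S(t | G1; G2..G5) = exp{ -theta e^{alpha G1} [1 - exp(-lambda0 t e^{g})] },

where g = g(gamma, G2..G5) assigns one of five log-hazard levels through a
binary tree on G2..G5 (G2=0: split on G3; G2=1: split on G4 then G5).  The
binary confounder G1 shifts the plateau: a row is nonsusceptible (latent
event time infinite) with probability exp(-theta'), theta' = theta e^{alpha G1},
and theta is anchored so that exp(-theta) equals the nonsusceptible
proportion of the reference group G1=0.  Susceptible event times are drawn
by inverting the conditional distribution in closed form.  Censoring is
exponential with the rate calibrated (by quadrature over the ten
(G1, leaf) strata) to a target censoring proportion among susceptibles.

Noise candidates are independent Bernoulli(0.5), or blocks of correlated
binaries obtained by thresholding a Gaussian copula at its median.

Default parameter values: exp(alpha) = 1.25, lambda0 = 1,
gamma = (0.6, 1.8, 0.45, 0.35, 2), Bernoulli rates
nu = (0.5, 0.6, 0.5, 0.3, 0.65) for G1..G5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .data import SurvivalDataset

__all__ = [
    "ScenarioConfig",
    "SimulatedDataset",
    "leaf_gamma",
    "simulate_scenario",
    "calibrate_censoring",
    "correlated_noise",
    "scenario_config",
]

GAMMA = (0.6, 1.8, 0.45, 0.35, 2.0)
NU = (0.5, 0.6, 0.5, 0.3, 0.65)
EXP_ALPHA = 1.25
LAMBDA0 = 1.0


@dataclass
class ScenarioConfig:
    n: int = 250
    plateau: float = 0.25           # nonsusceptible proportion, reference group G1=0
    censor_target: float = 0.10     # censoring proportion among susceptibles
    n_noise: int = 10
    correlated: list[int] | None = None   # block sizes summing to n_noise
    corr_range: tuple[float, float] = (-0.2, 0.3)
    seed: int = 0
    exp_alpha: float = EXP_ALPHA
    lambda0: float = LAMBDA0
    gamma: tuple = GAMMA
    nu: tuple = NU

    def __post_init__(self):
        if not 0 < self.plateau < 1:
            raise ValueError("plateau must be in (0, 1)")
        if not 0 <= self.censor_target < 1:
            raise ValueError("censor_target must be in [0, 1)")
        if len(self.gamma) != 5 or len(self.nu) != 5:
            raise ValueError("gamma and nu must have length 5")
        if self.correlated is not None and sum(self.correlated) != self.n_noise:
            raise ValueError("correlated block sizes must sum to n_noise")

    @property
    def theta(self) -> float:
        return -np.log(self.plateau)


@dataclass
class SimulatedDataset:
    dataset: SurvivalDataset
    truth: pd.DataFrame            # susceptible, leaf, true_time per row
    censoring_rate: float


def scenario_config(number: int, n_noise: int = 10, seed: int = 0, **kw) -> ScenarioConfig:
    """The eight tabulated scenarios: 1–4 at n=250, 5–8 at n=500, crossing
    a population plateau of 25/50% with 10/25% censoring among susceptibles."""
    table = {
        1: (250, 0.25, 0.10), 2: (250, 0.25, 0.25),
        3: (250, 0.50, 0.10), 4: (250, 0.50, 0.25),
        5: (500, 0.25, 0.10), 6: (500, 0.25, 0.25),
        7: (500, 0.50, 0.10), 8: (500, 0.50, 0.25),
    }
    n, plateau, censoring = table[number]
    return ScenarioConfig(n=n, plateau=plateau, censor_target=censoring,
                          n_noise=n_noise, seed=seed, **kw)


def leaf_gamma(g2, g3, g4, g5, gamma=GAMMA):
    """Leaf index (1..5) and log-hazard level for one G2..G5 pattern."""
    if g2 == 0:
        leaf = 1 if g3 == 0 else 2
    elif g4 == 0:
        leaf = 3
    else:
        leaf = 4 if g5 == 0 else 5
    return leaf, gamma[leaf - 1]


def _leaf_index(G: np.ndarray) -> np.ndarray:
    """Vectorized leaf assignment from columns (G2, G3, G4, G5)."""
    g2, g3, g4, g5 = G.T
    leaf = np.where(g2 == 0, np.where(g3 == 0, 1, 2),
                    np.where(g4 == 0, 3, np.where(g5 == 0, 4, 5)))
    return leaf


def _strata(cfg: ScenarioConfig):
    """(weight, theta', e^g) for the ten (G1, leaf) strata."""
    nu = cfg.nu
    p_leaf = np.array([
        (1 - nu[1]) * (1 - nu[2]),
        (1 - nu[1]) * nu[2],
        nu[1] * (1 - nu[3]),
        nu[1] * nu[3] * (1 - nu[4]),
        nu[1] * nu[3] * nu[4],
    ])
    out = []
    for g1, p_g1 in ((0, 1 - nu[0]), (1, nu[0])):
        theta_p = cfg.theta * cfg.exp_alpha ** g1
        for leaf in range(5):
            out.append((p_g1 * p_leaf[leaf], theta_p, np.exp(cfg.gamma[leaf])))
    return out


def calibrate_censoring(cfg: ScenarioConfig) -> float:
    """Exponential censoring rate giving P(C < T | susceptible) = target.

    P(C < T | stratum, susceptible) = E[1 - exp(-rho T)] is computed by
    quadrature of the conditional event-time density in each (G1, leaf)
    stratum and averaged with the susceptible-stratum weights; the rate is
    found by bracketing root search (monotone in rho).
    """
    if cfg.censor_target == 0:
        return 0.0
    strata = _strata(cfg)
    weights = np.array([w * (1 - np.exp(-tp)) for w, tp, _ in strata])
    weights = weights / weights.sum()

    def prob_censored(rho):
        total = 0.0
        for w, (_, theta_p, eg) in zip(weights, strata):
            denom = 1 - np.exp(-theta_p)
            rate = cfg.lambda0 * eg

            def dens(t):
                e = np.exp(-rate * t)
                return theta_p * rate * e * np.exp(-theta_p * (1 - e)) / denom

            val, _ = integrate.quad(lambda t: (1 - np.exp(-rho * t)) * dens(t),
                                    0, np.inf, limit=200)
            total += w * val
        return total

    lo, hi = 1e-10, 1.0
    while prob_censored(hi) < cfg.censor_target:
        hi *= 4
        if hi > 1e6:
            raise RuntimeError("censoring calibration failed to bracket the target")
    return float(optimize.brentq(lambda r: prob_censored(r) - cfg.censor_target, lo, hi,
                                 xtol=1e-10, rtol=1e-12))


def correlated_noise(blocks, n, rng, corr_range=(-0.2, 0.3)) -> np.ndarray:
    """Blocks of correlated Bernoulli(0.5) columns via a Gaussian copula.

    Within each block the latent pairwise correlations are drawn uniformly
    from ``corr_range``; the latent covariance is projected to the nearest
    positive-definite matrix (eigenvalue clipping) if needed.  Columns are
    the signs of the latent Gaussians; blocks are mutually independent.
    """
    cols = []
    for size in blocks:
        if size == 1:
            cols.append((rng.standard_normal((n, 1)) > 0).astype(np.int8))
            continue
        corr = np.eye(size)
        iu = np.triu_indices(size, 1)
        vals = rng.uniform(*corr_range, size=iu[0].size)
        corr[iu] = vals
        corr.T[iu] = vals
        eigval, eigvec = np.linalg.eigh(corr)
        if eigval.min() < 1e-8:
            warnings.warn("infeasible latent correlation block; projecting to nearest PD matrix")
            eigval = np.clip(eigval, 1e-8, None)
            corr = eigvec @ np.diag(eigval) @ eigvec.T
            d = np.sqrt(np.diag(corr))
            corr = corr / np.outer(d, d)
        chol = np.linalg.cholesky(corr)
        latent = rng.standard_normal((n, size)) @ chol.T
        cols.append((latent > 0).astype(np.int8))
    return np.hstack(cols)


def simulate_scenario(cfg: ScenarioConfig, rng: np.random.Generator | None = None,
                      censoring_rate: float | None = None) -> SimulatedDataset:
    """Generate one dataset (with latent truth) under the scenario config."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n
    nu = np.asarray(cfg.nu)
    G = (rng.random((n, 5)) < nu[None, :]).astype(np.int8)
    g1 = G[:, 0]
    leaf = _leaf_index(G[:, 1:])
    g_val = np.asarray(cfg.gamma)[leaf - 1]
    theta_p = cfg.theta * cfg.exp_alpha ** g1

    susceptible = rng.random(n) >= np.exp(-theta_p)
    T = np.full(n, np.inf)
    ns = susceptible
    u = rng.random(ns.sum()) * (1 - np.exp(-theta_p[ns]))
    T[ns] = -np.log1p(np.log1p(-u) / theta_p[ns]) / (cfg.lambda0 * np.exp(g_val[ns]))

    rate = censoring_rate if censoring_rate is not None else calibrate_censoring(cfg)
    C = rng.exponential(1.0 / rate, size=n) if rate > 0 else np.full(n, np.inf)
    X = np.minimum(T, C)
    delta = (T <= C).astype(np.int8)
    infinite = ~np.isfinite(X)
    if infinite.any():
        # administrative end of study for rows with neither event nor censoring
        X[infinite] = X[np.isfinite(X)].max()
        delta[infinite] = 0

    if cfg.correlated is not None:
        noise = correlated_noise(cfg.correlated, n, rng, cfg.corr_range)
    else:
        noise = (rng.random((n, cfg.n_noise)) < 0.5).astype(np.int8)
    names = [f"G{j}" for j in range(2, 6)] + [f"N{j + 1}" for j in range(noise.shape[1])]
    dataset = SurvivalDataset(
        time=X,
        event=delta,
        confounders=g1[:, None].astype(float),
        candidates=np.hstack([G[:, 1:], noise]).astype(float),
        candidate_names=names,
        confounder_names=["G1"],
    )
    truth = pd.DataFrame({"susceptible": susceptible, "leaf": leaf, "true_time": T})
    return SimulatedDataset(dataset=dataset, truth=truth, censoring_rate=rate)
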