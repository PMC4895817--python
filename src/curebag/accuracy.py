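"""IPCW Brier score, integrated Brier score and their out-of-bag versions.

The Brier score at time t weights squared prediction errors by the inverse
of the censoring-survival estimate G (Kaplan–Meier of the censoring
indicator):

    BS(t) = (1/N) sum_i [ S_i(t)^2 / G(X_i-) * 1{X_i <= t, delta_i = 1}
                          + (1 - S_i(t))^2 / G(t) * 1{X_i > t} ],

with the standard Graf convention of the left limit G(X_i-) for past-event
terms.  Terms whose weight denominator is zero are dropped.  The IBS is
the time average of BS over [0, max X_i], integrated exactly: BS is
right-continuous and piecewise constant between observed times, so the
integral is the step (left-endpoint) sum on that grid.  The OOB variants plug in
the out-of-bag survival prediction S*(t|Z_i) = exp(-Lambda*(t|Z_i)), either
from the whole ensemble (IBS*) or from a single tree restricted to its own
OOB sample (IBS*_b, the building block of the permutation importance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .data import StepFunction, SurvivalDataset
from .ensemble import Ensemble, _leaf_curves_on_grid, _tree_scale, oob_matrix

__all__ = [
    "AccuracyResult",
    "censoring_km",
    "brier_score",
    "brier_curve",
    "integrated_brier",
    "oob_ibs",
]


@dataclass(frozen=True)
class AccuracyResult:
    grid: np.ndarray
    bs: np.ndarray
    ibs: float
    variant: str


def censoring_km(data: SurvivalDataset) -> StepFunction:
    """Kaplan–Meier estimate G of the censoring survival distribution."""
    kmf = KaplanMeierFitter()
    kmf.fit(data.time, event_observed=1 - data.event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(float)
    vals = sf.iloc[:, 0].to_numpy(float)
    keep = times > 0
    return StepFunction(times[keep], vals[keep], side="right", initial=1.0)


def brier_curve(
    surv: np.ndarray,
    grid: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    G: StepFunction,
    include: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized BS(t) on a grid; ``surv`` is n x len(grid).

    ``include`` restricts the averaged rows (the 1/N denominator counts
    only included rows).
    """
    grid = np.asarray(grid, float)
    if np.any(grid < 0):
        raise ValueError("evaluation times must be nonnegative")
    time = np.asarray(time, float)
    event = np.asarray(event)
    if include is not None:
        surv = surv[include]
        time = time[include]
        event = event[include]
    n = time.size
    g_left = G.opposite_side()(time)          # G(X_i-)
    g_grid = G(grid)                          # G(t)
    with np.errstate(divide="ignore"):
        inv_gi = np.where(g_left > 0, 1.0 / g_left, 0.0)
        inv_gt = np.where(g_grid > 0, 1.0 / g_grid, 0.0)
    past_event = (time[:, None] <= grid[None, :]) & (event[:, None] == 1)
    at_risk = time[:, None] > grid[None, :]
    terms = (surv ** 2) * inv_gi[:, None] * past_event \
        + (1.0 - surv) ** 2 * inv_gt[None, :] * at_risk
    return terms.sum(axis=0) / n


def brier_score(predictions, data: SurvivalDataset, t: float,
                G: StepFunction | None = None) -> float:
    """BS(t) for per-subject survival predictions.

    ``predictions`` is a sequence of callables S_i(t) (e.g. step functions)
    or a vector of survival probabilities already evaluated at ``t``.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    G = G or censoring_km(data)
    if callable(predictions[0]):
        surv_t = np.array([float(f(t)) for f in predictions])
    else:
        surv_t = np.asarray(predictions, float)
    if np.any((surv_t < 0) | (surv_t > 1)):
        raise ValueError("survival predictions must lie in [0, 1]")
    return float(brier_curve(surv_t[:, None], np.array([t]), data.time, data.event, G)[0])


def _trapz(y: np.ndarray, x: np.ndarray) -> float:
    """Exact integral of a right-continuous piecewise-constant curve whose
    jumps all lie on ``x`` (left-endpoint rule).  BS(t) is such a curve:
    predictions, censoring weights and event indicators all step at
    observed times, so this reproduces the true integral where a
    trapezoid on the same knots would average across the jumps."""
    return float(np.sum(y[:-1] * np.diff(x)))


def integrated_brier(predictions, data: SurvivalDataset,
                     G: StepFunction | None = None) -> float:
    """IBS: integral of BS over [0, max X_i], divided by max X_i.

    The grid is the sorted unique observed times augmented with 0; the
    step-sum on that grid is the exact integral of the piecewise-constant
    Brier curve.
    """
    G = G or censoring_km(data)
    grid = np.unique(np.concatenate(([0.0], data.time)))
    if callable(predictions[0]):
        surv = np.vstack([np.clip(f(grid), 0.0, 1.0) for f in predictions])
    else:
        surv = np.asarray(predictions, float)
    bs = brier_curve(surv, grid, data.time, data.event, G)
    return _trapz(bs, grid) / grid[-1]


def oob_ibs(
    ens: Ensemble,
    data: SurvivalDataset | None = None,
    scope: str | int = "all",
    estimator: str | None = None,
    G: StepFunction | None = None,
    return_curve: bool = False,
):
    """Out-of-bag integrated Brier score.

    scope="all": S*(t|Z_i) = exp(-Lambda*(t|Z_i)) from the OOB ensemble
    prediction, averaged over the rows that are OOB for at least one tree.
    scope=b (int): restriction to OOB_b with tree b as the only predictor
    and the integral truncated at max(X_i, i in OOB_b).
    """
    data = data or ens.data
    estimator = estimator or ens.estimator
    G = G or censoring_km(data)
    if scope == "all":
        counts = ens.oob_mask.sum(axis=0)
        include = counts > 0
        if not include.any():
            raise ValueError("no row is out of bag for any tree")
        tmax = data.time[include].max()
        grid = np.unique(np.concatenate(([0.0], data.time[include])))
        chf, counts = oob_matrix(ens, grid, estimator)
        surv = np.exp(-chf)
        bs = brier_curve(surv, grid, data.time, data.event, G, include=include)
        ibs = _trapz(bs, grid) / grid[-1]
        result = AccuracyResult(grid, bs, ibs, "oob")
        return result if return_curve else ibs
    b = int(scope)
    rows = np.flatnonzero(ens.oob_mask[b])
    if rows.size == 0:
        raise ValueError(f"tree {b} has an empty OOB sample")
    tree = ens.trees[b]
    tmax = data.time[rows].max()
    grid = np.unique(np.concatenate(([0.0], data.time[rows][data.time[rows] <= tmax])))
    curves = _leaf_curves_on_grid(tree, grid, estimator)
    leaves = tree.apply(data.candidates[rows])
    scale = _tree_scale(tree, data.confounders[rows])
    surv = np.exp(-scale[:, None] * curves[leaves])
    bs = brier_curve(surv, grid, data.time[rows], data.event[rows], G)
    ibs = _trapz(bs, grid) / grid[-1]
    result = AccuracyResult(grid, bs, ibs, f"oob_tree_{b}")
    return result if return_curve else ibs
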