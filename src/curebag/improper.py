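"""Null fit of the improper (cure-fraction) survival model.

The model bounds the conditional cumulative hazard by a finite plateau,

    Lambda(t | Z1) = theta * exp(alpha' Z1) * (1 - exp(-H(t))),

so that a fraction exp(-theta * exp(alpha' Z1)) of subjects never
experiences the event.  Under the null hypothesis of no split effect
(gamma = 0) the quantities needed by the splitting criterion are:

* ``alpha``   — maximum partial-likelihood estimate over the confounders Z1
                (Breslow tie handling);
* ``Lambda0`` — Breslow baseline cumulative hazard, stored right-continuous
                and queried left-continuously where the criterion requires
                the left limit;
* ``theta``   — plateau estimate, the total Breslow mass up to and including
                the last observed event time (this keeps H finite at every
                event time when Lambda0 is queried through its left limit);
* ``omega``   — per-subject event weights omega(X_i) = 1 - H(X_i) with
                H(t) = -log(1 - Lambda0(t-)/theta).

When theta is large (nonsusceptible fraction near zero) H(t) ~ Lambda0(t-)/theta
vanishes, omega -> 1 and the downstream score reduces to the classical
adjusted log-rank statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import StepFunction, SurvivalDataset

__all__ = [
    "ImproperNullFit",
    "fit_null_cox",
    "breslow_baseline",
    "estimate_theta",
    "event_weights",
]


class EstimationError(RuntimeError):
    def __init__(self, msg, last_iterate=None):
        super().__init__(msg)
        self.last_iterate = last_iterate


def _order_stats(time, event, z=None):
    """Sort ascending in time and compute tie-group first/last positions."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    m = t.size
    new = np.r_[True, t[1:] != t[:-1]]
    first = np.maximum.accumulate(np.where(new, np.arange(m), 0))
    # last index of each tie group: next position that starts a new group, -1
    last = np.empty(m, dtype=np.intp)
    group_ids = np.cumsum(new) - 1
    boundaries = np.r_[np.flatnonzero(new), m]
    last = boundaries[group_ids + 1] - 1
    return order, t, event[order], first, last, (None if z is None else z[order])


def fit_null_cox(
    data: SurvivalDataset | None = None,
    *,
    time=None,
    event=None,
    z1=None,
    tol: float = 1e-9,
    max_iter: int = 50,
    ridge: float = 1e-8,
) -> np.ndarray:
    """Cox partial-likelihood Newton solver over the confounders only.

    Breslow tie convention: all events tied at a time share the full risk
    set.  ``m1 = 0`` returns the empty vector.  A singular information
    matrix triggers a small Jeffreys-style ridge; non-convergence raises
    :class:`EstimationError` carrying the last iterate.
    """
    if data is not None:
        time, event, z1 = data.time, data.event, data.confounders
    time = np.asarray(time, float)
    event = np.asarray(event)
    z1 = np.atleast_2d(np.asarray(z1, float))
    if z1.shape[0] != time.size:
        z1 = z1.T
    p = z1.shape[1]
    if p == 0:
        return np.empty(0)
    if event.sum() == 0:
        raise EstimationError("no events: alpha is not estimable")
    order, t, d, first, last, z = _order_stats(time, event, z1)
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = z @ beta
        eta = eta - eta.max()  # guard overflow; cancels in ratios
        w = np.exp(eta)
        wz = w[:, None] * z
        s0 = np.cumsum(w[::-1])[::-1][first]
        s1 = np.cumsum(wz[::-1], axis=0)[::-1][first]
        zbar = s1 / s0[:, None]
        grad = ((z - zbar) * d[:, None]).sum(axis=0)
        # S2/S0 - zbar zbar'
        wzz = wz[:, :, None] * z[:, None, :]
        s2 = np.cumsum(wzz[::-1], axis=0)[::-1][first]
        info = (
            d[:, None, None]
            * (s2 / s0[:, None, None] - zbar[:, :, None] * zbar[:, None, :])
        ).sum(axis=0)
        if np.linalg.norm(grad) < tol:
            return beta
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            warnings.warn("singular information matrix: applying ridge fallback")
            step = np.linalg.solve(info + ridge * np.eye(p), grad)
        if not np.all(np.isfinite(step)) or np.linalg.norm(step) > 50:
            # likely separation: damp and regularize
            warnings.warn("ill-conditioned Newton step (possible separation); damping")
            step = np.linalg.solve(info + max(ridge, 1e-4) * np.eye(p), grad)
            step = step / max(1.0, np.linalg.norm(step) / 5.0)
        beta = beta + step
    eta = z @ beta
    w = np.exp(eta - eta.max())
    s0 = np.cumsum(w[::-1])[::-1][first]
    s1 = np.cumsum((w[:, None] * z)[::-1], axis=0)[::-1][first]
    grad = ((z - s1 / s0[:, None]) * d[:, None]).sum(axis=0)
    if np.linalg.norm(grad) < 1e-6:  # close enough for flat likelihoods
        return beta
    raise EstimationError(f"Cox fit did not converge in {max_iter} iterations", beta)


def breslow_baseline(
    data: SurvivalDataset | None = None,
    alpha: np.ndarray | None = None,
    *,
    time=None,
    event=None,
    risk_scores=None,
) -> StepFunction:
    """Breslow estimate of the baseline cumulative hazard under ``alpha``.

    Jumps only at distinct event times ``t_k``, of size
    ``d_k / sum_{j at risk at t_k} exp(alpha' Z1_j)``.  Returned
    right-continuous; use :meth:`StepFunction.opposite_side` for left
    limits.  Zero events gives the zero function (with a warning).
    """
    if data is not None:
        time, event = data.time, data.event
        if risk_scores is None:
            if alpha is None or (alpha.size == 0 and data.m1 == 0):
                risk_scores = np.ones(data.n)
            else:
                risk_scores = np.exp(data.confounders @ alpha)
    time = np.asarray(time, float)
    event = np.asarray(event)
    risk_scores = np.ones(time.size) if risk_scores is None else np.asarray(risk_scores, float)
    if event.sum() == 0:
        warnings.warn("no events: baseline cumulative hazard is identically zero")
        return StepFunction(np.empty(0), np.empty(0))
    order, t, d, first, last, w = _order_stats(time, event, risk_scores)
    s0 = np.cumsum(w[::-1])[::-1][first]
    cum = np.cumsum(d / s0)
    # distinct event times with their cumulative value (value at last of group)
    grp_first = np.unique(first[d.astype(bool)])
    knots = t[grp_first]
    values = cum[last[grp_first]]
    return StepFunction(knots, values, side="right")


def estimate_theta(baseline: StepFunction) -> float:
    """Plateau estimate: the full Breslow mass at the last event time."""
    if baseline.knots.size == 0:
        raise EstimationError("baseline has no jumps: theta is not estimable")
    return float(baseline.values[-1])


def event_weights(time, event, baseline: StepFunction, theta: float) -> np.ndarray:
    """omega(X_i) = 1 - H(X_i), H(t) = -log(1 - Lambda0(t-)/theta).

    Uses the left limit of the baseline.  For censored subjects observed
    after the last event the argument of the log can reach 0 (H infinite);
    these weights only ever multiply ``delta = 0`` terms and are stored as 0.
    An event time with a non-positive argument violates the plateau
    invariant and raises.
    """
    time = np.asarray(time, float)
    event = np.asarray(event)
    lam_left = baseline.opposite_side()(time) if baseline.side == "right" else baseline(time)
    arg = 1.0 - lam_left / theta
    omega = np.empty(time.size)
    bad = arg <= 0
    if np.any(bad & (event == 1)):
        raise EstimationError("Lambda0(t-)/theta >= 1 at an event time (plateau invariant violated)")
    ok = ~bad
    omega[ok] = 1.0 + np.log(arg[ok])
    omega[bad] = 0.0
    return omega


@dataclass
class ImproperNullFit:
    """Bundled null-model estimates used by the splitting criterion."""

    alpha: np.ndarray
    baseline: StepFunction
    theta: float
    risk_scores: np.ndarray

    @classmethod
    def fit(cls, data: SurvivalDataset, alpha: np.ndarray | None = None) -> "ImproperNullFit":
        """Fit on ``data``; pass ``alpha`` to reuse a tree-level estimate."""
        if alpha is None:
            alpha = fit_null_cox(data) if data.m1 > 0 else np.empty(0)
        risk = np.exp(data.confounders @ alpha) if alpha.size else np.ones(data.n)
        baseline = breslow_baseline(time=data.time, event=data.event, risk_scores=risk)
        theta = estimate_theta(baseline)
        return cls(alpha=alpha, baseline=baseline, theta=theta, risk_scores=risk)

    def weights(self, data: SurvivalDataset) -> np.ndarray:
        return event_weights(data.time, data.event, self.baseline, self.theta)
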