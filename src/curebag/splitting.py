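"""Pseudo-R2 splitting criterion for improper survival trees.

For a candidate binary partition of a node (membership ``Z*``), the score of
the improper-model partial likelihood at gamma = 0 is

    U = sum_i delta_i * omega(X_i) * (Z*_i - rbar(X_i)),

where ``rbar(t)`` is the risk-weighted mean of ``Z*`` over the at-risk set
(weights exp(alpha' Z1)) and ``omega`` the event weights of the improper
null model.  The robust variance V is the sum of squared Lin–Wei score
residuals

    resid_i = delta_i omega_i (Z*_i - rbar(X_i))
              - e_i * sum_l delta_l omega_l Y_i(X_l) / S0(X_l) * (Z*_i - rbar(X_l)),

with ``e_i = exp(alpha' Z1_i)`` and ``S0(t)`` the at-risk risk-score sum.
The splitting statistic is the pseudo-R2

    S = (U^2 / V) / K,   K = number of distinct event times in the node,

a unit-free index in [0, 1].  With ``omega`` forced to one (criterion
``"logrank"``, or theta -> infinity) U and V are the classical adjusted
log-rank score and its robust variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SurvivalDataset
from .improper import ImproperNullFit, breslow_baseline, estimate_theta, event_weights

__all__ = ["SplitStatistic", "NodeWorkspace", "score_and_variance", "split_candidates"]

CRITERIA = ("pseudoR2", "logrank")


@dataclass(frozen=True)
class SplitStatistic:
    U: float
    V: float
    K: int
    S: float
    criterion: str
    degenerate: bool = False


class NodeWorkspace:
    """Per-node precomputation shared by every candidate membership.

    Sorts the node rows by time, builds the node-level Breslow baseline /
    theta / omega under the tree-level risk scores, and caches the at-risk
    cumulative sums so that scoring one membership vector is a handful of
    O(m) numpy passes.
    """

    def __init__(self, time, event, risk_scores, criterion: str = "pseudoR2",
                 theta_override: float | None = None):
        if criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {criterion!r}")
        self.criterion = criterion
        time = np.asarray(time, float)
        event = np.asarray(event)
        risk = np.asarray(risk_scores, float)
        order = np.argsort(time, kind="stable")
        self.order = order
        t = time[order]
        m = t.size
        self.m = m
        self.t = t
        self.d = event[order].astype(float)
        self.w = risk[order]
        new = np.r_[True, t[1:] != t[:-1]]
        self.first = np.maximum.accumulate(np.where(new, np.arange(m), 0))
        group_ids = np.cumsum(new) - 1
        boundaries = np.r_[np.flatnonzero(new), m]
        self.last = boundaries[group_ids + 1] - 1
        self.s0 = np.cumsum(self.w[::-1])[::-1][self.first]
        self.n_events = int(self.d.sum())
        self.K = int(np.unique(t[self.d > 0]).size)
        if self.n_events == 0:
            self.omega = np.zeros(m)
            self.theta = None
            self._a_pos = np.zeros(m)
            self._cumA = np.zeros(m)
            return
        if criterion == "logrank":
            self.omega = np.ones(m)
            self.theta = None
        else:
            cum = np.cumsum(self.d / self.s0)
            theta = theta_override if theta_override is not None else float(cum[-1])
            lam_left = np.where(self.first > 0, cum[np.maximum(self.first - 1, 0)], 0.0)
            arg = 1.0 - lam_left / theta
            omega = np.zeros(m)
            ok = arg > 0
            omega[ok] = 1.0 + np.log(arg[ok])
            self.omega = omega
            self.theta = theta
        # event-side cumulative A(t) = sum_{events l: X_l <= t} omega_l / S0(X_l)
        self._a_pos = self.d * self.omega / self.s0
        self._cumA = np.cumsum(self._a_pos)

    def score(self, membership: np.ndarray) -> SplitStatistic:
        """U, V, S for one 0/1 membership vector (original row order)."""
        z = np.asarray(membership, float)[self.order]
        w, d, omega = self.w, self.d, self.omega
        s1 = np.cumsum((w * z)[::-1])[::-1][self.first]
        rbar = s1 / self.s0
        diff = z - rbar
        U = float(np.sum(d * omega * diff))
        # cumulative sums over events with X_l <= X_i (ties inclusive)
        A = self._cumA[self.last]
        B = np.cumsum(self._a_pos * rbar)[self.last]
        resid = d * omega * diff - w * (z * A - B)
        V = float(np.sum(resid * resid))
        if V <= 0.0 or not np.isfinite(V):
            return SplitStatistic(U, max(V, 0.0), self.K, 0.0, self.criterion, degenerate=True)
        S = min((U * U / V) / self.K, 1.0)
        return SplitStatistic(U, V, self.K, S, self.criterion)


def score_and_variance(
    node_data: SurvivalDataset,
    membership,
    fit: ImproperNullFit | None = None,
    criterion: str = "pseudoR2",
    theta_override: float | None = None,
) -> SplitStatistic:
    """Score one candidate partition of a node.

    ``fit`` supplies the risk scores exp(alpha' Z1) (typically the tree-level
    alpha); the node baseline / theta / omega are recomputed on the node's
    own rows, as the criterion is defined on the sample under comparison.
    ``theta_override`` forces the plateau (theta -> infinity recovers the
    adjusted log-rank statistic).
    """
    membership = np.asarray(membership)
    if membership.size != node_data.n:
        raise ValueError("membership length must equal node size")
    if node_data.n_events < 1:
        raise ValueError("node has no events")
    risk = fit.risk_scores if fit is not None else np.ones(node_data.n)
    if risk.shape[0] != node_data.n:
        raise ValueError("fit.risk_scores length must equal node size")
    ws = NodeWorkspace(node_data.time, node_data.event, risk, criterion, theta_override)
    return ws.score(membership)


def split_candidates(
    x: np.ndarray,
    event: np.ndarray | None = None,
    min_node: int = 0,
    min_events: int = 0,
    max_thresholds: int = 32,
):
    """Admissible (threshold, membership) pairs for one candidate column.

    Membership 1 means ``x <= threshold`` (the left child).  A binary column
    yields its single partition; a continuous one, memberships at midpoints
    of consecutive sorted unique values, quantile-thinned to at most
    ``max_thresholds``.  Partitions leaving either side with fewer than
    ``min_node`` observations or ``min_events`` events are dropped.
    """
    x = np.asarray(x, float)
    uniq = np.unique(x)
    if uniq.size < 2:
        return []
    thresholds = (uniq[:-1] + uniq[1:]) / 2.0
    if thresholds.size > max_thresholds:
        qs = np.linspace(0, thresholds.size - 1, max_thresholds).round().astype(int)
        thresholds = thresholds[np.unique(qs)]
    out = []
    ev = None if event is None else np.asarray(event)
    for c in thresholds:
        member = (x <= c).astype(np.int8)
        n_left = int(member.sum())
        if min(n_left, x.size - n_left) < min_node:
            continue
        if ev is not None and min_events > 0:
            e_left = int(ev[member == 1].sum())
            if min(e_left, int(ev.sum()) - e_left) < min_events:
                continue
        out.append((float(c), member))
    return out
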