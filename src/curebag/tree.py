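"""Growing one maximal improper survival tree.

Trees are grown without pruning (the bagging loop averages over maximal
trees).  Only the candidate columns ``Z2`` are eligible for splitting; the
confounders ``Z1`` act through the tree-level risk scores exp(alpha' Z1)
inside the criterion and the leaf Breslow-type estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data import StepFunction, SurvivalDataset
from .improper import EstimationError, fit_null_cox
from .splitting import NodeWorkspace, split_candidates

__all__ = ["TreeControl", "TreeNode", "SurvivalTree", "grow_tree", "leaf_chf"]


@dataclass(frozen=True)
class TreeControl:
    """Growth parameters.

    min_node : minimum observations per child.
    min_events : minimum events per child.
    s_min : a node is terminal when no admissible candidate has S > s_min.
    max_thresholds : cap on thresholds tried per continuous column per node.
    """

    min_node: int = 15
    min_events: int = 3
    s_min: float = 0.0
    max_thresholds: int = 32


@dataclass
class TreeNode:
    depth: int                      # root split has depth 1
    n_obs: int
    n_events: int
    variable: int | None = None     # Z2 column index; None for a leaf
    threshold: float | None = None
    s_value: float | None = None
    left: int | None = None         # child node indices
    right: int | None = None
    leaf_id: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.variable is None


@dataclass
class SurvivalTree:
    nodes: list[TreeNode]
    leaf_rows: list[np.ndarray]       # training-row indices per leaf
    chf_bre: list[StepFunction]
    chf_na: list[StepFunction]
    alpha: np.ndarray
    control: TreeControl
    criterion: str
    candidate_names: list[str] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_rows)

    def apply(self, z2: np.ndarray) -> np.ndarray:
        """Leaf id for each row of ``z2`` (n x m2, or a single vector)."""
        z2 = np.atleast_2d(np.asarray(z2, float))
        n = z2.shape[0]
        leaf = np.empty(n, dtype=np.intp)
        node_of = np.zeros(n, dtype=np.intp)
        active = np.arange(n)
        while active.size:
            nxt = []
            for nid in np.unique(node_of[active]):
                node = self.nodes[nid]
                rows = active[node_of[active] == nid]
                if node.is_leaf:
                    leaf[rows] = node.leaf_id
                    continue
                go_left = z2[rows, node.variable] <= node.threshold
                node_of[rows[go_left]] = node.left
                node_of[rows[~go_left]] = node.right
                nxt.append(rows)
            active = np.concatenate(nxt) if nxt else np.empty(0, dtype=np.intp)
        return leaf

    def splits(self):
        """(variable, depth, S, events-at-split) for every internal node."""
        return [
            (nd.variable, nd.depth, nd.s_value, nd.n_events)
            for nd in self.nodes
            if not nd.is_leaf
        ]

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "alpha": self.alpha.tolist(),
            "control": vars(self.control).copy() if not isinstance(self.control, TreeControl)
            else {k: getattr(self.control, k) for k in ("min_node", "min_events", "s_min", "max_thresholds")},
            "candidate_names": self.candidate_names,
            "nodes": [vars(nd).copy() for nd in self.nodes],
            "leaves": [
                {
                    "rows": rows.tolist(),
                    "bre": {"knots": f.knots.tolist(), "values": f.values.tolist()},
                    "na": {"knots": g.knots.tolist(), "values": g.values.tolist()},
                }
                for rows, f, g in zip(self.leaf_rows, self.chf_bre, self.chf_na)
            ],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "SurvivalTree":
        return cls(
            nodes=[TreeNode(**nd) for nd in d["nodes"]],
            leaf_rows=[np.asarray(lf["rows"], dtype=np.intp) for lf in d["leaves"]],
            chf_bre=[StepFunction(np.asarray(lf["bre"]["knots"]), np.asarray(lf["bre"]["values"]))
                     for lf in d["leaves"]],
            chf_na=[StepFunction(np.asarray(lf["na"]["knots"]), np.asarray(lf["na"]["values"]))
                    for lf in d["leaves"]],
            alpha=np.asarray(d["alpha"], float),
            control=TreeControl(**d["control"]),
            criterion=d["criterion"],
            candidate_names=list(d.get("candidate_names", [])),
        )


def _node_chf(time, event, risk, weighted: bool) -> StepFunction:
    """Breslow-type (weighted) or Nelson–Aalen (unweighted) CHF of a leaf."""
    if event.sum() == 0:
        return StepFunction(np.empty(0), np.empty(0))
    order = np.argsort(time, kind="stable")
    t, d = time[order], event[order].astype(float)
    w = risk[order] if weighted else np.ones(t.size)
    m = t.size
    new = np.r_[True, t[1:] != t[:-1]]
    first = np.maximum.accumulate(np.where(new, np.arange(m), 0))
    s0 = np.cumsum(w[::-1])[::-1][first]
    cum = np.cumsum(d / s0)
    group_ids = np.cumsum(new) - 1
    boundaries = np.r_[np.flatnonzero(new), m]
    last = boundaries[group_ids + 1] - 1
    ev_first = np.unique(first[d > 0])
    return StepFunction(t[ev_first], cum[last[ev_first]])


def grow_tree(
    data: SurvivalDataset,
    control: TreeControl | None = None,
    criterion: str = "pseudoR2",
    alpha: np.ndarray | None = None,
) -> SurvivalTree:
    """Grow a maximal tree on ``data`` (deterministic given its inputs).

    ``alpha`` is the tree-level confounder estimate; fitted on ``data``
    when omitted (falls back to zero on estimation failure, with the
    solver's warning).  Each node re-derives its own baseline / plateau /
    event weights inside :class:`NodeWorkspace`.
    """
    control = control or TreeControl()
    if data.n_events < 1:
        raise ValueError("cannot grow a tree on data with no events")
    if alpha is None:
        if data.m1 > 0:
            try:
                alpha = fit_null_cox(data)
            except EstimationError:
                alpha = np.zeros(data.m1)
        else:
            alpha = np.empty(0)
    risk = np.exp(data.confounders @ alpha) if alpha.size else np.ones(data.n)

    nodes: list[TreeNode] = []
    leaf_rows: list[np.ndarray] = []
    # iterative growth; each entry: (rows, depth, parent node index, child slot)
    stack = [(np.arange(data.n), 1, None, None)]
    while stack:
        rows, depth, parent, side = stack.pop()
        t, d = data.time[rows], data.event[rows]
        nid = len(nodes)
        node = TreeNode(depth=depth, n_obs=rows.size, n_events=int(d.sum()))
        nodes.append(node)
        if parent is not None:
            setattr(nodes[parent], side, nid)

        best = None  # (S, var, threshold, membership)
        if node.n_events >= 2 * control.min_events and rows.size >= 2 * control.min_node:
            ws = NodeWorkspace(t, d, risk[rows], criterion)
            for j in range(data.m2):
                for thr, member in split_candidates(
                    data.candidates[rows, j], d,
                    min_node=control.min_node,
                    min_events=control.min_events,
                    max_thresholds=control.max_thresholds,
                ):
                    stat = ws.score(member)
                    if stat.degenerate:
                        continue
                    key = (-stat.S, j, thr)
                    if best is None or key < best[0]:
                        best = (key, stat.S, j, thr, member)
        if best is not None and best[1] > control.s_min:
            _, s_val, j, thr, member = best
            node.variable = j
            node.threshold = thr
            node.s_value = s_val
            # push right first so left is processed/numbered first
            stack.append((rows[member == 0], depth + 1, nid, "right"))
            stack.append((rows[member == 1], depth + 1, nid, "left"))
        else:
            node.leaf_id = len(leaf_rows)
            leaf_rows.append(rows)

    chf_bre = [_node_chf(data.time[r], data.event[r], risk[r], weighted=True) for r in leaf_rows]
    chf_na = [_node_chf(data.time[r], data.event[r], risk[r], weighted=False) for r in leaf_rows]
    return SurvivalTree(
        nodes=nodes,
        leaf_rows=leaf_rows,
        chf_bre=chf_bre,
        chf_na=chf_na,
        alpha=alpha,
        control=control,
        criterion=criterion,
        candidate_names=list(data.candidate_names),
    )


def leaf_chf(tree: SurvivalTree, leaf_id: int, estimator: str = "BRE") -> StepFunction:
    """CHF step function of one leaf (``"BRE"`` risk-weighted, ``"NA"`` not)."""
    if estimator not in ("BRE", "NA"):
        raise ValueError("estimator must be 'BRE' or 'NA'")
    return (tree.chf_bre if estimator == "BRE" else tree.chf_na)[leaf_id]
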