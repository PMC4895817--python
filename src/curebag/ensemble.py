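"""Bagging loop, ensemble CHF prediction and out-of-bag prediction.

Each of the B trees is grown on a bootstrap resample of the learning set
(n draws with replacement; on average 36.8% of rows are left out and form
the tree's OOB sample).  The ensemble prediction for a covariate vector is
the average over trees of the leaf CHF the candidates fall into, scaled by
the tree-level confounder factor exp(alpha_b' z1); the OOB prediction for a
training row averages only over trees for which that row is out of bag.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import StepFunction, SurvivalDataset
from .improper import EstimationError, fit_null_cox
from .tree import SurvivalTree, TreeControl, grow_tree

__all__ = ["Ensemble", "fit_bagging", "predict_chf", "oob_chf", "draw_bootstrap"]


def draw_bootstrap(n: int, rng: np.random.Generator) -> np.ndarray:
    """One bootstrap multiset: n row indices drawn with replacement."""
    return rng.integers(0, n, size=n)


@dataclass
class Ensemble:
    trees: list[SurvivalTree]
    inbag: list[np.ndarray]
    oob_mask: np.ndarray            # B x n booleans
    data: SurvivalDataset
    criterion: str
    estimator: str                  # "BRE" or "NA"
    control: TreeControl
    seed: int
    resample_retries: int = 0

    @property
    def B(self) -> int:
        return len(self.trees)

    @property
    def n(self) -> int:
        return self.data.n

    # -- serialization ----------------------------------------------------
    def manifest(self) -> dict:
        return {
            "B": self.B,
            "n": self.n,
            "seed": self.seed,
            "criterion": self.criterion,
            "estimator": self.estimator,
            "control": {k: getattr(self.control, k)
                        for k in ("min_node", "min_events", "s_min", "max_thresholds")},
            "resample_retries": self.resample_retries,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(
            {
                "manifest": self.manifest(),
                "inbag": [ib.tolist() for ib in self.inbag],
                "trees": [t.to_dict() for t in self.trees],
            },
            **kw,
        )


def fit_bagging(
    data: SurvivalDataset,
    B: int = 400,
    control: TreeControl | None = None,
    criterion: str = "pseudoR2",
    estimator: str = "BRE",
    seed: int = 0,
    bootstrap_indices: list[np.ndarray] | None = None,
) -> Ensemble:
    """Fit the bagged improper-survival-tree ensemble.

    Reproducible given ``seed``: per-tree RNG substreams are spawned from a
    single master ``SeedSequence``, so results do not depend on execution
    order.  A bootstrap replicate with zero events is redrawn (at most 100
    times per tree).  A failed tree-level Cox fit for alpha falls back to
    alpha = 0 with a warning.  ``bootstrap_indices`` is a testing hook that
    bypasses resampling.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if estimator not in ("BRE", "NA"):
        raise ValueError("estimator must be 'BRE' or 'NA'")
    control = control or TreeControl()
    n = data.n
    streams = [np.random.Generator(np.random.PCG64(s))
               for s in np.random.SeedSequence(seed).spawn(B)]
    trees, inbag = [], []
    oob = np.zeros((B, n), dtype=bool)
    retries_total = 0
    for b in range(B):
        rng = streams[b]
        if bootstrap_indices is not None:
            idx = np.asarray(bootstrap_indices[b])
        else:
            idx = draw_bootstrap(n, rng)
            retries = 0
            while data.event[idx].sum() == 0:
                retries += 1
                if retries > 100:
                    raise EstimationError("bootstrap resampling failed to find events (100 retries)")
                idx = draw_bootstrap(n, rng)
            retries_total += retries
        sample = data.subset(idx)
        if sample.m1 > 0:
            try:
                alpha = fit_null_cox(sample)
            except EstimationError:
                warnings.warn(f"tree {b}: confounder Cox fit failed; using alpha = 0")
                alpha = np.zeros(sample.m1)
        else:
            alpha = np.empty(0)
        trees.append(grow_tree(sample, control, criterion, alpha=alpha))
        inbag.append(idx)
        oob[b] = ~np.isin(np.arange(n), idx)
    return Ensemble(
        trees=trees, inbag=inbag, oob_mask=oob, data=data,
        criterion=criterion, estimator=estimator, control=control,
        seed=seed, resample_retries=retries_total,
    )


def _leaf_curves_on_grid(tree: SurvivalTree, grid: np.ndarray, estimator: str) -> np.ndarray:
    """L(b) x len(grid) matrix of leaf CHFs evaluated on ``grid``."""
    curves = tree.chf_bre if estimator == "BRE" else tree.chf_na
    return np.vstack([f(grid) for f in curves]) if curves else np.empty((0, grid.size))


def _tree_scale(tree: SurvivalTree, z1: np.ndarray) -> np.ndarray:
    """exp(alpha_b' z1) per row of ``z1`` (ones when no confounders)."""
    z1 = np.atleast_2d(np.asarray(z1, float))
    return np.exp(z1 @ tree.alpha) if tree.alpha.size else np.ones(z1.shape[0])


def predict_chf(ens: Ensemble, z1, z2, estimator: str | None = None) -> StepFunction:
    """Ensemble CHF prediction for one new observation.

    Lambda(t|Z) = (1/B) sum_b exp(alpha_b' z1) * Lambda_leaf_b(z2)(t),
    returned as a right-continuous step function on the pooled knot grid.
    """
    estimator = estimator or ens.estimator
    z1 = np.atleast_1d(np.asarray(z1, float))
    z2 = np.atleast_1d(np.asarray(z2, float))
    knots = np.unique(np.concatenate([
        (t.chf_bre if estimator == "BRE" else t.chf_na)[int(t.apply(z2)[0])].knots
        for t in ens.trees
    ] or [np.empty(0)]))
    total = np.zeros(knots.size)
    for tree in ens.trees:
        leaf = int(tree.apply(z2)[0])
        f = (tree.chf_bre if estimator == "BRE" else tree.chf_na)[leaf]
        total += float(_tree_scale(tree, z1)[0]) * f(knots)
    return StepFunction(knots, total / ens.B)


def oob_matrix(ens: Ensemble, grid: np.ndarray, estimator: str | None = None):
    """OOB CHF for every training row on a common time grid.

    Returns ``(chf, counts)``: an n x len(grid) matrix (rows never OOB are
    zero) and the per-row count of trees in which the row is out of bag.
    """
    estimator = estimator or ens.estimator
    n = ens.n
    acc = np.zeros((n, grid.size))
    counts = ens.oob_mask.sum(axis=0)
    for b, tree in enumerate(ens.trees):
        rows = np.flatnonzero(ens.oob_mask[b])
        if rows.size == 0:
            continue
        leaves = tree.apply(ens.data.candidates[rows])
        curves = _leaf_curves_on_grid(tree, grid, estimator)
        scale = _tree_scale(tree, ens.data.confounders[rows])
        acc[rows] += scale[:, None] * curves[leaves]
    with np.errstate(invalid="ignore"):
        chf = np.where(counts[:, None] > 0, acc / np.maximum(counts, 1)[:, None], 0.0)
    return chf, counts


def oob_chf(ens: Ensemble, i: int, estimator: str | None = None) -> StepFunction:
    """OOB CHF prediction for training row ``i``.

    Averages exp(alpha_b' z1_i) * Lambda_leaf_b(z2_i)(t) over the trees for
    which row i is out of bag.  Raises if the row is in-bag everywhere.
    """
    estimator = estimator or ens.estimator
    which = np.flatnonzero(ens.oob_mask[:, i])
    if which.size == 0:
        raise ValueError(f"row {i} is in-bag for every tree (no OOB prediction)")
    knots = []
    for b in which:
        tree = ens.trees[b]
        leaf = int(tree.apply(ens.data.candidates[i])[0])
        knots.append((tree.chf_bre if estimator == "BRE" else tree.chf_na)[leaf].knots)
    grid = np.unique(np.concatenate(knots)) if knots else np.empty(0)
    total = np.zeros(grid.size)
    for b in which:
        tree = ens.trees[b]
        leaf = int(tree.apply(ens.data.candidates[i])[0])
        f = (tree.chf_bre if estimator == "BRE" else tree.chf_na)[leaf]
        total += float(_tree_scale(tree, ens.data.confounders[i])[0]) * f(grid)
    return StepFunction(grid, total / which.size)
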