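"""Variable-importance scores for a fitted bagging ensemble.

* IIS  — index importance: for each tree, each split on variable j
  contributes (events in the split node) x (criterion value S); the
  per-variable totals are normalized to sum to 100 across variables.
* DIIS — depth-and-index importance: same contributions weighted by
  2^(-depth) with the root split at depth 1.
* PPIS — permutation prediction importance: the mean over trees of the
  increase in the tree's OOB integrated Brier score after permuting the
  variable within the tree's OOB sample (PPIS-NA / PPIS-BRE depending on
  the leaf CHF estimator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accuracy import brier_curve, censoring_km, _trapz, oob_ibs
from .data import SurvivalDataset
from .ensemble import Ensemble, _leaf_curves_on_grid, _tree_scale

__all__ = [
    "index_importance",
    "depth_index_importance",
    "permutation_importance",
    "importance_table",
]


def _split_sums(ens: Ensemble, depth_weighted: bool) -> np.ndarray:
    """B x m2 matrix of raw per-tree contributions omega_j^b."""
    m2 = ens.data.m2
    raw = np.zeros((ens.B, m2))
    for b, tree in enumerate(ens.trees):
        for var, depth, s_val, n_events in tree.splits():
            w = n_events * s_val
            if depth_weighted:
                w *= 2.0 ** (-depth)
            raw[b, var] += w
    return raw


def _normalize(raw: np.ndarray) -> np.ndarray:
    total = raw.sum()
    if total <= 0:
        warnings.warn("ensemble contains no splits: importance scores are all zero")
        return np.zeros(raw.shape[1])
    return 100.0 * raw.sum(axis=0) / total


def index_importance(ens: Ensemble, raw: bool = False):
    """IIS per candidate variable (sums to 100 when any split occurred)."""
    mat = _split_sums(ens, depth_weighted=False)
    return mat if raw else _normalize(mat)


def depth_index_importance(ens: Ensemble, raw: bool = False):
    """DIIS per candidate variable (2^-depth weighting, root depth 1)."""
    mat = _split_sums(ens, depth_weighted=True)
    return mat if raw else _normalize(mat)


def permutation_importance(
    ens: Ensemble,
    data: SurvivalDataset | None = None,
    seed: int = 0,
    estimator: str | None = None,
    permutations: dict | None = None,
) -> np.ndarray:
    """PPIS_j = mean_b ( IBS*_b after permuting j within OOB_b  -  IBS*_b ).

    Trees with an empty OOB sample are skipped.  ``permutations`` is a test
    hook mapping tree index -> permutation array over that tree's OOB rows
    (identity arrays give PPIS exactly 0).
    """
    data = data or ens.data
    estimator = estimator or ens.estimator
    rng = np.random.default_rng(seed)
    G = censoring_km(data)
    m2 = data.m2
    diffs = np.zeros(m2)
    used = 0
    for b, tree in enumerate(ens.trees):
        rows = np.flatnonzero(ens.oob_mask[b])
        if rows.size == 0:
            continue
        used += 1
        tmax = data.time[rows].max()
        grid = np.unique(np.concatenate(([0.0], data.time[rows])))
        curves = _leaf_curves_on_grid(tree, grid, estimator)
        scale = _tree_scale(tree, data.confounders[rows])
        z2 = data.candidates[rows].copy()
        leaves = tree.apply(z2)
        surv = np.exp(-scale[:, None] * curves[leaves])
        base = _trapz(brier_curve(surv, grid, data.time[rows], data.event[rows], G), grid) / tmax
        hook = None if permutations is None else np.asarray(permutations[b])
        for j in range(m2):
            perm = hook if hook is not None else rng.permutation(rows.size)
            col = z2[:, j].copy()
            z2[:, j] = col[perm]
            leaves_j = tree.apply(z2)
            z2[:, j] = col
            surv_j = np.exp(-scale[:, None] * curves[leaves_j])
            ibs_j = _trapz(brier_curve(surv_j, grid, data.time[rows], data.event[rows], G), grid) / tmax
            diffs[j] += ibs_j - base
    if used == 0:
        raise ValueError("every tree has an empty OOB sample")
    return diffs / used


def importance_table(
    ens: Ensemble,
    data: SurvivalDataset | None = None,
    seed: int = 0,
    include_ppis: bool = True,
) -> pd.DataFrame:
    """All scores as a DataFrame sorted by IIS descending."""
    data = data or ens.data
    tab = pd.DataFrame({
        "variable": data.candidate_names,
        "iis": index_importance(ens),
        "diis": depth_index_importance(ens),
    })
    if include_ppis:
        tab["ppis"] = permutation_importance(ens, data, seed=seed)
    return tab.sort_values("iis", ascending=False).reset_index(drop=True)
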