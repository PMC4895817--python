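"""Permutation test selecting a basket of important variables.

The null hypothesis for each candidate is that its importance score is
zero.  The null distribution is built by refitting the whole bagging
ensemble on partially permuted data: the (time, event, confounder) block is
jointly permuted against the candidate block, which preserves the
relationship between the outcome and the confounders Z1 while breaking any
link with the candidates.  P-values are the fraction of the Q permuted
refits whose score reaches the observed one; the basket applies a
Bonferroni threshold alpha / m2.

Note the p-value granularity is 1/Q (no "+1" correction), so the Bonferroni
threshold is unreachable unless Q >= m2 / alpha; a warning is issued in
that case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import SurvivalDataset
from .ensemble import fit_bagging
from .importance import depth_index_importance, index_importance
from .tree import TreeControl

__all__ = ["SelectionResult", "permute_learning_set", "basket_selection"]

_SCORES = {"IIS": index_importance, "DIIS": depth_index_importance}


@dataclass
class SelectionResult:
    variables: list[str]
    observed_scores: np.ndarray
    null_scores: np.ndarray         # Q x m2
    p_values: np.ndarray
    alpha: float
    selected: np.ndarray            # booleans
    Q: int
    score: str
    seed: int


def permute_learning_set(
    data: SurvivalDataset,
    rng: np.random.Generator | int = 0,
    sigma: np.ndarray | None = None,
) -> SurvivalDataset:
    """Partial permutation: (time, event, Z1) rows jointly permuted, Z2 fixed.

    ``sigma`` is a testing hook (the identity returns an equal dataset).
    """
    if sigma is None:
        rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
        sigma = rng.permutation(data.n)
    sigma = np.asarray(sigma)
    return SurvivalDataset(
        time=data.time[sigma],
        event=data.event[sigma],
        confounders=data.confounders[sigma],
        candidates=data.candidates,
        candidate_names=list(data.candidate_names),
        confounder_names=list(data.confounder_names),
        ids=list(data.ids),
    )


def basket_selection(
    data: SurvivalDataset,
    score: str = "IIS",
    Q: int = 100,
    alpha: float = 0.05,
    B: int = 400,
    control: TreeControl | None = None,
    criterion: str = "pseudoR2",
    estimator: str = "BRE",
    seed: int = 0,
) -> SelectionResult:
    """Steps 1–5 of the permutation selection procedure.

    1. fit the ensemble on the learning set and record the observed scores;
    2–3. Q refits on partially permuted copies give null scores;
    4. p_j = (1/Q) * #{q : null score_jq >= observed score_j};
    5. select variables with p_j <= alpha / m2 (Bonferroni).
    """
    if Q < 1:
        raise ValueError("Q must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    score_fn = _SCORES[score]
    m2 = data.m2
    if Q < m2 / alpha:
        warnings.warn(
            f"Q={Q} < m2/alpha={m2 / alpha:.0f}: the Bonferroni threshold "
            "alpha/m2 is below the p-value granularity 1/Q; only p=0 can select"
        )
    ss = np.random.SeedSequence(seed)
    fit_seed, *perm_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * Q + 1)]
    observed_fit = fit_bagging(data, B=B, control=control, criterion=criterion,
                               estimator=estimator, seed=fit_seed)
    observed = score_fn(observed_fit)
    null = np.zeros((Q, m2))
    for q in range(Q):
        rng = np.random.default_rng(perm_seeds[2 * q])
        permuted = permute_learning_set(data, rng)
        fit_q = fit_bagging(permuted, B=B, control=control, criterion=criterion,
                            estimator=estimator, seed=perm_seeds[2 * q + 1])
        null[q] = score_fn(fit_q)
    p_values = (null >= observed[None, :]).mean(axis=0)
    selected = p_values <= alpha / m2
    return SelectionResult(
        variables=list(data.candidate_names),
        observed_scores=observed,
        null_scores=null,
        p_values=p_values,
        alpha=alpha,
        selected=selected,
        Q=Q,
        score=score,
        seed=seed,
    )
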