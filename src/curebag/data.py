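"""Domain containers and delimited-text IO for right-censored survival data.

The central object is :class:`SurvivalDataset`: observed follow-up times
``X_i``, event indicators ``delta_i`` and two groups of covariates with
distinct roles.  *Confounders* (``Z1``) are variables linked to the
nonsusceptible (cured) fraction and enter the model linearly; *candidates*
(``Z2``) are the explanatory variables the trees are allowed to split on.

:class:`StepFunction` is the shared representation for every cumulative
estimator in the package (Breslow / Nelson–Aalen cumulative hazards,
censoring Kaplan–Meier) and supports both continuity conventions, since the
splitting criterion queries the baseline hazard through its left limit.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalDataset",
    "StepFunction",
    "read_survival_table",
    "write_survival_table",
    "evaluate_step",
]


class SchemaError(ValueError):
    """A column required by the schema is missing or mis-declared."""


class ParseError(ValueError):
    """A cell violates the survival-data invariants (reports the row)."""


# ---------------------------------------------------------------------------
# step functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepFunction:
    """Piecewise-constant function with jumps at ``knots``.

    Parameters
    ----------
    knots : strictly increasing jump locations.
    values : function value *at* each knot (cumulative, i.e. including the
        jump there).
    side : ``"right"`` evaluates right-continuously (value at a knot includes
        its jump); ``"left"`` evaluates the left limit (excludes it).
    initial : value before the first knot (0 for cumulative hazards, 1 for
        a survival curve).
    """

    knots: np.ndarray
    values: np.ndarray
    side: str = "right"
    initial: float = 0.0

    def __post_init__(self):
        knots = np.asarray(self.knots, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if knots.ndim != 1 or values.shape != knots.shape:
            raise ValueError("knots and values must be 1-d arrays of equal length")
        if knots.size and np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if self.side not in ("right", "left"):
            raise ValueError(f"side must be 'right' or 'left', got {self.side!r}")
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "values", values)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.knots.size == 0:
            out = np.full(t.shape, self.initial)
            return float(out) if out.ndim == 0 else out
        # right-continuous: last knot <= t ; left-continuous: last knot < t
        search = "right" if self.side == "right" else "left"
        idx = np.searchsorted(self.knots, t, side=search)
        padded = np.concatenate(([self.initial], self.values))
        out = padded[idx]
        return float(out) if out.ndim == 0 else out

    def opposite_side(self) -> "StepFunction":
        """Same function evaluated under the other continuity convention."""
        return replace(self, side="left" if self.side == "right" else "right")


def evaluate_step(f: StepFunction, t) -> float:
    """Evaluate ``f`` at ``t`` under its continuity convention."""
    return f(t)


# ---------------------------------------------------------------------------
# survival dataset
# ---------------------------------------------------------------------------

@dataclass
class SurvivalDataset:
    """Right-censored observations with role-tagged covariates.

    ``time`` must be strictly positive and finite; ``event`` is 0/1.
    ``confounders`` may be empty (shape ``(n, 0)``): the improper model then
    reduces to an unadjusted one with unit risk scores.
    """

    time: np.ndarray
    event: np.ndarray
    confounders: np.ndarray
    candidates: np.ndarray
    candidate_names: list[str]
    confounder_names: list[str] = field(default_factory=list)
    ids: list[str] | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float).ravel()
        self.event = np.asarray(self.event).ravel()
        n = self.time.size
        self.confounders = np.atleast_2d(np.asarray(self.confounders, dtype=float))
        if self.confounders.size == 0:
            self.confounders = np.empty((n, 0))
        self.candidates = np.atleast_2d(np.asarray(self.candidates, dtype=float))
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            bad = int(np.flatnonzero(~np.isfinite(self.time) | (self.time <= 0))[0])
            raise ParseError(f"nonpositive or non-finite time at row {bad}")
        if not np.isin(self.event, (0, 1)).all():
            bad = int(np.flatnonzero(~np.isin(self.event, (0, 1)))[0])
            raise ParseError(f"event indicator outside {{0,1}} at row {bad}")
        self.event = self.event.astype(np.int8)
        for name, mat in (("confounders", self.confounders), ("candidates", self.candidates)):
            if mat.shape[0] != n:
                raise ValueError(f"{name} has {mat.shape[0]} rows, expected {n}")
            if not np.all(np.isfinite(mat)):
                raise ParseError(f"missing or non-numeric value in {name}")
        if len(self.candidate_names) != self.candidates.shape[1]:
            raise ValueError("candidate_names length mismatch")
        if len(set(self.candidate_names)) != len(self.candidate_names):
            raise ValueError("candidate_names must be unique")
        if len(self.confounder_names) != self.confounders.shape[1]:
            if not self.confounder_names:
                self.confounder_names = [f"Z1_{j}" for j in range(self.confounders.shape[1])]
            else:
                raise ValueError("confounder_names length mismatch")
        if self.ids is None:
            self.ids = [str(i) for i in range(n)]
        elif len(self.ids) != n:
            raise ValueError("ids length mismatch")

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def m1(self) -> int:
        return self.confounders.shape[1]

    @property
    def m2(self) -> int:
        return self.candidates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx) -> "SurvivalDataset":
        """Row subset / bootstrap view (``idx`` may repeat indices)."""
        idx = np.asarray(idx)
        return SurvivalDataset(
            time=self.time[idx],
            event=self.event[idx],
            confounders=self.confounders[idx],
            candidates=self.candidates[idx],
            candidate_names=list(self.candidate_names),
            confounder_names=list(self.confounder_names),
            ids=[self.ids[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids, "time": self.time, "event": self.event})
        for j, name in enumerate(self.confounder_names):
            df[name] = self.confounders[:, j]
        for j, name in enumerate(self.candidate_names):
            df[name] = self.candidates[:, j]
        return df


def _detect_sep(source) -> str:
    name = getattr(source, "name", source if isinstance(source, (str, os.PathLike)) else "")
    return "\t" if str(name).endswith((".tsv", ".txt")) else ","


def read_survival_table(
    source,
    time: str,
    event: str,
    confounders: Sequence[str] = (),
    candidates: Sequence[str] | None = None,
    id_col: str | None = None,
    sep: str | None = None,
) -> SurvivalDataset:
    """Read a delimited text file into a :class:`SurvivalDataset`.

    ``candidates=None`` takes every column not otherwise assigned a role.
    The delimiter is autodetected from the extension (``.tsv``/``.txt`` are
    tab, anything else comma) unless ``sep`` is given.
    """
    sep = sep or _detect_sep(source)
    df = pd.read_csv(source, sep=sep, float_precision="round_trip")
    roles = {time: "time", event: "event"}
    for c in confounders:
        if c in roles:
            raise SchemaError(f"column {c!r} assigned two roles")
        roles[c] = "confounder"
    missing = [c for c in roles if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")
    if candidates is None:
        reserved = set(roles) | ({id_col} if id_col else set())
        candidates = [c for c in df.columns if c not in reserved]
    else:
        overlap = set(candidates) & set(roles)
        if overlap:
            raise SchemaError(f"column(s) {sorted(overlap)} assigned two roles")
        missing = [c for c in candidates if c not in df.columns]
        if missing:
            raise SchemaError(f"missing candidate column(s): {missing}")
    if not candidates:
        raise SchemaError("no candidate (Z2) columns")
    t = pd.to_numeric(df[time], errors="coerce").to_numpy()
    if np.any(~np.isfinite(t)):
        raise ParseError(f"non-numeric time at row {int(np.flatnonzero(~np.isfinite(t))[0])}")
    ids = [str(v) for v in df[id_col]] if id_col else None
    return SurvivalDataset(
        time=t,
        event=df[event].to_numpy(),
        confounders=df[list(confounders)].to_numpy(dtype=float) if confounders else np.empty((len(df), 0)),
        candidates=df[list(candidates)].to_numpy(dtype=float),
        candidate_names=list(candidates),
        confounder_names=list(confounders),
        ids=ids,
    )


def write_survival_table(data: SurvivalDataset, target, sep: str | None = None) -> None:
    """Write the dataset as delimited text (exact float round-trip)."""
    sep = sep or _detect_sep(target)
    df = data.to_frame()
    # repr-based formatting round-trips float64 exactly
    out = df.to_csv(sep=sep, index=False, float_format=lambda x: repr(float(x)))
    if isinstance(target, (str, os.PathLike)):
        with open(target, "w") as fh:
            fh.write(out)
    else:
        target.write(out)
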