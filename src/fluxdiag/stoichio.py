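"""Stoichiometric model containers, file I/O, partitioning and estimability checks.

A metabolic model is held as a dense metabolites x reactions coefficient
matrix ``S`` with the production-positive sign convention: ``S[i, j] = +1``
means reaction ``j`` produces one unit of metabolite ``i``.  Measured exchange
reactions are designated separately; partitioning splits the columns into an
exchange block ``S_E`` (measured fluxes ``v_E`` with standard deviations
``sd_E``) and an internal block ``S_I`` whose fluxes are to be estimated.

Models travel as tab-separated tables (metabolite ids in the first column,
reaction ids in the header row); measurements as CSV with columns
``reaction_id,value,sd``.  Overdetermined-MFA models are small (at most a few
hundred reactions), so no sparse representation is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class ModelValidationError(ValueError):
    """A model or measurement table violates a structural invariant."""


class EstimabilityError(ValueError):
    """A design matrix fails the full-column-rank condition.

    Carries the offending :class:`RankReport` in ``report`` when available.
    """

    def __init__(self, message: str, report: "RankReport | None" = None):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class RankReport:
    """Numerical-rank summary of a design matrix."""

    numerical_rank: int
    n_columns: int
    singular_values: np.ndarray
    tolerance: float

    @property
    def is_estimable(self) -> bool:
        return self.numerical_rank == self.n_columns


def check_estimability(M: np.ndarray, tolerance: float | None = None) -> RankReport:
    """Report the numerical rank of ``M`` from its singular values.

    The default threshold is ``max(M.shape) * eps * s_max``, the standard
    criterion for numerical rank determination.  A matrix is *estimable*
    (usable as a least-squares design) iff its numerical rank equals its
    column count.
    """
    M = np.asarray(M, dtype=float)
    if M.size == 0:
        raise ValueError("cannot rank-check an empty matrix")
    s = np.linalg.svd(M, compute_uv=False)
    if tolerance is None:
        tolerance = max(M.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tolerance))
    return RankReport(rank, M.shape[1], s, float(tolerance))


@dataclass
class MetabolicModel:
    """An m x n stoichiometric matrix with metabolite/reaction identifiers.

    ``exchange_reaction_ids`` lists the columns whose fluxes are measured
    exchange fluxes; it may be empty for an internal-only matrix.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    exchange_reaction_ids: list[str] = field(default_factory=list)
    #: orphan (all-zero) metabolite rows are rejected unless disabled; the
    #: random-network tooling disables this for reduced models, where a
    #: species may legitimately lose all its reactions.
    check_orphans: bool = True

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        m, n = len(self.metabolite_ids), len(self.reaction_ids)
        if self.S.shape != (m, n):
            raise ModelValidationError(
                f"S has shape {self.S.shape}, expected ({m}, {n})"
            )
        for name, ids in (("metabolite", self.metabolite_ids),
                          ("reaction", self.reaction_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ModelValidationError(f"duplicate {name} ids: {sorted(dupes)}")
        unknown = set(self.exchange_reaction_ids) - set(self.reaction_ids)
        if unknown:
            raise ModelValidationError(f"unknown exchange reaction ids: {sorted(unknown)}")
        if self.check_orphans:
            orphans = [mid for mid, row in zip(self.metabolite_ids, self.S)
                       if not np.any(row)]
            if orphans:
                raise ModelValidationError(f"orphan species {', '.join(orphans)}")

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def internal_reaction_ids(self) -> list[str]:
        ex = set(self.exchange_reaction_ids)
        return [r for r in self.reaction_ids if r not in ex]

    def column(self, reaction_id: str) -> np.ndarray:
        return self.S[:, self.reaction_ids.index(reaction_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.S, index=self.metabolite_ids,
                            columns=self.reaction_ids)


@dataclass
class PartitionedModel:
    """Column split of a model into measured exchange and internal blocks.

    ``[S_E S_I]`` is an exact column reordering of the parent matrix; ``v_E``
    and ``sd_E`` align with the columns of ``S_E``.  ``S_I`` is guaranteed full
    column rank at construction.
    """

    metabolite_ids: list[str]
    exchange_ids: list[str]
    internal_ids: list[str]
    S_E: np.ndarray
    S_I: np.ndarray
    v_E: np.ndarray
    sd_E: np.ndarray
    unit: str = ""

    @property
    def n_exchange(self) -> int:
        return len(self.exchange_ids)

    @property
    def n_internal(self) -> int:
        return len(self.internal_ids)


def _duplicates(ids: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    return {x for x in ids if x in seen or seen.add(x)}


def load_model(path: str | Path,
               exchange_reaction_ids: Iterable[str] = ()) -> MetabolicModel:
    """Read a model from a tab-separated coefficient table.

    First column: metabolite ids; header row: reaction ids; body: numeric
    stoichiometric coefficients (production-positive).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        S = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ModelValidationError(f"non-numeric cell in {path}: {exc}") from exc
    if np.isnan(S).any():
        i, j = map(int, np.argwhere(np.isnan(S))[0])
        raise ModelValidationError(
            f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r}")
    return MetabolicModel(
        metabolite_ids=[str(i) for i in df.index],
        reaction_ids=[str(c) for c in df.columns],
        S=S,
        exchange_reaction_ids=list(exchange_reaction_ids),
    )


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write the coefficient table in the same TSV dialect read by load_model."""
    model.to_frame().to_csv(path, sep="\t", index_label="metabolite_id")


def load_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement CSV with columns reaction_id, value, sd."""
    df = pd.read_csv(path)
    required = {"reaction_id", "value", "sd"}
    missing = required - set(df.columns)
    if missing:
        raise ModelValidationError(f"measurement file missing columns {sorted(missing)}")
    if (df["sd"] < 0).any():
        bad = df.loc[df["sd"] < 0, "reaction_id"].tolist()
        raise ModelValidationError(f"negative sd for {bad}")
    return df


def partition(model: MetabolicModel, measurements: pd.DataFrame,
              rank_tolerance: float | None = None) -> PartitionedModel:
    """Split ``S`` into ``[S_E S_I]`` using a measurement table.

    Measured columns are collected in measurement order into ``S_E``; the
    remaining columns form ``S_I`` in model order.  ``S_I`` must have full
    column rank (unique least-squares flux solution) and must be non-empty.
    """
    ids = list(measurements["reaction_id"].astype(str))
    dupes = _duplicates(ids)
    if dupes:
        raise ModelValidationError(f"duplicate measured reaction ids: {sorted(dupes)}")
    unknown = [r for r in ids if r not in model.reaction_ids]
    if unknown:
        raise ModelValidationError(f"measured reaction ids not in model: {unknown}")
    sd = measurements["sd"].to_numpy(dtype=float)
    if (sd < 0).any():
        raise ModelValidationError("negative measurement sd")

    measured = set(ids)
    internal_ids = [r for r in model.reaction_ids if r not in measured]
    if not internal_ids:
        raise EstimabilityError("all reactions measured: nothing to estimate")
    col = {r: j for j, r in enumerate(model.reaction_ids)}
    S_E = model.S[:, [col[r] for r in ids]]
    S_I = model.S[:, [col[r] for r in internal_ids]]
    report = check_estimability(S_I, rank_tolerance)
    if not report.is_estimable:
        raise EstimabilityError(
            f"S_I rank {report.numerical_rank} < {report.n_columns} columns: "
            "internal fluxes are not uniquely estimable", report)
    return PartitionedModel(
        metabolite_ids=list(model.metabolite_ids),
        exchange_ids=ids,
        internal_ids=internal_ids,
        S_E=S_E,
        S_I=S_I,
        v_E=measurements["value"].to_numpy(dtype=float),
        sd_E=sd,
    )


def remove_reactions(model: MetabolicModel, ids: Iterable[str],
                     forbid_orphans: bool = True) -> MetabolicModel:
    """Drop reaction columns, optionally refusing removals that orphan a species.

    An orphan is a metabolite left with an all-zero row, i.e. participating in
    no remaining reaction.
    """
    ids = set(ids)
    unknown = ids - set(model.reaction_ids)
    if unknown:
        raise ModelValidationError(f"cannot remove unknown reactions: {sorted(unknown)}")
    keep = [j for j, r in enumerate(model.reaction_ids) if r not in ids]
    S_new = model.S[:, keep]
    if forbid_orphans:
        orphans = [mid for mid, row in zip(model.metabolite_ids, S_new)
                   if not np.any(row)]
        if orphans:
            raise ModelValidationError(
                f"removal would orphan species {', '.join(orphans)}")
    return MetabolicModel(
        metabolite_ids=list(model.metabolite_ids),
        reaction_ids=[model.reaction_ids[j] for j in keep],
        S=S_new,
        exchange_reaction_ids=[r for r in model.exchange_reaction_ids
                               if r not in ids],
        check_orphans=forbid_orphans,
    )
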