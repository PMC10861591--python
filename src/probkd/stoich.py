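"""Stoichiometry number matrix model of a biochemical network.

A network of J reactants/products and I reactions is modelled as an integer
J x I matrix S whose columns are reaction vectors: negative entries count
molecules consumed by the reaction, positive entries molecules produced.
The canonical in-memory orientation is always reactants-as-rows x
reactions-as-columns; an orientation flag at load time only affects parsing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StoichiometryMatrix",
    "ValidationReport",
    "MatrixFormatError",
    "load_matrix",
    "dump_matrix",
    "validate_network",
    "deduplicate_reactions",
]

#: smallest admissible number of reactants/products
MIN_REACTANTS = 4
#: smallest admissible number of reactions
MIN_REACTIONS = 6
#: reactions must outnumber reactants by at least this margin
MIN_REACTION_EXCESS = 2


class MatrixFormatError(ValueError):
    """Raised when a delimited table cannot be read as an integer matrix."""


@dataclass(frozen=True)
class StoichiometryMatrix:
    """Integer stoichiometry number matrix with row/column identifiers.

    Attributes
    ----------
    entries:
        J x I integer array; ``entries[j, i]`` is the (signed) stoichiometry
        number of reactant ``j`` in reaction ``i``.
    reactant_ids:
        J unique row labels.
    reaction_ids:
        I unique column labels.
    """

    entries: np.ndarray
    reactant_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries)
        if entries.ndim != 2:
            raise MatrixFormatError("stoichiometry matrix must be 2-dimensional")
        if not np.issubdtype(entries.dtype, np.integer):
            if not np.all(np.isfinite(entries)) or np.any(entries != np.round(entries)):
                raise MatrixFormatError("stoichiometry numbers must be integers")
            entries = entries.astype(np.int64)
        object.__setattr__(self, "entries", entries.astype(np.int64, copy=False))
        object.__setattr__(self, "reactant_ids", tuple(str(r) for r in self.reactant_ids))
        object.__setattr__(self, "reaction_ids", tuple(str(r) for r in self.reaction_ids))
        if len(self.reactant_ids) != entries.shape[0]:
            raise MatrixFormatError("reactant_ids length does not match row count")
        if len(self.reaction_ids) != entries.shape[1]:
            raise MatrixFormatError("reaction_ids length does not match column count")
        if len(set(self.reactant_ids)) != len(self.reactant_ids):
            raise MatrixFormatError("reactant_ids must be unique")
        if len(set(self.reaction_ids)) != len(self.reaction_ids):
            raise MatrixFormatError("reaction_ids must be unique")

    @property
    def J(self) -> int:
        """Number of reactants/products (rows)."""
        return self.entries.shape[0]

    @property
    def I_bar(self) -> int:
        """Number of reactions (columns)."""
        return self.entries.shape[1]

    def reaction_vector(self, reaction_id: str) -> np.ndarray:
        """Signed stoichiometry numbers of one reaction (a column)."""
        i = self.reaction_ids.index(reaction_id)
        return self.entries[:, i].copy()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, index=list(self.reactant_ids), columns=list(self.reaction_ids)
        )

    def select_reactions(self, reaction_ids: Sequence[str]) -> "StoichiometryMatrix":
        idx = [self.reaction_ids.index(r) for r in reaction_ids]
        return StoichiometryMatrix(
            self.entries[:, idx], self.reactant_ids, tuple(reaction_ids)
        )


@dataclass
class ValidationReport:
    """Outcome of the network validity checks.

    ``valid`` is true only when the (deduplicated) matrix satisfies all of:
    J >= 4, I >= 6, I - J >= 2, no all-zero reaction column, and a
    non-trivial null space (nullity >= 1).
    """

    valid: bool
    removed_duplicate_reactions: list[str] = field(default_factory=list)
    violations: list[str] = field(default_factory=list)
    rank: int = 0
    nullity: int = 0


def _coerce_integer_frame(frame: pd.DataFrame) -> np.ndarray:
    values = frame.to_numpy()
    out = np.empty(values.shape, dtype=np.int64)
    for (j, i), v in np.ndenumerate(values):
        try:
            f = float(v)
        except (TypeError, ValueError) as exc:
            raise MatrixFormatError(
                f"non-numeric entry at row '{frame.index[j]}', column '{frame.columns[i]}': {v!r}"
            ) from exc
        if not np.isfinite(f) or f != round(f):
            raise MatrixFormatError(
                f"non-integral entry at row '{frame.index[j]}', column '{frame.columns[i]}': {v!r}"
            )
        out[j, i] = int(round(f))
    return out


def load_matrix(
    source: str | Path | pd.DataFrame,
    orientation: str = "reactions-as-columns",
    sep: str | None = None,
) -> StoichiometryMatrix:
    """Read a stoichiometry number matrix from a delimited-text table.

    Parameters
    ----------
    source:
        Path to a CSV/TSV file (header row of labels, first column of
        labels) or an already-parsed labelled DataFrame.
    orientation:
        ``"reactions-as-columns"`` (the canonical layout) or
        ``"reactions-as-rows"`` (the table is transposed on load).
    sep:
        Field delimiter; inferred from the file suffix when omitted
        (``.tsv`` -> tab, otherwise comma).
    """
    if orientation not in ("reactions-as-columns", "reactions-as-rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    if isinstance(source, pd.DataFrame):
        frame = source.copy()
    else:
        path = Path(source)
        if sep is None:
            sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        frame = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    if frame.isna().any().any():
        raise MatrixFormatError("ragged or incomplete table: missing cells detected")
    if orientation == "reactions-as-rows":
        frame = frame.T
    entries = _coerce_integer_frame(frame)
    return StoichiometryMatrix(
        entries,
        tuple(str(r) for r in frame.index),
        tuple(str(c) for c in frame.columns),
    )


def dump_matrix(S: StoichiometryMatrix, path: str | Path, sep: str | None = None) -> None:
    """Write the canonical (reactants x reactions) table back to disk."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    S.to_frame().to_csv(path, sep=sep)


def _duplicate_columns(entries: np.ndarray, reaction_ids: Sequence[str]) -> tuple[list[int], list[str]]:
    """Indices to keep (first occurrence) and ids of removed exact duplicates."""
    seen: dict[bytes, int] = {}
    keep: list[int] = []
    removed: list[str] = []
    for i in range(entries.shape[1]):
        key = entries[:, i].tobytes()
        if key in seen:
            removed.append(reaction_ids[i])
        else:
            seen[key] = i
            keep.append(i)
    return keep, removed


def deduplicate_reactions(S: StoichiometryMatrix) -> tuple[StoichiometryMatrix, list[str]]:
    """Drop reaction columns that are exact integer duplicates, keeping the first."""
    keep, removed = _duplicate_columns(S.entries, S.reaction_ids)
    if not removed:
        return S, []
    kept_ids = tuple(S.reaction_ids[i] for i in keep)
    return StoichiometryMatrix(S.entries[:, keep], S.reactant_ids, kept_ids), removed


def validate_network(S: StoichiometryMatrix) -> ValidationReport:
    """Check a matrix against the minimum-network requirements.

    Duplicate reaction columns are reported for removal (one representative
    kept).  Violations are reported, never raised; downstream operations
    refuse matrices whose report is not valid.
    """
    dedup, removed = deduplicate_reactions(S)
    violations: list[str] = []
    if dedup.J < MIN_REACTANTS:
        violations.append(f"J >= {MIN_REACTANTS}: network has only {dedup.J} reactants/products")
    if dedup.I_bar < MIN_REACTIONS:
        violations.append(f"I >= {MIN_REACTIONS}: network has only {dedup.I_bar} reactions")
    if dedup.I_bar - dedup.J < MIN_REACTION_EXCESS:
        violations.append(
            f"I - J >= {MIN_REACTION_EXCESS}: difference is {dedup.I_bar - dedup.J}"
        )
    zero_cols = [
        dedup.reaction_ids[i]
        for i in range(dedup.I_bar)
        if not dedup.entries[:, i].any()
    ]
    if zero_cols:
        violations.append("trivial reaction vector: " + ", ".join(zero_cols))
    rank = int(np.linalg.matrix_rank(dedup.entries.astype(float)))
    nullity = dedup.I_bar - rank
    if nullity < 1:
        violations.append("trivial null space: nullity is 0")
    return ValidationReport(
        valid=not violations,
        removed_duplicate_reactions=removed,
        violations=violations,
        rank=rank,
        nullity=nullity,
    )
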