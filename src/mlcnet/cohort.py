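"""Cohort data model and delimited-text I/O.

A cohort is a subjects-by-variables table of real-valued measurements with
missing values allowed, plus per-subject group labels (e.g. ``never_smoker``,
``smoker``, ``copd``) and per-variable metadata assigning each variable to a
measurement level — clinical, lung function, bone marrow or circulating
blood — and a kind (continuous or count).  Every downstream stage (group
comparisons, correlation networks, stratification, subsampling) consumes this
one container.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LEVELS = ("clinical", "lung_function", "bone_marrow", "blood")
KINDS = ("continuous", "count")

#: tokens treated as missing on read (case-insensitive); "NA" is written.
MISSING_TOKENS = frozenset({"", "na", "nan"})


class CohortValidationError(ValueError):
    """A cohort, metadata table or selection violates a structural invariant."""


class CohortParseError(ValueError):
    """A delimited-text cell could not be interpreted as a number or NA."""


@dataclass(frozen=True)
class VariableMeta:
    """Metadata for one measured variable.

    Parameters
    ----------
    name : str
        Unique variable identifier (column name in the values table).
    level : str
        Measurement compartment, one of :data:`LEVELS`.
    kind : str
        ``"continuous"`` or ``"count"``.
    units : str
        Free-text units; may be empty.
    """

    name: str
    level: str
    kind: str
    units: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise CohortValidationError("variable name must be non-empty")
        if self.level not in LEVELS:
            raise CohortValidationError(
                f"variable {self.name!r}: level {self.level!r} not in {LEVELS}"
            )
        if self.kind not in KINDS:
            raise CohortValidationError(
                f"variable {self.name!r}: kind {self.kind!r} not in {KINDS}"
            )


class CohortTable:
    """Validated subjects-by-variables table with groups and variable metadata.

    Parameters
    ----------
    data : pandas.DataFrame
        Numeric matrix, index = subject ids, columns = variable names;
        ``NaN`` encodes missing values.
    groups : pandas.Series
        Group label per subject, aligned with ``data.index``.
    meta : sequence of VariableMeta
        One entry per column of ``data`` (any order; reordered to match).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        groups: pd.Series,
        meta: Sequence[VariableMeta],
    ) -> None:
        if data.shape[0] < 1:
            raise CohortValidationError("cohort must contain at least one subject")
        if data.shape[1] < 1:
            raise CohortValidationError("cohort must contain at least one variable")
        if not data.index.is_unique:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise CohortValidationError(f"duplicate subject ids: {dupes}")
        groups = groups.reindex(data.index)
        if groups.isna().any():
            missing = groups.index[groups.isna()].tolist()
            raise CohortValidationError(f"missing group label for subjects: {missing}")
        by_name = {m.name: m for m in meta}
        if len(by_name) != len(list(meta)):
            raise CohortValidationError("duplicate variable names in metadata")
        unmapped = [c for c in data.columns if c not in by_name]
        if unmapped:
            raise CohortValidationError(
                f"variables missing from metadata: {unmapped}"
            )
        if len(by_name) != data.shape[1]:
            extra = sorted(set(by_name) - set(data.columns))
            raise CohortValidationError(
                f"metadata count ({len(by_name)}) does not match column count "
                f"({data.shape[1]}); unmatched metadata entries: {extra}"
            )
        self.data = data.astype(float)
        self.groups = groups.astype(str)
        self.meta: tuple[VariableMeta, ...] = tuple(by_name[c] for c in data.columns)

    # ------------------------------------------------------------------ views
    @property
    def subject_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def variables(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]

    @property
    def levels(self) -> dict[str, str]:
        """Mapping variable name -> level label."""
        return {m.name: m.level for m in self.meta}

    @property
    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [m.name for m in self.meta],
                "level": [m.level for m in self.meta],
                "kind": [m.kind for m in self.meta],
                "units": [m.units for m in self.meta],
            }
        )

    def group_sizes(self) -> dict[str, int]:
        counts = self.groups.value_counts()
        return {str(g): int(counts[g]) for g in sorted(counts.index)}

    # ------------------------------------------------------------- selections
    def select_subjects(self, mask_or_ids) -> "CohortTable":
        """Restrict to a subset of subjects (boolean mask or id list)."""
        sub = self.data.loc[mask_or_ids]
        if sub.shape[0] == 0:
            raise CohortValidationError("subject selection is empty")
        return CohortTable(sub, self.groups.loc[sub.index], self.meta)

    def equals(self, other: "CohortTable") -> bool:
        return (
            self.variables == other.variables
            and self.subject_ids == other.subject_ids
            and list(self.groups) == list(other.groups)
            and self.meta == other.meta
            and np.array_equal(
                self.data.to_numpy(), other.data.to_numpy(), equal_nan=True
            )
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CohortTable({self.n_subjects} subjects x {self.n_variables} "
            f"variables, groups={self.group_sizes()})"
        )


def select_variables(cohort: CohortTable, levels: Iterable[str]) -> CohortTable:
    """Restrict a cohort to variables whose level is in ``levels``.

    Subjects are unchanged.  Raises :class:`CohortValidationError` if a level
    label is unknown or no variable matches.
    """
    levels = set(levels)
    unknown = levels - set(LEVELS)
    if unknown:
        raise CohortValidationError(f"unknown levels: {sorted(unknown)}")
    keep = [m.name for m in cohort.meta if m.level in levels]
    if not keep:
        raise CohortValidationError(
            f"no variables with level in {sorted(levels)}"
        )
    meta = [m for m in cohort.meta if m.name in set(keep)]
    return CohortTable(cohort.data[keep], cohort.groups, meta)


# ---------------------------------------------------------------------- I/O

def _parse_cell(raw: str, row_label, column: str) -> float:
    token = raw.strip()
    if token.lower() in MISSING_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise CohortParseError(
            f"non-numeric value {raw!r} in row {row_label!r}, column {column!r}"
        ) from None


def read_cohort(values_path, meta_path, sep: str = ",") -> CohortTable:
    """Read a cohort from a values CSV and a metadata CSV.

    The values file must have columns ``subject_id``, ``group``, then one
    column per variable; empty cells and the tokens ``NA``/``NaN`` (any case)
    are read as missing.  The metadata file must have columns ``name``,
    ``level``, ``kind`` and optionally ``units`` covering every variable.
    """
    values_path, meta_path = Path(values_path), Path(meta_path)
    raw = pd.read_csv(values_path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("subject_id", "group"):
        if col not in raw.columns:
            raise CohortValidationError(
                f"values file {values_path} lacks required column {col!r}"
            )
    var_cols = [c for c in raw.columns if c not in ("subject_id", "group")]
    if not var_cols:
        raise CohortValidationError("values file contains no variable columns")

    meta_raw = pd.read_csv(meta_path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("name", "level", "kind"):
        if col not in meta_raw.columns:
            raise CohortValidationError(
                f"metadata file {meta_path} lacks required column {col!r}"
            )
    meta_by_name: dict[str, VariableMeta] = {}
    for _, row in meta_raw.iterrows():
        meta_by_name[row["name"]] = VariableMeta(
            name=row["name"],
            level=row["level"],
            kind=row["kind"],
            units=row.get("units", "") or "",
        )
    unmapped = [c for c in var_cols if c not in meta_by_name]
    if unmapped:
        raise CohortValidationError(
            f"variables missing from metadata: {unmapped}"
        )

    subject_ids = raw["subject_id"].tolist()
    values = np.empty((len(raw), len(var_cols)), dtype=float)
    for j, col in enumerate(var_cols):
        cells = raw[col].tolist()
        for i, cell in enumerate(cells):
            values[i, j] = _parse_cell(cell, subject_ids[i], col)
    data = pd.DataFrame(values, index=pd.Index(subject_ids, name="subject_id"),
                        columns=var_cols)
    groups = pd.Series(raw["group"].tolist(), index=data.index, name="group")
    if (groups.str.strip() == "").any():
        bad = groups.index[groups.str.strip() == ""].tolist()
        raise CohortValidationError(f"empty group label for subjects: {bad}")
    return CohortTable(data, groups, [meta_by_name[c] for c in var_cols])


def write_cohort(cohort: CohortTable, values_path, meta_path, sep: str = ",") -> None:
    """Write a cohort as the standard values/metadata CSV pair.

    Missing values are written as ``NA``; the pair round-trips through
    :func:`read_cohort` losslessly (up to float formatting).
    """
    if not isinstance(cohort, CohortTable):
        raise CohortValidationError("write_cohort requires a CohortTable")
    out = cohort.data.copy()
    out.insert(0, "group", cohort.groups)
    out.index.name = "subject_id"
    out.to_csv(values_path, sep=sep, na_rep="NA")
    cohort.meta_frame.to_csv(meta_path, sep=sep, index=False)
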