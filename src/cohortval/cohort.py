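"""Cohort tables: typed patient records with real/virtual provenance.

A :class:`Cohort` is an ordered table of patient records in which every
variable carries a declared kind (``continuous``, ``discrete`` or
``time_to_event``).  Time-to-event variables are encoded as a numeric time
column plus a companion 0/1 event-indicator column (1 = event observed,
0 = censored).  Cohorts are read from and written to plain CSV (comma
separator, UTF-8, ``.`` decimal, mandatory header row); cells equal to
``""`` or ``"NA"`` are treated as missing.
"""

from __future__ import annotations

import csv
import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
DISCRETE = "discrete"
TIME_TO_EVENT = "time_to_event"
KINDS = (CONTINUOUS, DISCRETE, TIME_TO_EVENT)

#: cell contents interpreted as a missing value on read
MISSING_TOKENS = ("", "NA")


class CohortError(ValueError):
    """Raised for malformed cohort files or invalid cohort operations."""


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of a single cohort variable.

    Parameters
    ----------
    name:
        Column name; non-empty and unique within a cohort.
    kind:
        One of ``continuous``, ``discrete``, ``time_to_event``.
    event_indicator_name:
        Name of the companion 0/1 event column.  Required for (and only
        allowed on) ``time_to_event`` variables.
    """

    name: str
    kind: str
    event_indicator_name: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise CohortError("variable name must be non-empty")
        if self.kind not in KINDS:
            raise CohortError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.kind == TIME_TO_EVENT and not self.event_indicator_name:
            raise CohortError(
                f"time-to-event variable {self.name!r} needs event_indicator_name"
            )
        if self.kind != TIME_TO_EVENT and self.event_indicator_name is not None:
            raise CohortError(
                f"event_indicator_name only applies to time_to_event ({self.name!r})"
            )


@dataclass(frozen=True)
class ContextDoc:
    """Free-text Context-of-Use and Question-of-Interest statements."""

    cou: str
    qoi: str

    def to_dict(self) -> dict:
        return {"cou": self.cou, "qoi": self.qoi}


@dataclass
class Cohort:
    """Typed table of patient records.

    ``data`` holds one column per CSV column, in header order.  Continuous,
    time-to-event and event-indicator columns are float64 with NaN marking
    missing cells; discrete columns are object dtype with None marking
    missing cells.  ``variables`` lists the analysis variables (event
    indicator columns are companions referenced via
    :attr:`VariableSpec.event_indicator_name`, not variables themselves).
    """

    data: pd.DataFrame
    variables: list[VariableSpec]
    provenance: str = "unspecified"
    source: str | None = None

    def __post_init__(self) -> None:
        if self.provenance not in ("real", "virtual", "unspecified"):
            raise CohortError(f"unknown provenance {self.provenance!r}")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise CohortError("duplicate variable names")
        for v in self.variables:
            if v.name not in self.data.columns:
                raise CohortError(f"variable {v.name!r} missing from data")
            if v.kind == TIME_TO_EVENT:
                if v.event_indicator_name not in self.data.columns:
                    raise CohortError(
                        f"event indicator column {v.event_indicator_name!r} "
                        f"for {v.name!r} missing from data"
                    )
        self._validate_values()

    # -- validation ------------------------------------------------------

    def _validate_values(self) -> None:
        for v in self.variables:
            if v.kind in (CONTINUOUS, TIME_TO_EVENT):
                col = self.data[v.name].to_numpy(dtype=float)
                present = ~np.isnan(col)
                if np.any(~np.isfinite(col[present])):
                    raise CohortError(f"non-finite value in {v.name!r}")
                if v.kind == TIME_TO_EVENT and np.any(col[present] < 0):
                    raise CohortError(f"negative time in {v.name!r}")
            if v.kind == TIME_TO_EVENT:
                ind = self.data[v.event_indicator_name].to_numpy(dtype=float)
                present = ~np.isnan(ind)
                if not np.all(np.isin(ind[present], (0.0, 1.0))):
                    raise CohortError(
                        f"event indicator {v.event_indicator_name!r} outside {{0, 1}}"
                    )

    # -- accessors -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise CohortError(f"unknown variable {name!r}")

    def kind_of(self, name: str) -> str:
        return self.variable(name).kind

    def values(self, name: str) -> np.ndarray | pd.Series:
        """Raw column values (float array for numeric kinds, Series for discrete)."""
        v = self.variable(name)
        if v.kind == DISCRETE:
            return self.data[name]
        return self.data[name].to_numpy(dtype=float)

    def numeric(self, name: str) -> np.ndarray:
        """Complete (non-missing) values of a continuous variable."""
        v = self.variable(name)
        if v.kind != CONTINUOUS:
            raise CohortError(f"variable {name!r} is {v.kind}, expected continuous")
        col = self.data[name].to_numpy(dtype=float)
        return col[~np.isnan(col)]

    def complete_mask(self, variables: Sequence[str]) -> np.ndarray:
        """Boolean mask of rows with no missing value in ``variables``."""
        mask = np.ones(self.n, dtype=bool)
        for name in variables:
            v = self.variable(name)
            cols = [name]
            if v.kind == TIME_TO_EVENT:
                cols.append(v.event_indicator_name)
            for c in cols:
                mask &= ~self.data[c].isna().to_numpy()
        return mask

    def fingerprint(self) -> dict:
        """Identify the cohort for report provenance (shape + content hash)."""
        h = hashlib.sha256()
        h.update(",".join(self.data.columns).encode())
        for _, row in self.data.iterrows():
            h.update(
                ",".join("" if pd.isna(x) else str(x) for x in row).encode()
            )
        return {
            "source": self.source,
            "provenance": self.provenance,
            "n_rows": self.n,
            "n_columns": int(self.data.shape[1]),
            "sha256": h.hexdigest(),
        }


# -- structure comparison ------------------------------------------------


@dataclass
class StructureReport:
    """Outcome of comparing the variable structure of two cohorts."""

    passed: bool
    discrepancies: list[str] = field(default_factory=list)
    order_differs: bool = False

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "discrepancies": list(self.discrepancies),
            "order_differs": self.order_differs,
        }


def check_structure_match(real: Cohort, virtual: Cohort) -> StructureReport:
    """Compare variable names and kinds between a real/virtual pair.

    Variables present on one side only and kind mismatches fail the check;
    a difference in column order is reported but does not fail.
    """
    discrepancies: list[str] = []
    real_vars = {v.name: v for v in real.variables}
    virt_vars = {v.name: v for v in virtual.variables}
    for name in real_vars:
        if name not in virt_vars:
            discrepancies.append(f"variable {name!r} present only in real cohort")
    for name in virt_vars:
        if name not in real_vars:
            discrepancies.append(f"variable {name!r} present only in virtual cohort")
    for name in real_vars.keys() & virt_vars.keys():
        rv, vv = real_vars[name], virt_vars[name]
        if rv.kind != vv.kind:
            discrepancies.append(
                f"kind mismatch for {name!r}: {rv.kind} (real) vs {vv.kind} (virtual)"
            )
        elif rv.event_indicator_name != vv.event_indicator_name:
            discrepancies.append(
                f"event indicator mismatch for {name!r}: "
                f"{rv.event_indicator_name!r} (real) vs "
                f"{vv.event_indicator_name!r} (virtual)"
            )
    order_differs = (
        not discrepancies and real.variable_names != virtual.variable_names
    )
    return StructureReport(
        passed=not discrepancies,
        discrepancies=discrepancies,
        order_differs=order_differs,
    )


# -- loading -------------------------------------------------------------


def _is_missing(cell: str) -> bool:
    return cell in MISSING_TOKENS


def _parse_float(cell: str, column: str) -> float:
    try:
        value = float(cell)
    except ValueError:
        raise CohortError(f"non-numeric value {cell!r} in column {column!r}") from None
    if not math.isfinite(value):
        raise CohortError(f"non-finite value {cell!r} in column {column!r}")
    return value


def load_cohort(
    path: str | Path,
    variable_kinds: Mapping[str, str] | None = None,
    provenance: str = "unspecified",
    event_indicators: Mapping[str, str] | None = None,
) -> Cohort:
    """Read a cohort from CSV.

    Parameters
    ----------
    path:
        CSV file with a header row; comma separator, UTF-8, ``.`` decimal.
    variable_kinds:
        Mapping column name -> kind.  Unmapped columns default to
        ``continuous`` when every present cell parses as a number, else
        ``discrete``.
    provenance:
        ``real``, ``virtual`` or ``unspecified``.
    event_indicators:
        Mapping time-to-event variable name -> companion 0/1 event column
        name.  Required for every declared ``time_to_event`` variable.
    """
    variable_kinds = dict(variable_kinds or {})
    event_indicators = dict(event_indicators or {})
    path = Path(path)
    try:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                raise CohortError(f"{path}: empty file, header row required") from None
            rows = list(reader)
    except OSError as exc:
        raise CohortError(f"cannot read {path}: {exc}") from exc

    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise CohortError(f"{path}: duplicate header names {dupes}")
    # a fully blank line means one all-missing record
    rows = [[""] * len(header) if row == [] else row for row in rows]
    for i, row in enumerate(rows):
        if len(row) != len(header):
            raise CohortError(
                f"{path}: row {i + 2} has {len(row)} fields, expected {len(header)}"
            )

    # declared names absent from the header are ignored: a shared config may
    # describe more variables than one file has; check_structure_match reports
    # the discrepancy between the pair
    variable_kinds = {k: v for k, v in variable_kinds.items() if k in header}
    event_indicators = {
        k: v for k, v in event_indicators.items() if k in header
    }
    for name, kind in variable_kinds.items():
        if kind not in KINDS:
            raise CohortError(f"unknown kind {kind!r} for variable {name!r}")
        if kind == TIME_TO_EVENT:
            ind = event_indicators.get(name)
            if ind is None:
                raise CohortError(
                    f"time-to-event variable {name!r} needs an event indicator column"
                )
            if ind not in header:
                raise CohortError(
                    f"{path}: event indicator column {ind!r} for {name!r} not found"
                )

    indicator_cols = set(event_indicators.values())
    columns: dict[str, list] = {}
    kinds: dict[str, str] = {}
    for j, name in enumerate(header):
        cells = [row[j] for row in rows]
        if name in indicator_cols:
            kind = "indicator"
        elif name in variable_kinds:
            kind = variable_kinds[name]
        else:
            numeric = all(_is_missing(c) or _parses_as_float(c) for c in cells)
            kind = CONTINUOUS if numeric else DISCRETE
        if kind == DISCRETE:
            columns[name] = [None if _is_missing(c) else c for c in cells]
        else:
            columns[name] = [
                math.nan if _is_missing(c) else _parse_float(c, name) for c in cells
            ]
        kinds[name] = kind

    data = pd.DataFrame(columns, columns=header)
    for name, kind in kinds.items():
        if kind != DISCRETE:
            data[name] = data[name].astype(float)
        else:
            data[name] = data[name].astype(object)

    variables = [
        VariableSpec(
            name=name,
            kind=kinds[name],
            event_indicator_name=event_indicators.get(name)
            if kinds[name] == TIME_TO_EVENT
            else None,
        )
        for name in header
        if kinds[name] != "indicator"
    ]
    return Cohort(data=data, variables=variables, provenance=provenance,
                  source=str(path))


def _parses_as_float(cell: str) -> bool:
    try:
        return math.isfinite(float(cell))
    except ValueError:
        return False


# -- complete cases ------------------------------------------------------


def complete_cases(
    cohort: Cohort, variables: Sequence[str]
) -> tuple[Cohort, int]:
    """Restrict a cohort to rows fully observed on ``variables``.

    Returns the filtered cohort and the number of rows dropped.  With an
    empty variable list this is the identity.
    """
    for name in variables:
        cohort.variable(name)  # raises on unknown name
    mask = cohort.complete_mask(variables)
    dropped = int((~mask).sum())
    filtered = Cohort(
        data=cohort.data.loc[mask].reset_index(drop=True),
        variables=list(cohort.variables),
        provenance=cohort.provenance,
        source=cohort.source,
    )
    return filtered, dropped


# -- writing -------------------------------------------------------------


def _format_cell(value, kind: str) -> str:
    if pd.isna(value):
        return ""
    if kind == DISCRETE:
        return str(value)
    return repr(float(value))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort to CSV so that :func:`load_cohort` round-trips it.

    Floats are written with shortest round-trip ``repr``; missing cells
    become empty fields; discrete values containing separators are quoted.
    """
    kinds = {v.name: v.kind for v in cohort.variables}
    for v in cohort.variables:
        if v.kind == TIME_TO_EVENT:
            kinds[v.event_indicator_name] = CONTINUOUS
    path = Path(path)
    try:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            header = list(cohort.data.columns)
            writer.writerow(header)
            for _, row in cohort.data.iterrows():
                writer.writerow(
                    _format_cell(row[c], kinds.get(c, CONTINUOUS)) for c in header
                )
    except OSError as exc:
        raise CohortError(f"cannot write {path}: {exc}") from exc
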