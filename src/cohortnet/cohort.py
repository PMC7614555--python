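"""Cohort tables: domain types, CSV I/O, descriptives, subscore combination.

A cohort is a child-by-measure matrix in raw measure units together with a
missingness mask and per-measure metadata (category, scale range,
orientation). Everything downstream — standardisation, imputation, factor
and network analysis — consumes this container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MeasureDefinition",
    "CohortTable",
    "Descriptives",
    "read_cohort_csv",
    "write_cohort_csv",
    "descriptives",
    "combine_subscores",
    "SchemaError",
    "CellParseError",
]

#: measure categories used for node colouring in network figures
CATEGORIES = ("SES", "cognition", "attitude", "mental-health", "education", "speed")


class SchemaError(ValueError):
    """CSV header does not match the declared measure schema."""


class CellParseError(ValueError):
    """A non-missing cell could not be parsed as a decimal number."""


@dataclass(frozen=True)
class MeasureDefinition:
    """Metadata for one analysis measure.

    Parameters
    ----------
    name : str
        Unique measure name (e.g. ``"Sums"``).
    category : str
        One of ``SES, cognition, attitude, mental-health, education, speed``.
    scale_min, scale_max : float
        Admissible range in measure units.
    discrete : bool
        True for integer-ish scores (e.g. number correct).
    higher_is_better : bool
        Orientation flag; used when combining subscores so that, e.g.,
        inter-click times (lower is better) align with accuracy scores.
    """

    name: str
    category: str
    scale_min: float
    scale_max: float
    discrete: bool = False
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.name!r}")
        if not self.scale_min < self.scale_max:
            raise ValueError(f"scale_min >= scale_max for measure {self.name!r}")


@dataclass
class CohortTable:
    """Child × measure matrix with an explicit missingness mask."""

    child_ids: list[str]
    measures: list[MeasureDefinition]
    values: np.ndarray  # (n_children, n_measures), raw measure units
    missing_mask: np.ndarray  # same shape, True where missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.values.shape
        if len(self.child_ids) != n or len(self.measures) != p:
            raise ValueError("shape mismatch between ids/measures and value matrix")
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape differs from values")
        if len(set(self.child_ids)) != n:
            raise ValueError("duplicate child_ids")
        names = [m.name for m in self.measures]
        if len(set(names)) != p:
            raise ValueError("duplicate measure names")
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValueError("observed cells must be finite")

    @property
    def n_children(self) -> int:
        return self.values.shape[0]

    @property
    def measure_names(self) -> list[str]:
        return [m.name for m in self.measures]

    def row_missing_fraction(self) -> np.ndarray:
        return self.missing_mask.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.child_ids, columns=self.measure_names)
        return df.mask(self.missing_mask)


@dataclass
class Descriptives:
    """Per-measure mean, SD (n−1), min and max over observed cells."""

    measure_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    min: np.ndarray
    max: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"M": self.mean, "SD": self.sd, "min": self.min, "max": self.max},
            index=self.measure_names,
        )

    def to_json(self) -> str:
        out = {
            name: {"M": m, "SD": s, "min": lo, "max": hi}
            for name, m, s, lo, hi in zip(
                self.measure_names, self.mean, self.sd, self.min, self.max
            )
        }
        return json.dumps(out, indent=2)


def read_cohort_csv(
    path,
    schema: list[MeasureDefinition],
    *,
    id_column: str = "child_id",
    na_values: tuple[str, ...] = ("", "NA"),
) -> CohortTable:
    """Read a cohort table from a headered CSV file.

    The header must contain ``id_column`` plus exactly the schema's measure
    names (order-insensitive). Cells equal to one of ``na_values`` are
    flagged missing; every other cell must parse as a decimal number.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if id_column not in df.columns:
        raise SchemaError(f"missing id column {id_column!r}")
    names = {m.name for m in schema}
    data_cols = [c for c in df.columns if c != id_column]
    unknown = sorted(set(data_cols) - names)
    if unknown:
        raise SchemaError(f"columns not in schema: {unknown}")
    absent = sorted(names - set(data_cols))
    if absent:
        raise SchemaError(f"schema measures absent from file: {absent}")

    ordered = [m.name for m in schema]
    raw = df[ordered].to_numpy(dtype=object)
    mask = np.isin(raw, list(na_values))
    values = np.zeros(raw.shape, dtype=float)
    for (i, j), cell in np.ndenumerate(raw):
        if mask[i, j]:
            continue
        try:
            values[i, j] = float(cell)
        except ValueError as exc:
            raise CellParseError(
                f"cannot parse cell at row {i}, column {ordered[j]!r}: {cell!r}"
            ) from exc
    return CohortTable(
        child_ids=df[id_column].tolist(),
        measures=list(schema),
        values=values,
        missing_mask=mask,
    )


def write_cohort_csv(
    table: CohortTable, path, *, id_column: str = "child_id", na_rep: str = ""
) -> None:
    """Write a cohort table as CSV; missing cells become ``na_rep``.

    Values are printed with 17 significant digits so a write→read round-trip
    reproduces every double exactly.
    """
    df = table.to_frame()
    df.index.name = id_column
    df.to_csv(path, na_rep=na_rep, float_format="%.17g")


def descriptives(table: CohortTable) -> Descriptives:
    """Table-1-style descriptive statistics over observed cells only."""
    vals = np.where(table.missing_mask, np.nan, table.values)
    n_obs = (~table.missing_mask).sum(axis=0)
    for name, n in zip(table.measure_names, n_obs):
        if n < 2:
            raise ValueError(f"measure {name!r} has fewer than 2 observed values")
    with np.errstate(invalid="ignore"):
        return Descriptives(
            measure_names=table.measure_names,
            mean=np.nanmean(vals, axis=0),
            sd=np.nanstd(vals, axis=0, ddof=1),
            min=np.nanmin(vals, axis=0),
            max=np.nanmax(vals, axis=0),
        )


def combine_subscores(
    table: CohortTable,
    mapping: dict[str, list[str]],
    *,
    combined_defs: dict[str, MeasureDefinition] | None = None,
) -> CohortTable:
    """Collapse groups of subscore columns into single analysis measures.

    Each target column is the unweighted mean of its sources' z-scores,
    orientation-aligned first (a lower-is-better source is negated so that
    higher always means better on the combined scale). A combined cell is
    missing only when every source cell is missing. Columns not mentioned in
    any group pass through unchanged, in their original relative order;
    combined columns take the position of their first source.
    """
    name_to_idx = {m.name: i for i, m in enumerate(table.measures)}
    seen: set[str] = set()
    for target, sources in mapping.items():
        if not sources:
            raise ValueError(f"empty source group for target {target!r}")
        for s in sources:
            if s not in name_to_idx:
                raise ValueError(f"unknown source column {s!r} for target {target!r}")
            if s in seen:
                raise ValueError(f"source column {s!r} appears in multiple groups")
            seen.add(s)

    vals = np.where(table.missing_mask, np.nan, table.values)
    z = np.full_like(vals, np.nan)
    source_cols = [name_to_idx[s] for s in seen]
    for j in source_cols:
        col = vals[:, j]
        mu = np.nanmean(col)
        sd = np.nanstd(col, ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(
                f"source column {table.measures[j].name!r} is constant"
            )
        z[:, j] = (col - mu) / sd
        if not table.measures[j].higher_is_better:
            z[:, j] = -z[:, j]

    # build output column plan preserving source order
    plan: list[tuple[str, list[int]]] = []
    consumed_targets: set[str] = set()
    source_of = {s: t for t, ss in mapping.items() for s in ss}
    for m in table.measures:
        if m.name in source_of:
            t = source_of[m.name]
            if t in consumed_targets:
                continue
            consumed_targets.add(t)
            plan.append((t, [name_to_idx[s] for s in mapping[t]]))
        else:
            plan.append((m.name, [name_to_idx[m.name]]))

    out_vals = np.empty((table.n_children, len(plan)))
    out_mask = np.empty((table.n_children, len(plan)), dtype=bool)
    out_defs: list[MeasureDefinition] = []
    mapped_targets = set(mapping)
    for col, (target, idxs) in enumerate(plan):
        if target not in mapped_targets:
            out_vals[:, col] = table.values[:, idxs[0]]
            out_mask[:, col] = table.missing_mask[:, idxs[0]]
            out_defs.append(table.measures[idxs[0]])
            continue
        block = z[:, idxs]
        n_obs = (~np.isnan(block)).sum(axis=1)
        combined = np.nansum(block, axis=1) / np.maximum(n_obs, 1)
        all_missing = n_obs == 0
        out_vals[:, col] = np.where(all_missing, 0.0, combined)
        out_mask[:, col] = all_missing
        if combined_defs and target in combined_defs:
            out_defs.append(combined_defs[target])
        else:
            src = table.measures[idxs[0]]
            out_defs.append(
                replace(src, name=target, scale_min=-10.0, scale_max=10.0,
                        discrete=False, higher_is_better=True)
            )
    return CohortTable(
        child_ids=list(table.child_ids),
        measures=out_defs,
        values=out_vals,
        missing_mask=out_mask,
    )
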