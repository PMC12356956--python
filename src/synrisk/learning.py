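"""CPT estimation from categorical records given a fixed structure.

The estimator is maximum likelihood with optional Laplace smoothing:

    P(level | config) = (count + alpha) / (total + alpha * K)

with K the number of child levels.  Missing values are handled complete-case
per table: a record is excluded from one variable's count table when the
variable or any of its parents is missing in that record, and the exclusion
count is logged.  An unseen parent configuration with alpha = 0 yields a
uniform row and a warning rather than an error, so sparse categorical data
never blocks a fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .network import (
    ConditionalTable,
    DiscreteNetwork,
    NetworkError,
    NetworkStructure,
    parent_configurations,
)

logger = logging.getLogger(__name__)

#: sentinel for a missing cell (empty CSV cells map to this)
MISSING = ""


@dataclass
class RecordSet:
    """Rectangular categorical records: one row per observation."""

    columns: tuple[str, ...]
    rows: list[tuple[str, ...]]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.columns = tuple(self.columns)
        self.rows = [tuple(r) for r in self.rows]
        for r in self.rows:
            if len(r) != len(self.columns):
                raise NetworkError("record set is not rectangular")

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=list(self.columns), dtype=object)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "") -> "RecordSet":
        df = df.fillna(MISSING).astype(str)
        return cls(tuple(df.columns), [tuple(r) for r in df.itertuples(index=False)], provenance)


@dataclass
class CountTable:
    """Sufficient statistics: per parent configuration, counts per child level."""

    variable: str
    parents: tuple[str, ...]
    levels: tuple[str, ...]
    counts: dict[tuple[str, ...], dict[str, int]]
    excluded: int = 0

    def total(self, config: tuple[str, ...]) -> int:
        return sum(self.counts[config].values())


def read_records_csv(path: str, provenance: str | None = None) -> RecordSet:
    """Read records from CSV: header row of variable names, cells are levels."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return RecordSet.from_dataframe(df, provenance or str(path))


def write_records_csv(records: RecordSet, path: str) -> None:
    records.to_dataframe().to_csv(path, index=False)


def tabulate_counts(
    records: RecordSet, structure: NetworkStructure
) -> list[CountTable]:
    """Complete-case counts per (variable, parent configuration, level).

    Record columns must cover every network variable.  A cell holding a label
    that is not a legal level of its column is an error naming the row and
    column; an empty cell is missing data and triggers per-table exclusion.
    """
    missing_cols = [v.name for v in structure.variables if v.name not in records.columns]
    if missing_cols:
        raise NetworkError(f"records lack columns for variables {missing_cols}")
    col_idx = {c: i for i, c in enumerate(records.columns)}
    legal = {v.name: set(v.levels) for v in structure.variables}
    for r, row in enumerate(records.rows):
        for v in structure.variables:
            cell = row[col_idx[v.name]]
            if cell != MISSING and cell not in legal[v.name]:
                raise NetworkError(
                    f"illegal level {cell!r} in row {r}, column {v.name!r}"
                )

    tables: list[CountTable] = []
    for v in structure.variables:
        parents = structure.parents(v.name)
        counts = {
            cfg: dict.fromkeys(v.levels, 0)
            for cfg in parent_configurations(parents, structure)
        }
        excluded = 0
        needed = [col_idx[p] for p in parents] + [col_idx[v.name]]
        for row in records.rows:
            vals = [row[i] for i in needed]
            if MISSING in vals:
                excluded += 1
                continue
            counts[tuple(vals[:-1])][vals[-1]] += 1
        if excluded:
            logger.info(
                "tabulate_counts: excluded %d incomplete record(s) for %r",
                excluded,
                v.name,
            )
        tables.append(CountTable(v.name, parents, v.levels, counts, excluded))
    return tables


def fit_cpts(
    counts: list[CountTable], alpha: float = 0.0
) -> dict[str, ConditionalTable]:
    """Smoothed maximum-likelihood CPTs from count tables.

    alpha is the Laplace pseudo-count added to every (config, level) cell;
    alpha = 0 reproduces exact empirical frequencies on observed
    configurations.  A configuration with zero effective total yields a
    uniform row with a logged warning.
    """
    if alpha < 0:
        raise NetworkError(f"smoothing pseudo-count must be nonnegative, got {alpha}")
    fitted: dict[str, ConditionalTable] = {}
    for ct in counts:
        k = len(ct.levels)
        rows: dict[tuple[str, ...], dict[str, float]] = {}
        for cfg, dist in ct.counts.items():
            denom = ct.total(cfg) + alpha * k
            if denom == 0:
                logger.warning(
                    "fit_cpts: unseen parent configuration %s for %r; using uniform row",
                    dict(zip(ct.parents, cfg)),
                    ct.variable,
                )
                rows[cfg] = dict.fromkeys(ct.levels, 1.0 / k)
            else:
                rows[cfg] = {lv: (dist[lv] + alpha) / denom for lv in ct.levels}
        fitted[ct.variable] = ConditionalTable(ct.variable, ct.parents, rows)
    return fitted


def fit_network(
    records: RecordSet, structure: NetworkStructure, alpha: float = 0.0
) -> DiscreteNetwork:
    """Convenience: counts + fit in one step, returning a full network."""
    tables = fit_cpts(tabulate_counts(records, structure), alpha=alpha)
    return DiscreteNetwork(structure, tables)


def unseen_configurations(counts: list[CountTable]) -> list[tuple[str, tuple[str, ...]]]:
    """(variable, parent configuration) pairs with zero observations."""
    out = []
    for ct in counts:
        for cfg in ct.counts:
            if ct.total(cfg) == 0:
                out.append((ct.variable, cfg))
    return out
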