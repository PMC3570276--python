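"""Data model and I/O for subject-level clustered surveillance records.

A cohort is a flat delimited-text table, one row per woman, with one column
identifying the primary sampling unit (the hospital/center, called the
*cluster*) and one column per collected variable.  Analyses operate on
*dichotomized* variables: a declarative :class:`VariableSpec` maps each raw
value to success / failure / missing, optionally restricting the denominator
to a subpopulation (e.g. "among abortion cases").

Missingness is handled listwise **per variable**: a missing value removes the
record from that variable's denominator only.  Clusters left with zero valid
observations for a variable are dropped for that variable, and the effective
number of clusters ``a_eff`` is what downstream estimators use.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "ConfigError",
    "CohortError",
    "Rule",
    "VariableSpec",
    "SubjectRecord",
    "ClusterSummary",
    "CohortDesign",
    "Cohort",
    "VariableSummary",
    "read_cohort",
    "read_variable_config",
    "parse_rule",
    "summarize_variable",
    "write_summaries",
    "read_summaries",
]

BLOCKS = ("process", "outcome", "personal", "structure")


class ConfigError(ValueError):
    """Raised for fatal problems in the variable configuration."""


class CohortError(ValueError):
    """Raised for fatal problems in a cohort file."""


# ---------------------------------------------------------------------------
# dichotomization rules
# ---------------------------------------------------------------------------

_NUMERIC_OPS = {
    "lt": lambda x, v: x < v,
    "le": lambda x, v: x <= v,
    "gt": lambda x, v: x > v,
    "ge": lambda x, v: x >= v,
}


@dataclass(frozen=True)
class Rule:
    """Declarative success predicate applied to a raw (string) cell value.

    ``kind`` is one of ``equals``, ``in``, ``lt``, ``le``, ``gt``, ``ge``.
    String comparison is exact; numeric kinds parse the cell as a float and
    raise :class:`CohortError` on unparsable non-missing values rather than
    silently coercing.
    """

    kind: str
    value: object

    def __call__(self, raw: str) -> bool:
        if self.kind == "equals":
            return raw == str(self.value)
        if self.kind == "in":
            return raw in {str(v) for v in self.value}
        try:
            x = float(raw)
        except ValueError:
            raise CohortError(
                f"non-numeric value {raw!r} under numeric rule {self.kind} {self.value}"
            ) from None
        return _NUMERIC_OPS[self.kind](x, float(self.value))


def parse_rule(obj: object) -> Rule:
    """Build a :class:`Rule` from a config scalar or one-key mapping.

    A bare scalar is shorthand for ``{"equals": scalar}``.
    """
    if isinstance(obj, Mapping):
        items = [(k, v) for k, v in obj.items() if k != "column"]
        if len(items) != 1:
            raise ConfigError(f"rule must have exactly one operator, got {obj!r}")
        kind, value = items[0]
        if kind not in ("equals", "in") and kind not in _NUMERIC_OPS:
            raise ConfigError(f"unknown rule operator {kind!r}")
        return Rule(kind, value)
    if isinstance(obj, (str, int, float, bool)):
        return Rule("equals", obj)
    raise ConfigError(f"cannot interpret rule {obj!r}")


@dataclass(frozen=True)
class VariableSpec:
    """How one table row is computed: which column, which block of the
    report it belongs to, what counts as success, and (optionally) which
    subpopulation forms the denominator."""

    name: str
    block: str
    success: Rule
    column: str | None = None  # defaults to ``name``
    subpop_column: str | None = None
    subpop_rule: Rule | None = None

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise ConfigError(
                f"variable {self.name!r}: block must be one of {BLOCKS}, got {self.block!r}"
            )
        if (self.subpop_column is None) != (self.subpop_rule is None):
            raise ConfigError(
                f"variable {self.name!r}: subpopulation needs both a column and a rule"
            )

    @property
    def source_column(self) -> str:
        return self.column if self.column is not None else self.name


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectRecord:
    """One woman's registration: her center plus raw variable values
    (``None`` marks a missing cell)."""

    cluster_id: str
    values: Mapping[str, str | None]


@dataclass(frozen=True)
class ClusterSummary:
    """Per-cluster tallies for one dichotomized variable.

    ``x`` valid (non-missing, in-subpopulation) records, ``y`` successes.
    """

    cluster_id: str
    x: int
    y: int

    def __post_init__(self) -> None:
        if not (0 <= self.y <= self.x):
            raise ValueError(f"cluster {self.cluster_id}: need 0 <= y <= x, got x={self.x}, y={self.y}")

    @property
    def r(self) -> float:
        """Cluster-level proportion y/x (undefined when x = 0)."""
        if self.x == 0:
            raise ZeroDivisionError(f"cluster {self.cluster_id} has no valid observations")
        return self.y / self.x


@dataclass(frozen=True)
class CohortDesign:
    """The single-stage cluster design: fixed list of cluster sizes."""

    cluster_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.cluster_sizes or any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster_sizes must be non-empty with all sizes >= 1")

    @property
    def a(self) -> int:
        """Number of primary sampling units."""
        return len(self.cluster_sizes)

    @property
    def n(self) -> int:
        """Total number of subjects."""
        return int(sum(self.cluster_sizes))

    @property
    def b_bar(self) -> float:
        """Mean cluster size n / a."""
        return self.n / self.a


@dataclass
class Cohort:
    """In-memory cohort: a string-valued frame (missing cells as ``None``)
    plus the cluster column name and the derived design."""

    frame: pd.DataFrame
    cluster_column: str
    design: CohortDesign = field(init=False)

    def __post_init__(self) -> None:
        counts = self.frame[self.cluster_column].value_counts(sort=False)
        self.design = CohortDesign(tuple(int(c) for c in counts))

    @property
    def cluster_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame[self.cluster_column]))

    def records(self) -> Iterator[SubjectRecord]:
        cols = [c for c in self.frame.columns if c != self.cluster_column]
        for _, row in self.frame.iterrows():
            values = {c: (None if pd.isna(row[c]) else row[c]) for c in cols}
            yield SubjectRecord(cluster_id=row[self.cluster_column], values=values)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_cohort(
    path: str | os.PathLike | io.IOBase,
    cluster_column: str = "center",
    schema: Sequence[VariableSpec] | None = None,
    missing_marker: str = "",
    sep: str = ",",
) -> Cohort:
    """Read a delimited subject-level file into a :class:`Cohort`.

    All cells are read as strings; cells equal to ``missing_marker`` (and
    genuinely empty cells) become missing.  Rows without a cluster id are
    fatal and reported with their 1-based data row numbers.  When ``schema``
    is given, every referenced column must exist.
    """
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise CohortError(f"cohort file {path!r} is empty") from None
    if frame.empty:
        raise CohortError(f"cohort file {path!r} has a header but no rows")
    if cluster_column not in frame.columns:
        raise ConfigError(
            f"cluster column {cluster_column!r} not found; columns are {list(frame.columns)}"
        )
    frame = frame.replace(sorted({"", missing_marker}), None)
    bad = frame.index[frame[cluster_column].isna()]
    if len(bad):
        rows = ", ".join(str(i + 1) for i in bad[:20])
        raise CohortError(f"{len(bad)} row(s) lack a cluster id (data rows: {rows})")
    if schema is not None:
        for spec in schema:
            for col in filter(None, (spec.source_column, spec.subpop_column)):
                if col not in frame.columns:
                    raise ConfigError(
                        f"variable {spec.name!r} references column {col!r} absent from the cohort"
                    )
    return Cohort(frame=frame, cluster_column=cluster_column)


def read_variable_config(path: str | os.PathLike) -> tuple[str, list[VariableSpec]]:
    """Parse a YAML/JSON variable config.

    Layout::

        cluster_column: center
        variables:
          - name: maternal_death
            block: outcome
            success: {equals: "1"}
            subpopulation: {column: abortion, equals: "1"}   # optional
            column: death_flag                                # optional

    Returns ``(cluster_column, specs)``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping) or "variables" not in cfg:
        raise ConfigError(f"config {path!r} must be a mapping with a 'variables' list")
    cluster_column = str(cfg.get("cluster_column", "center"))
    specs: list[VariableSpec] = []
    for entry in cfg["variables"]:
        if not isinstance(entry, Mapping) or "name" not in entry:
            raise ConfigError(f"bad variable entry {entry!r}")
        sub = entry.get("subpopulation")
        sub_col = sub_rule = None
        if sub is not None:
            if not isinstance(sub, Mapping) or "column" not in sub:
                raise ConfigError(
                    f"variable {entry['name']!r}: subpopulation needs a 'column' key"
                )
            sub_col = str(sub["column"])
            sub_rule = parse_rule(sub)
        specs.append(
            VariableSpec(
                name=str(entry["name"]),
                block=str(entry.get("block", "outcome")),
                success=parse_rule(entry.get("success", "1")),
                column=entry.get("column"),
                subpop_column=sub_col,
                subpop_rule=sub_rule,
            )
        )
    if not specs:
        raise ConfigError(f"config {path!r} defines no variables")
    return cluster_column, specs


# ---------------------------------------------------------------------------
# per-variable summarization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSummary:
    """Cluster tallies for one variable, after missingness and subpopulation
    filtering.  ``valid_n`` = Σ x over contributing clusters, ``a_eff`` the
    number of contributing clusters; clusters with x = 0 are listed in
    ``excluded_clusters``."""

    spec: VariableSpec
    summaries: tuple[ClusterSummary, ...]
    excluded_clusters: tuple[str, ...]

    @property
    def valid_n(self) -> int:
        return sum(s.x for s in self.summaries)

    @property
    def a_eff(self) -> int:
        return len(self.summaries)

    def cluster_values(self) -> list[list[int]]:
        """Subject-level 0/1 values per contributing cluster (order within a
        cluster is immaterial to every downstream estimator)."""
        return [[1] * s.y + [0] * (s.x - s.y) for s in self.summaries]


def summarize_variable(cohort: Cohort, spec: VariableSpec) -> VariableSummary:
    """Tally one dichotomized variable per cluster.

    Applies, in order: the subpopulation restriction (records whose
    subpopulation cell is missing are outside the denominator), listwise
    missingness on the variable's own column, then the success rule.
    """
    frame = cohort.frame
    col = spec.source_column
    if col not in frame.columns:
        raise ConfigError(f"variable {spec.name!r} references column {col!r} absent from the cohort")
    mask = frame[col].notna()
    if spec.subpop_column is not None:
        sub = frame[spec.subpop_column]
        mask &= sub.notna() & sub.map(lambda v: bool(spec.subpop_rule(v)) if v is not None else False)
    if not mask.any():
        raise CohortError(f"variable {spec.name!r}: no valid observations")
    valid = frame.loc[mask, [cohort.cluster_column, col]]
    success = valid[col].map(lambda v: bool(spec.success(v)))
    grouped = success.groupby(valid[cohort.cluster_column], sort=False)
    tallies = {cid: (int(g.size), int(g.sum())) for cid, g in grouped}
    summaries, excluded = [], []
    for cid in cohort.cluster_ids:
        if cid in tallies:
            x, y = tallies[cid]
            summaries.append(ClusterSummary(cluster_id=cid, x=x, y=y))
        else:
            excluded.append(cid)
    return VariableSummary(
        spec=spec, summaries=tuple(summaries), excluded_clusters=tuple(excluded)
    )


def write_summaries(summaries: Iterable[ClusterSummary], path: str | os.PathLike) -> None:
    """Write cluster tallies as CSV with columns (cluster_id, x, y, r)."""
    rows = [
        {"cluster_id": s.cluster_id, "x": s.x, "y": s.y, "r": s.r if s.x else float("nan")}
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_summaries(path: str | os.PathLike) -> list[ClusterSummary]:
    frame = pd.read_csv(path, dtype={"cluster_id": str})
    return [
        ClusterSummary(cluster_id=row.cluster_id, x=int(row.x), y=int(row.y))
        for row in frame.itertuples()
    ]
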