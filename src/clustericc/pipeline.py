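"""End-to-end estimation pipeline and report summaries.

Runs the per-variable estimators over a cohort file, writes a results table
shaped like the surveillance study's published tables (prevalence %, ICC
with 95% CI, DEFF, mean cluster size), computes block-level summary
statistics (medians, ranges, proportions of low-ICC variables, the
process/outcome mean-ICC ratio, and the cluster-corrected sample size), and
can regression-check any results table against the packaged transcription
of the study's printed per-variable estimates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, read_cohort, read_variable_config
from .estimators import VariableResult, estimate_variable, recalc_sample_size

__all__ = [
    "BlockSummary",
    "SummaryReport",
    "Discrepancy",
    "PipelineResult",
    "load_reference_tables",
    "results_to_frame",
    "summarize_results",
    "check_against_fixture",
    "run_pipeline",
]

logger = logging.getLogger("clustericc")

#: value assigned to "<0.001" table entries for ordering/median computation
BELOW_PRINT_FLOOR = 0.0005

#: default per-field comparison tolerances: half a unit in the last printed
#: digit of each column of the published tables
DEFAULT_TOLERANCES: Mapping[str, float] = {
    "p": 0.05,
    "icc": 0.0005,
    "ci_low": 0.0005,
    "ci_high": 0.0005,
    "deff": 0.005,
    "n_a": 0.5,
}

ICC_THRESHOLDS = (0.05, 0.07, 0.1)

_COLUMN_ALIASES = {
    "p_percent": "p",
    "icc_ci_low": "ci_low",
    "icc_ci_high": "ci_high",
}


def _parse_printed(value: object) -> float:
    """Numeric value of a printed table cell; '<x' markers become x/2."""
    s = str(value).strip()
    if s.startswith("<"):
        return float(s[1:]) / 2.0
    return float(s)


def load_reference_tables() -> pd.DataFrame:
    """Packaged transcription of the study's printed per-variable tables.

    Columns: ``block`` (process/outcome/personal/structure), ``variable``,
    ``subitem`` (1 for indented sub-entries of a parent variable), printed
    strings ``p``/``icc``/``ci_low``/``ci_high`` plus ``deff`` and ``n_a``,
    and parsed numeric ``*_value`` columns where "<0.001" entries are valued
    at 0.0005 — below the printable floor, preserving order without
    inventing precision.
    """
    with resources.files("clustericc.data").joinpath("reference_tables.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t", dtype={"p": str, "icc": str, "ci_low": str, "ci_high": str})
    for col in ("p", "icc", "ci_low", "ci_high"):
        frame[f"{col}_value"] = frame[col].map(_parse_printed)
    return frame


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockSummary:
    n_variables: int
    icc_median: float
    icc_min: float
    icc_max: float
    icc_mean: float
    deff_median: float
    deff_min: float
    deff_max: float
    prop_icc_below: Mapping[float, float]


@dataclass(frozen=True)
class SummaryReport:
    """Results-section style summary of a per-variable results table."""

    overall: BlockSummary
    blocks: Mapping[str, BlockSummary]
    process_outcome_mean_icc_ratio: float | None
    n_star: int | None = None
    n_star_pct_of_total: float | None = None

    def to_dict(self) -> dict:
        def block(b: BlockSummary) -> dict:
            d = dataclasses.asdict(b)
            d["prop_icc_below"] = {str(k): v for k, v in b.prop_icc_below.items()}
            return d

        return {
            "overall": block(self.overall),
            "blocks": {name: block(b) for name, b in self.blocks.items()},
            "process_outcome_mean_icc_ratio": self.process_outcome_mean_icc_ratio,
            "n_star": self.n_star,
            "n_star_pct_of_total": self.n_star_pct_of_total,
        }


def _normalize(frame: pd.DataFrame) -> pd.DataFrame:
    """Accept either pipeline-output or fixture column naming; return a
    frame with numeric columns p/icc/ci_low/ci_high/deff/n_a."""
    out = frame.copy()
    out.columns = [_COLUMN_ALIASES.get(c.lower(), c.lower()) for c in out.columns]
    for col in ("p", "icc", "ci_low", "ci_high"):
        if f"{col}_value" in out.columns:
            out[col] = out[f"{col}_value"]
        elif col in out.columns and out[col].dtype == object:
            out[col] = out[col].map(_parse_printed)
    return out


def _block_summary(sub: pd.DataFrame) -> BlockSummary:
    icc = sub["icc"].astype(float)
    deff = sub["deff"].astype(float)
    return BlockSummary(
        n_variables=len(sub),
        icc_median=float(icc.median()),
        icc_min=float(icc.min()),
        icc_max=float(icc.max()),
        icc_mean=float(icc.mean()),
        deff_median=float(deff.median()),
        deff_min=float(deff.min()),
        deff_max=float(deff.max()),
        prop_icc_below={t: float((icc < t).mean()) for t in ICC_THRESHOLDS},
    )


def summarize_results(
    frame: pd.DataFrame,
    reference_variable: str | None = "Maternal Death + NM",
    a: int | None = 27,
    total_n: int | None = None,
) -> SummaryReport:
    """Compute per-block and overall medians/ranges, low-ICC proportions,
    the process/outcome mean-ICC ratio, and (when the reference outcome
    variable is present) the cluster-corrected required sample size.

    Medians use the standard midpoint rule for even counts.  ``total_n``
    (e.g. the 9,555 subjects of the surveillance cohort) turns the
    recalculated n* into a percentage of the realized sample.
    """
    if frame.empty:
        raise ValueError("summarize_results: empty results table")
    norm = _normalize(frame)
    required = {"block", "icc", "deff"}
    if not required.issubset(norm.columns):
        raise ValueError(f"summarize_results: table must have columns {sorted(required)}")
    blocks = {
        name: _block_summary(sub) for name, sub in norm.groupby("block", sort=False)
    }
    overall = _block_summary(norm)
    ratio = None
    if "process" in blocks and "outcome" in blocks and blocks["outcome"].icc_mean > 0:
        ratio = blocks["process"].icc_mean / blocks["outcome"].icc_mean

    n_star = pct = None
    if reference_variable is not None and a is not None and "variable" in norm.columns:
        ref = norm[norm["variable"] == reference_variable]
        if len(ref) == 1 and float(ref["icc"].iloc[0]) > 0:
            res = recalc_sample_size(
                a=a, icc=float(ref["icc"].iloc[0]), deff=float(ref["deff"].iloc[0])
            )
            n_star = res.n_star
            if total_n:
                pct = 100.0 * n_star / total_n
    return SummaryReport(
        overall=overall,
        blocks=blocks,
        process_outcome_mean_icc_ratio=ratio,
        n_star=n_star,
        n_star_pct_of_total=pct,
    )


# ---------------------------------------------------------------------------
# fixture regression check
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Discrepancy:
    variable: str
    column: str
    got: float
    expected: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.variable}[{self.column}]: got {self.got}, expected {self.expected}"


def check_against_fixture(
    results: pd.DataFrame,
    fixture: pd.DataFrame | None = None,
    tolerances: Mapping[str, float] | None = None,
) -> list[Discrepancy]:
    """Cell-by-cell regression check of a results table against a reference
    table (default: the packaged transcription of the printed tables).

    Matches rows on variable name; fields compared at per-field tolerances
    (default: half a unit in the last printed digit).  Report-only — returns
    the list of mismatches, never raises on disagreement.
    """
    if fixture is None:
        fixture = load_reference_tables()
    tol = dict(DEFAULT_TOLERANCES)
    if tolerances:
        tol.update(tolerances)
    got = _normalize(results).set_index("variable")
    want = _normalize(fixture).set_index("variable")
    out: list[Discrepancy] = []
    for name in want.index.intersection(got.index):
        for fld, t in tol.items():
            if fld not in got.columns or fld not in want.columns:
                continue
            g = float(np.asarray(got.loc[name, fld]).reshape(-1)[0])
            w = float(np.asarray(want.loc[name, fld]).reshape(-1)[0])
            if math.isnan(g) and math.isnan(w):
                continue
            if math.isnan(g) or math.isnan(w) or abs(g - w) > t:
                out.append(Discrepancy(variable=name, column=fld, got=g, expected=w))
    return out


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    results: list[VariableResult]
    frame: pd.DataFrame
    summary: SummaryReport
    skipped: list[tuple[str, str]] = field(default_factory=list)


def results_to_frame(results: Sequence[VariableResult]) -> pd.DataFrame:
    """Results table with one row per variable, mirroring the published
    table layout plus bookkeeping columns."""
    rows = []
    for res in results:
        rows.append(
            {
                "variable": res.name,
                "block": res.block,
                "P_percent": round(res.p_percent, 1),
                "ICC": round(res.icc.rho_reported, 3),
                "ICC_CI_low": round(res.icc.ci_low, 3),
                "ICC_CI_high": round(res.icc.ci_high, 3),
                "DEFF": round(res.deff.deff, 2) if not math.isnan(res.deff.deff) else float("nan"),
                "n_a": res.n_a,
                "a_eff": res.a_eff,
                "flags": ";".join(res.flags),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    cohort_path: str | os.PathLike,
    config_path: str | os.PathLike,
    out_dir: str | os.PathLike | None = None,
    alpha: float = 0.05,
    reference_variable: str | None = None,
) -> PipelineResult:
    """Estimate every configured variable on a cohort file.

    Per-variable degeneracies (no valid observations, a single contributing
    cluster) are logged and carried as flagged rows, never silently dropped;
    configuration errors (a variable naming an absent column) abort.  When
    ``out_dir`` is given, writes ``results.csv`` and ``summary.json``.
    """
    cluster_column, specs = read_variable_config(config_path)
    cohort = read_cohort(cohort_path, cluster_column=cluster_column, schema=specs)
    logger.info(
        "cohort: a=%d clusters, n=%d subjects, mean size %.1f",
        cohort.design.a, cohort.design.n, cohort.design.b_bar,
    )
    results: list[VariableResult] = []
    skipped: list[tuple[str, str]] = []
    for spec in specs:
        try:
            res = estimate_variable(cohort, spec, alpha=alpha)
        except ValueError as exc:
            logger.warning("variable %r skipped: %s", spec.name, exc)
            skipped.append((spec.name, str(exc)))
            continue
        for flag in res.flags:
            logger.warning("variable %r flagged: %s", spec.name, flag)
        results.append(res)
    frame = results_to_frame(results)
    for name, reason in skipped:
        spec = next(s for s in specs if s.name == name)
        frame = pd.concat(
            [frame, pd.DataFrame([{"variable": name, "block": spec.block, "flags": f"error:{reason}"}])],
            ignore_index=True,
        )
    estimated = frame[~frame["flags"].fillna("").str.startswith("error:")] if len(frame) else frame
    summary = summarize_results(
        estimated,
        reference_variable=reference_variable,
        a=cohort.design.a,
        total_n=cohort.design.n,
    )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        frame.to_csv(os.path.join(out_dir, "results.csv"), index=False)
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2)
    return PipelineResult(results=results, frame=frame, summary=summary, skipped=skipped)
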