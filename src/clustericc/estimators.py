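"""Estimators for single-stage cluster samples of binary outcomes.

The statistical core of the package:

* ``ratio_estimator`` — the pooled-proportion (ratio) prevalence estimator
  r = Σy_α / Σx_α over clusters α.
* ``anova_icc`` — the one-way ANOVA intraclass correlation on 0/1 subject
  values, in the F-statistic form ρ̂ = [(F−1)·a/n] / [1 + (F−1)·a/n],
  which for mean cluster size k = n/a is identical to the
  variance-components form (MSB − MSW) / (MSB + (k−1)·MSW).  The standard
  error uses Smith's asymptotic variance for unequal group sizes.
* ``design_effect`` — var(r) under the cluster design over var(r) under
  simple random sampling of the same size.
* ``recalc_sample_size`` — the cluster-corrected required sample size
  n* = (a/ICC)·(DEFF − 1 + ICC).
* ``estimate_variable`` — the per-variable composition of all of the above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort import Cohort, ClusterSummary, VariableSpec, summarize_variable

__all__ = [
    "IccEstimate",
    "DeffEstimate",
    "SampleSizeResult",
    "VariableResult",
    "ratio_estimator",
    "anova_icc",
    "design_effect",
    "recalc_sample_size",
    "estimate_variable",
]

# degenerate-case flags
FLAG_CONSTANT = "constant"            # all subject values identical
FLAG_MSW_ZERO = "degenerate_msw_zero"  # perfect within-cluster homogeneity
FLAG_DEFF_UNDEFINED = "deff_undefined_boundary_prevalence"


@dataclass(frozen=True)
class IccEstimate:
    """ANOVA intraclass correlation with its asymptotic 95% CI.

    ``rho`` is the raw estimate (may be negative); ``rho_reported`` is the
    value clamped to [0, 1] for display, matching the reporting convention
    of printing "<0.001" for estimates at or below zero.
    """

    rho: float
    se: float
    ci_low: float
    ci_high: float
    F: float
    msb: float
    msw: float
    a: int
    n: int
    k: float
    flags: tuple[str, ...] = ()

    @property
    def rho_reported(self) -> float:
        return min(max(self.rho, 0.0), 1.0)

    @property
    def display(self) -> str:
        """Three-decimal table entry, '<0.001' below the printable floor."""
        return "<0.001" if self.rho_reported < 0.001 else f"{self.rho_reported:.3f}"


@dataclass(frozen=True)
class DeffEstimate:
    """Design effect: actual-design variance of r over its SRS variance."""

    var_actual: float
    var_srs: float
    flags: tuple[str, ...] = ()

    @property
    def deff(self) -> float:
        if self.var_srs == 0:
            return float("nan")
        return self.var_actual / self.var_srs


@dataclass(frozen=True)
class SampleSizeResult:
    """Cluster-corrected required sample size."""

    n_star: int
    a: int
    icc_used: float
    deff_used: float


@dataclass(frozen=True)
class VariableResult:
    """One report row: prevalence (%), ICC with CI, DEFF and mean cluster
    size for a single dichotomized variable."""

    name: str
    block: str
    prevalence: float          # proportion in [0, 1]
    icc: IccEstimate
    deff: DeffEstimate
    valid_n: int
    a_eff: int
    flags: tuple[str, ...] = ()

    @property
    def p_percent(self) -> float:
        return 100.0 * self.prevalence

    @property
    def n_a(self) -> int:
        """Mean cluster size for this variable, to the nearest subject."""
        return round(self.valid_n / self.a_eff)


def ratio_estimator(summaries: Sequence[ClusterSummary]) -> float:
    """Pooled-proportion prevalence r = Σy_α / Σx_α.

    Equals the overall sample proportion among valid records; the clustering
    affects its variance (see :func:`design_effect`), not its value.
    """
    if not summaries:
        raise ValueError("ratio_estimator: no cluster summaries")
    x = sum(s.x for s in summaries)
    if x == 0:
        raise ValueError("ratio_estimator: zero valid observations")
    return sum(s.y for s in summaries) / x


def anova_icc(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> IccEstimate:
    """One-way ANOVA intraclass correlation on subject values grouped by cluster.

    Parameters
    ----------
    groups
        One sequence of (typically 0/1) subject values per cluster; every
        cluster must contribute at least one observation.
    alpha
        Two-sided CI level (default 0.05 → 95% CI).

    Notes
    -----
    The point estimate uses mean cluster size k = n/a, so the F-form and the
    mean-squares form coincide for any size pattern.  The standard error is
    Smith's large-sample variance of the ANOVA estimator for unequal group
    sizes, evaluated with k0 = (n − Σn_i²/n)/(a−1); the normal-approximation
    CI is clamped to [0, 1].
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    a = len(arrays)
    if a < 2:
        raise ValueError(f"anova_icc: need at least 2 clusters, got {a}")
    if any(arr.size == 0 for arr in arrays):
        raise ValueError("anova_icc: every cluster needs at least one observation")
    sizes = np.array([arr.size for arr in arrays], dtype=float)
    n = int(sizes.sum())
    if n <= a:
        raise ValueError(f"anova_icc: need n > a, got n={n}, a={a}")

    means = np.array([arr.mean() for arr in arrays])
    grand = sum(arr.sum() for arr in arrays) / n
    ssb = float(np.sum(sizes * (means - grand) ** 2))
    ssw = float(sum(((arr - m) ** 2).sum() for arr, m in zip(arrays, means)))
    msb = ssb / (a - 1)
    msw = ssw / (n - a)
    k = n / a

    if msb == 0.0 and msw == 0.0:
        # every subject identical: ICC carries no information
        return IccEstimate(
            rho=0.0, se=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            F=float("nan"), msb=msb, msw=msw, a=a, n=n, k=k, flags=(FLAG_CONSTANT,),
        )
    if msw == 0.0:
        # perfect within-cluster homogeneity: F diverges, ICC at the boundary
        return IccEstimate(
            rho=1.0, se=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            F=float("inf"), msb=msb, msw=msw, a=a, n=n, k=k, flags=(FLAG_MSW_ZERO,),
        )

    F = msb / msw
    theta = (F - 1.0) * a / n
    rho = theta / (1.0 + theta)

    se = _smith_se(rho, sizes)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    ci_low = min(max(rho - z * se, 0.0), 1.0)
    ci_high = min(max(rho + z * se, 0.0), 1.0)
    return IccEstimate(
        rho=rho, se=se, ci_low=ci_low, ci_high=ci_high,
        F=F, msb=msb, msw=msw, a=a, n=n, k=k,
    )


def _smith_se(rho: float, sizes: np.ndarray) -> float:
    """Smith's asymptotic SE of the ANOVA ICC with unequal group sizes."""
    a = sizes.size
    n = float(sizes.sum())
    s2 = float(np.sum(sizes**2))
    s3 = float(np.sum(sizes**3))
    k0 = (n - s2 / n) / (a - 1)
    term1 = (1.0 + (k0 - 1.0) * rho) ** 2 / (n - a)
    term2 = (
        (a - 1.0) * (1.0 - rho) * (1.0 + (2.0 * k0 - 1.0) * rho)
        + rho**2 * (s2 - 2.0 * s3 / n + (s2 / n) ** 2)
    ) / (a - 1.0) ** 2
    var = 2.0 * (1.0 - rho) ** 2 / k0**2 * (term1 + term2)
    return math.sqrt(max(var, 0.0))


def design_effect(summaries: Sequence[ClusterSummary]) -> DeffEstimate:
    """Design effect of the pooled prevalence under the cluster design.

    ``var_actual`` is the variance of the mean of the a unweighted cluster
    proportions, Σ_α (r_α − r)² / (a·(a−1)); ``var_srs`` is the binomial
    variance r(1−r)/(n−1) at the same total size n = Σx_α.  At boundary
    prevalence (r = 0 or 1) the SRS variance vanishes and the ratio is
    flagged undefined.
    """
    a = len(summaries)
    if a < 2:
        raise ValueError(f"design_effect: need at least 2 clusters, got {a}")
    r = ratio_estimator(summaries)
    ratios = np.array([s.r for s in summaries])
    var_actual = float(np.sum((ratios - r) ** 2)) / (a * (a - 1))
    n = sum(s.x for s in summaries)
    var_srs = r * (1.0 - r) / (n - 1)
    flags = (FLAG_DEFF_UNDEFINED,) if var_srs == 0.0 else ()
    return DeffEstimate(var_actual=var_actual, var_srs=var_srs, flags=flags)


def recalc_sample_size(a: int, icc: float, deff: float) -> SampleSizeResult:
    """Required sample size corrected for clustering:
    n* = ceil[(a/ICC)·(DEFF − 1 + ICC)].

    With DEFF = 1 the design carries no penalty and n* = a·(icc/icc) · 1
    reduces to a.  Rounding is upward to the next whole subject; a 1e-9
    guard absorbs float noise so exact-integer values are not inflated.
    """
    if icc <= 0:
        raise ValueError("recalc_sample_size: formula undefined for non-positive ICC")
    if deff <= 0:
        raise ValueError("recalc_sample_size: design effect must be positive")
    if a < 1:
        raise ValueError("recalc_sample_size: need at least one cluster")
    value = a * (deff - 1.0 + icc) / icc
    return SampleSizeResult(
        n_star=math.ceil(value - 1e-9), a=a, icc_used=icc, deff_used=deff
    )


def estimate_variable(
    cohort: Cohort, spec: VariableSpec, alpha: float = 0.05
) -> VariableResult:
    """Full per-variable estimation: cluster tallies → prevalence, ICC, DEFF.

    Composes :func:`clustericc.cohort.summarize_variable` with the three
    estimators; the effective cluster count a_eff (clusters with at least
    one valid record) is what enters the ANOVA and the design effect.
    """
    summary = summarize_variable(cohort, spec)
    if summary.a_eff < 2:
        raise ValueError(
            f"variable {spec.name!r}: need valid data in >= 2 clusters, got {summary.a_eff}"
        )
    r = ratio_estimator(summary.summaries)
    icc = anova_icc(summary.cluster_values(), alpha=alpha)
    deff = design_effect(summary.summaries)
    flags = tuple(dict.fromkeys(icc.flags + deff.flags))
    return VariableResult(
        name=spec.name,
        block=spec.block,
        prevalence=r,
        icc=icc,
        deff=deff,
        valid_n=summary.valid_n,
        a_eff=summary.a_eff,
        flags=flags,
    )
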