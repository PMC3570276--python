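"""Shared fixtures and independent from-the-definitions oracles.

The naive oracles below follow the estimator definitions with plain Python
loops and never touch the package's vectorized implementations, so the two
routes stay independent.
"""

from __future__ import annotations

import pandas as pd
import pytest

from clustericc.cohort import ClusterSummary, Cohort


def naive_anova_icc(groups):
    """F statistic and ICC straight from the one-way ANOVA definitions."""
    flat = [v for g in groups for v in g]
    a, n = len(groups), len(flat)
    grand = sum(flat) / n
    means = [sum(g) / len(g) for g in groups]
    ssb = sum(len(g) * (m - grand) ** 2 for g, m in zip(groups, means))
    ssw = sum((v - m) ** 2 for g, m in zip(groups, means) for v in g)
    msb = ssb / (a - 1)
    msw = ssw / (n - a)
    if msw == 0.0:
        return float("inf"), 1.0
    f = msb / msw
    theta = (f - 1.0) * a / n
    return f, theta / (1.0 + theta)


def naive_design_effect(pairs):
    """DEFF straight from the cluster-ratio definitions; pairs = [(x, y)]."""
    a = len(pairs)
    n = sum(x for x, _ in pairs)
    r = sum(y for _, y in pairs) / n
    var_actual = sum((y / x - r) ** 2 for x, y in pairs) / (a * (a - 1))
    var_srs = r * (1.0 - r) / (n - 1)
    return var_actual / var_srs


def make_cohort(cluster_values: dict[str, list[str | None]], variable: str = "v") -> Cohort:
    """Build an in-memory one-variable cohort from per-cluster value lists."""
    rows = [
        {"center": cid, variable: val}
        for cid, values in cluster_values.items()
        for val in values
    ]
    return Cohort(frame=pd.DataFrame(rows), cluster_column="center")


@pytest.fixture
def toy_groups():
    """Three clusters whose ANOVA works out to F = 7, ICC = 2/3, DEFF = 2.8."""
    return [[1, 1, 1], [1, 0, 0], [0, 0, 0]]


@pytest.fixture
def toy_summaries(toy_groups):
    return [
        ClusterSummary(cluster_id=str(i), x=len(g), y=sum(g))
        for i, g in enumerate(toy_groups)
    ]
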