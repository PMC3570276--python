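"""Beta-binomial simulation of clustered binary cohorts.

The generator emulates the single-stage cluster design of the Brazilian
27-center severe-maternal-morbidity surveillance network: cluster sizes are
fixed (a census within each selected center, nothing resampled), and each
cluster draws a latent success probability

    p_α ~ Beta(μ(1−ρ)/ρ, (1−μ)(1−ρ)/ρ)

so the marginal prevalence is exactly μ and the intraclass correlation of
the generated 0/1 values is exactly ρ — no latent-scale conversion is
needed, which makes parameter recovery a clean check of the estimators.
With ρ = 0 every cluster shares p = μ.  Cells are then masked missing
completely at random at ``missing_rate``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = [
    "STUDY_CLUSTER_SIZES",
    "SimulationScenario",
    "sample_cluster_values",
    "generate_cohort",
    "generate_multivariable_cohort",
    "write_cohort",
]

#: Per-center subject counts of the 27-hospital surveillance network
#: (southeast 13 centers, northeast 10, south 2, midwest 1, north 1);
#: totals 9,555 subjects, mean cluster size 353.9.
STUDY_CLUSTER_SIZES: tuple[int, ...] = (
    48, 59, 66, 74, 96, 112, 154, 155, 172, 186, 253, 369, 1050,   # southeast
    118, 210, 263, 281, 294, 465, 566, 920, 945, 1086,             # northeast
    98, 841,                                                       # south
    609,                                                           # midwest
    65,                                                            # north
)

DEFAULT_SEED = 20120921


@dataclass(frozen=True)
class SimulationScenario:
    """One variable's generating conditions on a fixed cluster frame."""

    mu: float
    rho: float = 0.0
    cluster_sizes: tuple[int, ...] = STUDY_CLUSTER_SIZES
    missing_rate: float = 0.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not self.cluster_sizes or any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster_sizes must be non-empty with all sizes >= 1")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")
        if self.rho > 0.0 and not 0.0 < self.mu < 1.0:
            raise ValueError("mu must lie strictly in (0, 1) when rho > 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError(f"missing_rate must lie in [0, 1), got {self.missing_rate}")


def sample_cluster_values(
    scenario: SimulationScenario, rng: np.random.Generator | None = None
) -> list[np.ndarray]:
    """Draw subject-level values per cluster.

    Returns one float array per cluster with entries 0.0 / 1.0 and NaN for
    cells masked missing.  Deterministic given the scenario seed (or a
    caller-supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    a = len(scenario.cluster_sizes)
    if scenario.rho > 0.0:
        conc = (1.0 - scenario.rho) / scenario.rho
        p = rng.beta(scenario.mu * conc, (1.0 - scenario.mu) * conc, size=a)
    else:
        p = np.full(a, scenario.mu)
    out: list[np.ndarray] = []
    for p_alpha, size in zip(p, scenario.cluster_sizes):
        values = rng.binomial(1, p_alpha, size=size).astype(float)
        if scenario.missing_rate > 0.0:
            values[rng.random(size) < scenario.missing_rate] = np.nan
        out.append(values)
    return out


def _cluster_ids(n_clusters: int) -> list[str]:
    width = len(str(n_clusters))
    return [f"C{i + 1:0{width}d}" for i in range(n_clusters)]


def _values_to_column(values: list[np.ndarray]) -> list[str | None]:
    col: list[str | None] = []
    for arr in values:
        col.extend(None if np.isnan(v) else str(int(v)) for v in arr)
    return col


def generate_cohort(
    scenario: SimulationScenario,
    variable: str = "outcome",
    cluster_column: str = "center",
) -> Cohort:
    """Generate a one-variable cohort on the scenario's cluster frame.

    Values are the strings "0"/"1" with missing cells as ``None`` — the
    same convention :func:`clustericc.cohort.read_cohort` produces.
    """
    values = sample_cluster_values(scenario)
    ids = _cluster_ids(len(scenario.cluster_sizes))
    frame = pd.DataFrame(
        {
            cluster_column: np.repeat(ids, scenario.cluster_sizes),
            variable: _values_to_column(values),
        }
    )
    return Cohort(frame=frame, cluster_column=cluster_column)


def generate_multivariable_cohort(
    scenarios: Mapping[str, SimulationScenario],
    cluster_column: str = "center",
) -> Cohort:
    """Generate several independent variables on one shared cluster frame.

    Every scenario must declare identical ``cluster_sizes``; each variable
    is drawn from its own scenario (and seed), so columns are mutually
    independent given the frame.
    """
    if not scenarios:
        raise ValueError("generate_multivariable_cohort: no scenarios given")
    frames = {name: sc.cluster_sizes for name, sc in scenarios.items()}
    first = next(iter(frames.values()))
    for name, sizes in frames.items():
        if sizes != first:
            raise ValueError(
                f"scenario {name!r} has cluster_sizes differing from the shared frame"
            )
    ids = _cluster_ids(len(first))
    data: dict[str, object] = {cluster_column: np.repeat(ids, first)}
    for name, sc in scenarios.items():
        data[name] = _values_to_column(sample_cluster_values(sc))
    return Cohort(frame=pd.DataFrame(data), cluster_column=cluster_column)


def write_cohort(cohort: Cohort, path: str | os.PathLike) -> None:
    """Write a cohort as the CSV format ``read_cohort`` ingests (missing
    cells as empty strings).  Same seed → byte-identical file."""
    cohort.frame.to_csv(path, index=False, na_rep="")
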