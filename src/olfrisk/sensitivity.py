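"""Replicate-run robustness check for the Monte Carlo risk simulation.

The question answered here: is the configured iteration count large
enough that the risk distribution does not depend on the particular
random run?  The check repeats the simulation with independent child
seeds and quantifies pairwise agreement of the empirical CDFs with the
two-sample Kolmogorov–Smirnov sup distance.  At 1000 iterations the KS
null keeps the largest pairwise distance of five replicates comfortably
below 0.10, so the default stability tolerance is 0.05 per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ks_2samp

from .distributions import derive_seed
from .risk import (
    CategoryRiskInputs,
    ExposureModel,
    IRNotComputable,
    RiskDistribution,
    simulate_hi,
    simulate_ir,
)

__all__ = ["SensitivityReport", "cdf_sup_distance", "run_replicates"]

DEFAULT_REPLICATES = 5
DEFAULT_TOLERANCE = 0.05


def cdf_sup_distance(draws_a, draws_b) -> float:
    """Two-sample Kolmogorov–Smirnov sup-norm distance in [0, 1]."""
    a = np.asarray(draws_a, dtype=float)
    b = np.asarray(draws_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both draw sets must be non-empty")
    return float(ks_2samp(a, b).statistic)


@dataclass
class SensitivityReport:
    """Pairwise CDF distances among replicate runs and the stability verdict."""

    metric: str
    category: str
    replicate_count: int
    pairwise_sup_distances: np.ndarray  # symmetric, zero diagonal
    max_distance: float
    stable: bool
    tolerance: float
    replicates: list[RiskDistribution] = field(default_factory=list)


def run_replicates(
    inputs: CategoryRiskInputs,
    exposure: ExposureModel | None = None,
    iterations: int = 1000,
    replicate_count: int = DEFAULT_REPLICATES,
    master_seed: int = 0,
    metric: str = "HI",
    tolerance: float = DEFAULT_TOLERANCE,
    **simulate_kwargs,
) -> SensitivityReport:
    """Repeat the simulation with derived child seeds and compare CDFs.

    ``metric`` selects HI or IR; IR requires ``exposure`` and a category
    with at least one carcinogen (otherwise the run is meaningless and a
    ValueError carries the not-computable reason).
    """
    if replicate_count < 2:
        raise ValueError("replicate_count must be >= 2")
    replicates: list[RiskDistribution] = []
    for i in range(replicate_count):
        rep_seed = derive_seed(master_seed, "replicate", metric, i)
        if metric == "HI":
            dist = simulate_hi(inputs, iterations, rep_seed, **simulate_kwargs)
        elif metric == "IR":
            if exposure is None:
                raise ValueError("IR sensitivity requires an ExposureModel")
            dist = simulate_ir(inputs, exposure, iterations, rep_seed, **simulate_kwargs)
            if isinstance(dist, IRNotComputable):
                raise ValueError(
                    f"cannot run IR sensitivity for {inputs.category!r}: {dist.reason}"
                )
        else:
            raise ValueError(f"unknown metric: {metric!r}")
        replicates.append(dist)

    n = replicate_count
    distances = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = cdf_sup_distance(replicates[i].draws, replicates[j].draws)
            distances[i, j] = distances[j, i] = d
    max_distance = float(distances.max())
    return SensitivityReport(
        metric=metric,
        category=inputs.category,
        replicate_count=replicate_count,
        pairwise_sup_distances=distances,
        max_distance=max_distance,
        stable=max_distance <= tolerance,
        tolerance=tolerance,
        replicates=replicates,
    )
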