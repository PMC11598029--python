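"""Olfactometric arithmetic.

Dynamic olfactometry (EN 13725 style) presents an odorous sample to a
panel of assessors at decreasing dilutions; each assessor's individual
threshold estimate Z_ITE is the dilution factor at first perception.
The odor concentration C_od (ou_E/m³) is the geometric mean of at least
12 Z_ITE values times the square root of the olfactometer dilution step
(2 by default).  Retrospective screening bounds each assessor's ratio
ΔZ = Z_ITE / Z̄_ITE within ±ΔZ_max (default 5).

Because C_od is a panel average, an individual panelist may sit up to
ΔZ_max dilution steps below the mean threshold, and the confirmation
presentation doubles the perceived concentration — hence the safety
multiplication factor k = ΔZ_max × 2 = 10 applied to the inhalation
concentration Cin_i = (C_i / C_od) × k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MIN_ASSESSORS",
    "MIN_ROUNDS",
    "CONFIRMATION_FACTOR",
    "minimum_threshold_count",
    "ThresholdMatrix",
    "ScreeningResult",
    "compute_odor_concentration",
    "screen_panel",
    "compute_safety_factor",
    "compute_inhalation_concentration",
]

#: minimum panel configuration: 4 assessors x 3 rounds
MIN_ASSESSORS = 4
MIN_ROUNDS = 3

#: the confirmation presentation is at twice the perception concentration
CONFIRMATION_FACTOR = 2.0


def minimum_threshold_count(n_assessors: int = MIN_ASSESSORS, n_rounds: int = MIN_ROUNDS) -> int:
    """Number of Z_ITE values the minimum panel configuration yields (12)."""
    return int(n_assessors) * int(n_rounds)


@dataclass
class ThresholdMatrix:
    """Grid of individual threshold estimates Z_ITE, assessor x round."""

    entries: np.ndarray
    dilution_step_factor: float = 2.0

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.ndim != 2:
            raise ValueError("threshold matrix must be 2-D (assessor x round)")
        if self.entries.shape[0] < 1 or self.entries.shape[1] < 1:
            raise ValueError("threshold matrix needs >= 1 assessor and >= 1 round")
        if not np.all(self.entries > 0):
            raise ValueError("every Z_ITE must be > 0 (dilution factors)")
        if self.dilution_step_factor <= 0:
            raise ValueError("dilution_step_factor must be > 0")

    @property
    def n_entries(self) -> int:
        return self.entries.size

    def geometric_mean(self) -> float:
        """Z̄_ITE — geometric mean over all entries."""
        return float(np.exp(np.mean(np.log(self.entries))))


@dataclass
class ScreeningResult:
    """Per-entry ΔZ ratios and pass flags from retrospective screening."""

    delta_z: np.ndarray
    passed: np.ndarray
    overall_pass: bool
    geometric_mean: float
    delta_z_max: float


def compute_odor_concentration(matrix: ThresholdMatrix) -> float:
    """Odor concentration C_od (ou_E/m³) from a threshold matrix.

    C_od = geometric_mean(Z_ITE) × sqrt(dilution_step_factor), requiring
    at least 12 threshold values (the minimum 4-assessor, 3-round panel).
    """
    required = minimum_threshold_count()
    if matrix.n_entries < required:
        raise ValueError(
            f"odor concentration requires >= {required} Z_ITE values "
            f"({MIN_ASSESSORS} assessors x {MIN_ROUNDS} rounds minimum); "
            f"got {matrix.n_entries}"
        )
    return matrix.geometric_mean() * float(np.sqrt(matrix.dilution_step_factor))


def screen_panel(matrix: ThresholdMatrix, delta_z_max: float = 5.0) -> ScreeningResult:
    """Retrospective screening: ΔZ = Z_ITE / Z̄_ITE bounded in ±delta_z_max.

    The bound is closed (an entry at exactly ±delta_z_max passes).  Since
    thresholds are positive the lower bound is vacuous for a plain ratio;
    it is kept to mirror the printed two-sided criterion.
    """
    if delta_z_max <= 0:
        raise ValueError("delta_z_max must be > 0")
    gmean = matrix.geometric_mean()
    delta_z = matrix.entries / gmean
    passed = (delta_z >= -delta_z_max) & (delta_z <= delta_z_max)
    return ScreeningResult(
        delta_z=delta_z,
        passed=passed,
        overall_pass=bool(np.all(passed)),
        geometric_mean=gmean,
        delta_z_max=float(delta_z_max),
    )


def compute_safety_factor(
    delta_z_max: float = 5.0, confirmation_factor: float = CONFIRMATION_FACTOR
) -> float:
    """Safety multiplication factor k = ΔZ_max × confirmation factor.

    With the standard screening bound (5) and the confirmation doubling
    (2) this yields the conservative default k = 10.
    """
    if delta_z_max <= 0 or confirmation_factor <= 0:
        raise ValueError("delta_z_max and confirmation_factor must be > 0")
    return float(delta_z_max) * float(confirmation_factor)


def compute_inhalation_concentration(c_i, c_od: float, k: float):
    """Inhalation (exposure) concentration Cin_i = (C_i / C_od) × k, µg/m³.

    Accepts a scalar or array ``c_i`` (µg/m³).  ``c_od`` is the sample's
    odor concentration (ou_E/m³) and ``k`` the safety factor.
    """
    c_i = np.asarray(c_i, dtype=float)
    if np.any(c_i < 0):
        raise ValueError("chemical concentration c_i must be >= 0")
    if c_od <= 0:
        raise ValueError(
            "sample without a positive odor concentration cannot be risk-assessed"
        )
    if k <= 0:
        raise ValueError("safety factor k must be > 0")
    out = (c_i / float(c_od)) * float(k)
    return float(out) if out.ndim == 0 else out
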