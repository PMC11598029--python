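"""Deterministic and Monte Carlo risk characterization.

Non-carcinogenic risk is the hazard index

    HI = Σ_i HQ_i = Σ_i Cin_i / OEL_i

summed over detected compounds with an occupational exposure limit; the
exposure parameters play no role (HI compares a momentary inhaled
concentration with a limit concentration).  Carcinogenic risk is the
inhalation risk

    IR = Σ_i Cin_i · IUR_i · (N_Y · F_S · N_PR · N_R · IT) / (AT · LT)

where the bracketed ratio is the dimensionless lifetime exposure
fraction: total hours of exposure over a 70-year lifetime, with IT in
seconds converted through 86 400 s/day against AT·LT in days.

The Monte Carlo layer draws every randomized input (per-compound Cin_i;
N_PR, F_S, N_Y for IR) from its truncated-Gaussian spec independently
within each iteration, sums within the iteration, and summarizes the
resulting distribution.  Acceptability is judged at a configurable
percentile (default the 95th) against HI < 1 and IR < 1e-5, with strict
inequality: a 95th percentile exactly at the threshold is unacceptable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import LabConstants, ToxTable
from .distributions import TruncatedGaussianSpec, child_rng, sample, sample_integer

__all__ = [
    "SECONDS_PER_DAY",
    "HI_THRESHOLD",
    "IR_THRESHOLD",
    "ExposureModel",
    "CategoryRiskInputs",
    "RiskSummary",
    "RiskDistribution",
    "IRNotComputable",
    "hazard_quotient",
    "hazard_index",
    "lifetime_exposure_fraction",
    "inhalation_risk",
    "simulate_hi",
    "simulate_ir",
    "summarize",
    "empirical_cdf",
    "pdf_histogram",
]

SECONDS_PER_DAY = 86400.0

#: deterministic acceptability thresholds
HI_THRESHOLD = 1.0
IR_THRESHOLD = 1e-5

DEFAULT_ITERATIONS = 1000
DEFAULT_PERCENTILE = 95.0


@dataclass
class ExposureModel:
    """Laboratory constants plus the randomized exposure parameters.

    N_R and IT are fixed by the olfactometer set-up; N_PR (presentations
    per sample), F_S (samples analyzed per year) and N_Y (working years)
    carry panel variability and are randomized.
    """

    constants: LabConstants
    spec_n_pr: TruncatedGaussianSpec
    spec_f_s: TruncatedGaussianSpec
    spec_n_y: TruncatedGaussianSpec

    def __post_init__(self) -> None:
        for name in ("spec_n_pr", "spec_f_s", "spec_n_y"):
            if getattr(self, name).lower <= 0:
                raise ValueError(f"{name}: exposure parameters must have lower > 0")


@dataclass
class CategoryRiskInputs:
    """Per-category randomization inputs: Cin specs and the tox lookup."""

    category: str
    cin_specs: dict[str, TruncatedGaussianSpec]
    tox: ToxTable


@dataclass
class RiskSummary:
    """Distribution summary in the reporting layout: mean, sd, quartiles, p95, max."""

    mean: float
    sd: float
    p25: float
    p50: float
    p75: float
    p95: float
    max: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "p25": self.p25,
            "p50": self.p50,
            "p75": self.p75,
            "p95": self.p95,
            "max": self.max,
        }


@dataclass
class RiskDistribution:
    """Monte Carlo draws of HI or IR with summary and acceptability verdict."""

    metric: str  # "HI" or "IR"
    category: str
    draws: np.ndarray
    summary: RiskSummary
    verdict: bool  # True = acceptable
    threshold: float
    percentile_used: float = DEFAULT_PERCENTILE
    quantile_method: str = "linear"
    seed: int | None = None

    @property
    def iterations(self) -> int:
        return int(self.draws.size)


@dataclass
class IRNotComputable:
    """Explicit marker for categories without carcinogenic compounds."""

    category: str
    reason: str = "no carcinogenic compounds (no IUR) among detected species"


# ---------------------------------------------------------------------------
# deterministic building blocks


def hazard_quotient(cin: float, oel: float) -> float:
    """HQ = Cin / OEL, both in µg/m³."""
    if oel <= 0:
        raise ValueError("OEL must be > 0")
    if cin < 0:
        raise ValueError("Cin must be >= 0")
    return cin / oel


def hazard_index(hqs) -> float:
    """HI = Σ HQ (compensated summation; empty mixture -> 0)."""
    hqs = list(hqs)
    if any(h < 0 for h in hqs):
        raise ValueError("hazard quotients must be >= 0")
    return math.fsum(hqs)


def lifetime_exposure_fraction(n_y, f_s, n_pr, n_r, it_s, at=365.0, lt=70.0):
    """Dimensionless fraction of lifetime spent inhaling sample air.

    (N_Y · F_S · N_PR · N_R · (IT/86400 s/day)) / (AT · LT), with AT in
    days/year and LT in years.  Accepts scalars or arrays for the
    randomized arguments.
    """
    arrs = [np.asarray(x, dtype=float) for x in (n_y, f_s, n_pr)]
    for name, value in zip(("n_r", "it_s", "at", "lt"), (n_r, it_s, at, lt)):
        if value <= 0:
            raise ValueError(f"{name} must be > 0")
    if any(np.any(a <= 0) for a in arrs):
        raise ValueError("n_y, f_s and n_pr must be > 0")
    n_y, f_s, n_pr = arrs
    out = (n_y * f_s * n_pr * n_r * (it_s / SECONDS_PER_DAY)) / (at * lt)
    return float(out) if out.ndim == 0 else out


def inhalation_risk(cin, iur, fraction):
    """IR_i = Cin_i × fraction × IUR (CDI = Cin × fraction)."""
    cin = np.asarray(cin, dtype=float)
    if np.any(cin < 0) or iur < 0 or np.any(np.asarray(fraction) < 0):
        raise ValueError("cin, iur and fraction must be >= 0")
    out = cin * np.asarray(fraction, dtype=float) * iur
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# summaries


def summarize(
    draws,
    percentile_used: float = DEFAULT_PERCENTILE,
    threshold: float = HI_THRESHOLD,
) -> tuple[RiskSummary, bool]:
    """Empirical summary (linear-interpolated quantiles) and verdict.

    The verdict is acceptability: quantile(draws, percentile) strictly
    below the threshold.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("cannot summarize an empty draw set")
    p25, p50, p75, p95 = np.percentile(draws, [25, 50, 75, 95], method="linear")
    summary = RiskSummary(
        mean=float(np.mean(draws)),
        sd=float(np.std(draws, ddof=1)) if draws.size > 1 else 0.0,
        p25=float(p25),
        p50=float(p50),
        p75=float(p75),
        p95=float(p95),
        max=float(np.max(draws)),
    )
    q = float(np.percentile(draws, percentile_used, method="linear"))
    return summary, bool(q < threshold)


def empirical_cdf(draws) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF: sorted values and cumulative probabilities i/n."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("cannot build a CDF from zero draws")
    values = np.sort(draws)
    probs = np.arange(1, values.size + 1, dtype=float) / values.size
    return values, probs


def pdf_histogram(draws, bins: int = 30) -> tuple[np.ndarray, np.ndarray]:
    """Density histogram (bin centers, densities integrating to 1)."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("cannot build a histogram from zero draws")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    densities, edges = np.histogram(draws, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, densities


# ---------------------------------------------------------------------------
# Monte Carlo simulation


def _active_oel_compounds(inputs: CategoryRiskInputs) -> tuple[list[str], list[str]]:
    active, excluded = [], []
    for cid in sorted(inputs.cin_specs):
        profile = inputs.tox.get(cid)
        if profile is not None and profile.has_oel:
            active.append(cid)
        else:
            excluded.append(cid)
    return active, excluded


def simulate_hi(
    inputs: CategoryRiskInputs,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    threshold: float = HI_THRESHOLD,
    percentile_used: float = DEFAULT_PERCENTILE,
) -> RiskDistribution:
    """Monte Carlo hazard-index distribution for one category.

    Per iteration each compound's Cin is drawn independently from its
    truncated-Gaussian spec and the hazard quotients are summed; the
    exposure parameters are deliberately not sampled (HI is
    concentration-only).  Compounds without an active OEL are skipped;
    if none remains the category cannot be assessed.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    active, excluded = _active_oel_compounds(inputs)
    if not active:
        raise ValueError(
            f"category {inputs.category!r}: no compound with an OEL; "
            f"excluded: {excluded}"
        )
    hi = np.zeros(iterations)
    for cid in active:
        rng = child_rng(seed, "hi", inputs.category, cid)
        cin = sample(inputs.cin_specs[cid], iterations, rng)
        hi += cin / inputs.tox[cid].oel_value
    summary, verdict = summarize(hi, percentile_used, threshold)
    return RiskDistribution(
        metric="HI",
        category=inputs.category,
        draws=hi,
        summary=summary,
        verdict=verdict,
        threshold=threshold,
        percentile_used=percentile_used,
        seed=seed,
    )


def simulate_ir(
    inputs: CategoryRiskInputs,
    exposure: ExposureModel,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    threshold: float = IR_THRESHOLD,
    percentile_used: float = DEFAULT_PERCENTILE,
    integer_n_pr: bool = True,
) -> RiskDistribution | IRNotComputable:
    """Monte Carlo inhalation-risk distribution for one category.

    Per iteration: one Cin draw per carcinogenic compound, one N_PR, one
    F_S, one N_Y; the per-compound products Cin_i·IUR_i are summed and
    multiplied by the lifetime exposure fraction.  Categories with no
    IUR-bearing compound return :class:`IRNotComputable` rather than a
    distribution.  ``integer_n_pr`` rounds presentation counts to whole
    numbers (the default; set False to keep the continuous draws).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    carcinogens = [
        cid
        for cid in sorted(inputs.cin_specs)
        if (p := inputs.tox.get(cid)) is not None and p.is_carcinogen
    ]
    if not carcinogens:
        return IRNotComputable(category=inputs.category)

    c = exposure.constants
    draw_n_pr = sample_integer if integer_n_pr else sample
    n_pr = draw_n_pr(exposure.spec_n_pr, iterations, child_rng(seed, "ir", "n_pr"))
    f_s = sample(exposure.spec_f_s, iterations, child_rng(seed, "ir", "f_s"))
    n_y = sample(exposure.spec_n_y, iterations, child_rng(seed, "ir", "n_y"))
    fraction = lifetime_exposure_fraction(
        n_y,
        f_s,
        n_pr,
        c.rounds_per_sample,
        c.inhalation_time_s,
        c.averaging_time_days_per_year,
        c.lifetime_years,
    )

    weighted = np.zeros(iterations)  # Σ_i Cin_i · IUR_i
    for cid in carcinogens:
        rng = child_rng(seed, "ir", inputs.category, cid)
        cin = sample(inputs.cin_specs[cid], iterations, rng)
        weighted += cin * inputs.tox[cid].iur
    ir = weighted * fraction
    summary, verdict = summarize(ir, percentile_used, threshold)
    return RiskDistribution(
        metric="IR",
        category=inputs.category,
        draws=ir,
        summary=summary,
        verdict=verdict,
        threshold=threshold,
        percentile_used=percentile_used,
        seed=seed,
    )
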