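"""Fit-and-simulate orchestration: from raw tables to risk distributions.

The fitting stage turns the raw survey into the Monte Carlo inputs:

* per (category, compound): Cin_i = (C_i / C_od) · k is computed for
  every detection and a truncated-Gaussian spec is fitted on the
  detected values only (absence of a compound in a characterized sample
  is absence, not a zero);
* globally: one spec each for N_PR (pooled presentation counts), F_S
  and N_Y from the panelist survey — the laboratory-wide exposure
  parameters are applied to every category.

Compounds without a usable toxicology entry are excluded from the risk
metrics but tracked in an exclusion report, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .core import LabConstants, PanelistRecord, SampleRecord, ToxTable
from .distributions import TruncatedGaussianSpec, fit_spec
from .olfactometry import compute_inhalation_concentration
from .risk import (
    CategoryRiskInputs,
    ExposureModel,
    IRNotComputable,
    RiskDistribution,
    simulate_hi,
    simulate_ir,
)

__all__ = [
    "Exclusion",
    "FittedInputs",
    "compute_cin_table",
    "fit_category_inputs",
    "fit_exposure_model",
    "fit_all",
    "run_assessment",
    "AssessmentResult",
]

log = logging.getLogger(__name__)


@dataclass
class Exclusion:
    """A compound left out of the risk metrics, with the reason why."""

    category: str
    compound_id: str
    reason: str
    n_detections: int


@dataclass
class FittedInputs:
    """Everything the Monte Carlo engine needs, plus fit diagnostics."""

    categories: dict[str, CategoryRiskInputs]
    exposure: ExposureModel
    exclusions: list[Exclusion]
    detection_counts: dict[tuple[str, str], int]


def compute_cin_table(samples: list[SampleRecord], k: float) -> pd.DataFrame:
    """Per-detection inhalation concentrations, long format.

    Columns: category, sample_id, compound_id, cin (µg/m³).
    """
    rows = [
        {
            "category": s.category,
            "sample_id": s.sample_id,
            "compound_id": m.compound_id,
            "cin": compute_inhalation_concentration(
                m.concentration, s.odor_concentration, k
            ),
        }
        for s in samples
        for m in s.measurements
    ]
    return pd.DataFrame(rows, columns=["category", "sample_id", "compound_id", "cin"])


def fit_category_inputs(
    samples: list[SampleRecord],
    tox: ToxTable,
    constants: LabConstants,
) -> tuple[dict[str, CategoryRiskInputs], list[Exclusion], dict[tuple[str, str], int]]:
    """Fit one Cin spec per (category, compound) on detected values.

    Compounds missing from the tox table — or present but carrying
    neither OEL nor IUR — are excluded and reported.
    """
    cin = compute_cin_table(samples, constants.safety_factor_k)
    categories: dict[str, CategoryRiskInputs] = {}
    exclusions: list[Exclusion] = []
    detections: dict[tuple[str, str], int] = {}

    sample_counts = {}
    for s in samples:
        sample_counts[s.category] = sample_counts.get(s.category, 0) + s.is_characterized

    for category, group in cin.groupby("category", sort=True):
        specs: dict[str, TruncatedGaussianSpec] = {}
        for compound_id, values in group.groupby("compound_id")["cin"]:
            n_det = len(values)
            detections[(category, compound_id)] = n_det
            profile = tox.get(compound_id)
            if profile is None:
                exclusions.append(
                    Exclusion(category, compound_id, "not in tox table", n_det)
                )
                log.warning(
                    "%s/%s: not in tox table; excluded (%d detections)",
                    category,
                    compound_id,
                    n_det,
                )
                continue
            if not profile.usable:
                exclusions.append(
                    Exclusion(category, compound_id, "no OEL and no IUR", n_det)
                )
                log.warning(
                    "%s/%s: no OEL and no IUR; excluded (%d detections)",
                    category,
                    compound_id,
                    n_det,
                )
                continue
            specs[compound_id] = fit_spec(values.to_numpy())
            log.info(
                "%s/%s: fitted Cin spec on %d of %d characterized samples",
                category,
                compound_id,
                n_det,
                sample_counts.get(category, 0),
            )
        if specs:
            categories[category] = CategoryRiskInputs(
                category=category, cin_specs=specs, tox=tox
            )
        else:
            log.warning("category %s: no usable compound; skipped", category)
    return categories, exclusions, detections


def fit_exposure_model(
    survey: list[PanelistRecord], constants: LabConstants
) -> ExposureModel:
    """Global exposure-parameter specs from the panelist survey."""
    if not survey:
        raise ValueError("survey must contain at least one panelist")
    n_y = [p.working_years for p in survey]
    f_s = [p.samples_per_year for p in survey]
    n_pr = [n for p in survey for n in p.presentations_per_sample]
    if not n_pr:
        raise ValueError("survey carries no presentation counts (N_PR)")
    return ExposureModel(
        constants=constants,
        spec_n_pr=fit_spec(n_pr),
        spec_f_s=fit_spec(f_s),
        spec_n_y=fit_spec(n_y),
    )


def fit_all(
    samples: list[SampleRecord],
    survey: list[PanelistRecord],
    tox: ToxTable,
    constants: LabConstants | None = None,
) -> FittedInputs:
    constants = constants or LabConstants()
    categories, exclusions, detections = fit_category_inputs(samples, tox, constants)
    exposure = fit_exposure_model(survey, constants)
    return FittedInputs(
        categories=categories,
        exposure=exposure,
        exclusions=exclusions,
        detection_counts=detections,
    )


@dataclass
class AssessmentResult:
    """Per-category HI and IR outcomes for one full run."""

    hi: dict[str, RiskDistribution] = field(default_factory=dict)
    ir: dict[str, RiskDistribution | IRNotComputable] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    @property
    def any_unacceptable(self) -> bool:
        flagged = [d for d in self.hi.values() if not d.verdict]
        flagged += [
            d
            for d in self.ir.values()
            if isinstance(d, RiskDistribution) and not d.verdict
        ]
        return bool(flagged)


def run_assessment(
    fitted: FittedInputs,
    iterations: int = 1000,
    seed: int = 0,
    hi_threshold: float = 1.0,
    ir_threshold: float = 1e-5,
    percentile_used: float = 95.0,
) -> AssessmentResult:
    """Simulate HI and IR for every fitted category.

    A category that cannot be assessed (e.g. no compound with an OEL) is
    reported in ``skipped`` and the run continues.
    """
    result = AssessmentResult()
    for name, inputs in sorted(fitted.categories.items()):
        try:
            result.hi[name] = simulate_hi(
                inputs, iterations, seed, hi_threshold, percentile_used
            )
        except ValueError as exc:
            result.skipped[name] = str(exc)
            log.warning("category %s skipped for HI: %s", name, exc)
        result.ir[name] = simulate_ir(
            inputs, fitted.exposure, iterations, seed, ir_threshold, percentile_used
        )
        if isinstance(result.ir[name], IRNotComputable):
            log.info("category %s: IR not computable (%s)", name, result.ir[name].reason)
    return result
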