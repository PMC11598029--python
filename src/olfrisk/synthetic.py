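"""Synthetic laboratory datasets with known ground truth.

Real olfactometric survey data are confidential, so this module
generates datasets with the statistical structure the risk method
assumes: several industrial sample categories, each with an odor
concentration distribution and a panel of compounds; only a configurable
fraction of the samples is chemically characterized (one quarter by
default, matching the partial-characterization design of a typical
annual laboratory survey); and a panelist survey with dispersed working
years, analysis frequencies and presentation counts.

Concentrations and odor concentrations are drawn log-normally:
environmental mixture concentrations are right-skewed, with most mass in
the lower tail and rare high values.  The fitting stage of the pipeline
still uses truncated Gaussians, so the generator deliberately exercises
the same model misspecification the method incurs on real data.

The default scenario ships plausible placeholder compound panels and
toxicology values — it is synthetic and does not reproduce any real
laboratory's inventory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import numpy as np
import pandas as pd

from .core import (
    CompoundMeasurement,
    LabConstants,
    PanelistRecord,
    SampleRecord,
    ToxTable,
    load_tox_table,
)
from .distributions import (
    TruncatedGaussianSpec,
    child_rng,
    fit_spec,
    sample,
    sample_integer,
    truncated_normal_ppf,
)
from .olfactometry import compute_inhalation_concentration
from .risk import lifetime_exposure_fraction

__all__ = [
    "CompoundSpec",
    "CategorySpec",
    "PanelSpec",
    "ScenarioSpec",
    "GeneratedDataset",
    "ReferenceRisk",
    "generate_dataset",
    "analytic_reference_risk",
    "default_scenario",
    "default_tox_frame",
    "write_dataset_csvs",
]


@dataclass
class CompoundSpec:
    """Generating law for one compound's concentration (µg/m³).

    Concentrations are log-normal: exp(N(log_mean, log_sd)).  A compound
    is detected in a characterized sample with probability
    ``detection_prob``; undetected means no row for that sample (not a
    zero).  Optional ``max_concentration`` guards clip rare extremes.
    """

    compound_id: str
    log_mean: float
    log_sd: float
    detection_prob: float = 1.0
    max_concentration: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.detection_prob <= 1):
            raise ValueError(f"{self.compound_id}: detection_prob must be in (0, 1]")
        if self.log_sd < 0:
            raise ValueError(f"{self.compound_id}: log_sd must be >= 0")


@dataclass
class CategorySpec:
    """One industrial sample category of the scenario."""

    name: str
    n_samples: int
    chem_fraction: float
    compounds: list[CompoundSpec]
    odor_log_mean: float = 5.5  # exp(5.5) ~ 245 ou_E/m³ typical C_od
    odor_log_sd: float = 0.8

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"{self.name}: n_samples must be >= 1")
        if not (0 < self.chem_fraction <= 1):
            raise ValueError(f"{self.name}: chem_fraction must be in (0, 1]")
        if not self.compounds:
            raise ValueError(f"{self.name}: compounds must be non-empty")
        if self.odor_log_sd < 0:
            raise ValueError(f"{self.name}: odor_log_sd must be >= 0")

    @property
    def n_characterized(self) -> int:
        return int(round(self.chem_fraction * self.n_samples))


@dataclass
class PanelSpec:
    """Generating truncated Gaussians for the panelist survey."""

    n_panelists: int
    spec_n_y: TruncatedGaussianSpec
    spec_f_s: TruncatedGaussianSpec
    spec_n_pr: TruncatedGaussianSpec
    obs_per_panelist: int = 20  # N_PR observations recorded per panelist

    def __post_init__(self) -> None:
        if self.n_panelists < 1:
            raise ValueError("n_panelists must be >= 1")
        for name in ("spec_n_y", "spec_f_s", "spec_n_pr"):
            if getattr(self, name).lower <= 0:
                raise ValueError(f"{name}: generating spec must have lower > 0")


@dataclass
class ScenarioSpec:
    """Full synthetic-scenario description (categories + panel + seed)."""

    categories: list[CategorySpec]
    panel: PanelSpec
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError("categories must be non-empty")
        names = [c.name for c in self.categories]
        if len(set(names)) != len(names):
            raise ValueError("category names must be unique")


@dataclass
class GeneratedDataset:
    """Generated samples and survey with the generating truth echoed."""

    samples: list[SampleRecord]
    survey: list[PanelistRecord]
    truth: ScenarioSpec


def generate_dataset(spec: ScenarioSpec) -> GeneratedDataset:
    """Draw a full laboratory dataset; fully determined by master_seed.

    Exactly round(chem_fraction × n_samples) samples per category carry
    chemistry; the rest have an odor concentration only.
    """
    samples: list[SampleRecord] = []
    for cat in spec.categories:
        rng = child_rng(spec.master_seed, "category", cat.name)
        c_od = np.exp(rng.normal(cat.odor_log_mean, cat.odor_log_sd, cat.n_samples))
        characterized = set(rng.permutation(cat.n_samples)[: cat.n_characterized])
        for i in range(cat.n_samples):
            measurements: list[CompoundMeasurement] = []
            if i in characterized:
                for comp in cat.compounds:
                    if rng.random() >= comp.detection_prob:
                        continue
                    conc = float(np.exp(rng.normal(comp.log_mean, comp.log_sd)))
                    if comp.max_concentration is not None:
                        conc = min(conc, comp.max_concentration)
                    measurements.append(
                        CompoundMeasurement(comp.compound_id, conc, "µg/m³")
                    )
            samples.append(
                SampleRecord(
                    sample_id=f"{cat.name}-{i:04d}",
                    category=cat.name,
                    odor_concentration=float(c_od[i]),
                    measurements=measurements,
                )
            )

    survey: list[PanelistRecord] = []
    for p in range(spec.panel.n_panelists):
        rng = child_rng(spec.master_seed, "panel", p)
        survey.append(
            PanelistRecord(
                panelist_id=f"panelist-{p:02d}",
                working_years=float(sample(spec.panel.spec_n_y, 1, rng)[0]),
                samples_per_year=float(sample(spec.panel.spec_f_s, 1, rng)[0]),
                presentations_per_sample=[
                    int(v)
                    for v in sample_integer(
                        spec.panel.spec_n_pr, spec.panel.obs_per_panelist, rng
                    )
                ],
            )
        )
    return GeneratedDataset(samples=samples, survey=survey, truth=spec)


@dataclass
class ReferenceRisk:
    """Closed-form reference quantiles for a single-compound scenario."""

    compound_id: str
    cin_spec: TruncatedGaussianSpec
    hi_p95: float
    ir_p50: float | None
    ir_reason: str | None = None


def analytic_reference_risk(
    category: CategorySpec,
    panel: PanelSpec,
    tox: ToxTable,
    constants: LabConstants,
    master_seed: int = 0,
) -> ReferenceRisk:
    """Closed-form HI p95 and IR p50 for a single-compound scenario.

    Generates the dataset, computes per-sample Cin = (C_i/C_od)·k in the
    pipeline's own order of operations, fits the truncated-Gaussian spec,
    and returns analytic quantiles of the fitted law — the 95th
    percentile of Cin/OEL for HI and the median of Cin·IUR·fraction for
    IR.  Requires exactly one compound and a degenerate (σ = 0) panel so
    the closed form exists; a missing IUR yields the explicit
    not-computable marker (ir_p50 is None).
    """
    if len(category.compounds) != 1:
        raise ValueError("closed-form reference requires exactly one compound")
    for name in ("spec_n_y", "spec_f_s", "spec_n_pr"):
        if getattr(panel, name).sigma != 0:
            raise ValueError(
                f"closed-form reference requires a degenerate panel ({name} has sigma != 0)"
            )
    compound = category.compounds[0]
    profile = tox.get(compound.compound_id)
    if profile is None or not profile.has_oel:
        raise ValueError(f"{compound.compound_id}: no OEL in the tox table")

    dataset = generate_dataset(ScenarioSpec([category], panel, master_seed))
    k = constants.safety_factor_k
    cin_values = [
        compute_inhalation_concentration(m.concentration, s.odor_concentration, k)
        for s in dataset.samples
        for m in s.measurements
        if m.compound_id == compound.compound_id
    ]
    if not cin_values:
        raise ValueError("generated scenario contains no detections to fit")
    cin_spec = fit_spec(cin_values)

    hi_p95 = truncated_normal_ppf(cin_spec, 0.95) / profile.oel_value

    if not profile.is_carcinogen:
        return ReferenceRisk(
            compound.compound_id, cin_spec, hi_p95, None, "no IUR: IR not computable"
        )
    # degenerate panel: the exposure parameters collapse to constants,
    # with N_PR rounded exactly as the integer sampler rounds it
    n_pr = int(sample_integer(panel.spec_n_pr, 1, 0)[0])
    fraction = lifetime_exposure_fraction(
        panel.spec_n_y.mu,
        panel.spec_f_s.mu,
        n_pr,
        constants.rounds_per_sample,
        constants.inhalation_time_s,
        constants.averaging_time_days_per_year,
        constants.lifetime_years,
    )
    ir_p50 = truncated_normal_ppf(cin_spec, 0.5) * profile.iur * fraction
    return ReferenceRisk(compound.compound_id, cin_spec, hi_p95, ir_p50)


# ---------------------------------------------------------------------------
# default scenario (synthetic placeholder panels)


def default_tox_frame() -> pd.DataFrame:
    """Synthetic toxicology table for the default scenario.

    Values are plausible occupational reference values (order-of-magnitude
    realistic) but the table is a placeholder, not a vetted regulatory
    source; real assessments must supply their own tox CSV.
    """
    rows = [
        # compound_id, oel_value, oel_unit, oel_kind, iur, iur_unit, note
        ("toluene", 75.0, "mg/m3", "twa_8h", None, "", "synthetic placeholder; 8-h TWA"),
        ("benzene", 8.0, "mg/m3", "short_term_15min", 7.8e-6, "per_ug_m3", "synthetic placeholder; carcinogen"),
        ("xylene", 651.0, "mg/m3", "short_term_15min", None, "", "synthetic placeholder"),
        ("ethylbenzene", 87.0, "mg/m3", "twa_8h", 2.5e-6, "per_ug_m3", "synthetic placeholder; carcinogen"),
        ("hydrogen_sulfide", 7.0, "mg/m3", "short_term_15min", None, "", "synthetic placeholder"),
        ("ammonia", 24.0, "mg/m3", "short_term_15min", None, "", "synthetic placeholder"),
        ("limonene", 110.0, "mg/m3", "twa_8h", None, "", "synthetic placeholder"),
        ("formaldehyde", 0.37, "mg/m3", "short_term_15min", 1.3e-5, "per_ug_m3", "synthetic placeholder; carcinogen"),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "compound_id",
            "oel_value",
            "oel_unit",
            "oel_kind",
            "iur",
            "iur_unit",
            "source_note",
        ],
    )


def default_tox_table() -> ToxTable:
    return load_tox_table(default_tox_frame())


def default_scenario(master_seed: int = 0) -> ScenarioSpec:
    """Default synthetic laboratory year: 1035 samples, 25% characterized.

    Seven categories mirror the breadth of an industrial-odor laboratory;
    two of them (wwtp, biofuel) carry no carcinogenic compound, so their
    IR is reported as not computable.  Panel dispersion (working years
    1–12, 40–400 samples/year, 6–14 presentations) reflects the high
    variability typical of part-time olfactometric panels.
    """

    def cat(name, n, compounds, odor_mu=5.5, odor_sd=0.8):
        return CategorySpec(
            name=name,
            n_samples=n,
            chem_fraction=0.25,
            compounds=compounds,
            odor_log_mean=odor_mu,
            odor_log_sd=odor_sd,
        )

    categories = [
        cat(
            "refinery",
            180,
            [
                CompoundSpec("toluene", 8.6, 1.0, 0.9),
                CompoundSpec("benzene", 7.2, 1.1, 0.8),
                CompoundSpec("xylene", 8.2, 1.0, 0.85),
                CompoundSpec("hydrogen_sulfide", 6.8, 1.2, 0.7),
            ],
            odor_mu=6.0,
        ),
        cat(
            "petrochemical_cracking",
            150,
            [
                CompoundSpec("benzene", 7.8, 1.1, 0.85),
                CompoundSpec("toluene", 8.9, 1.0, 0.9),
                CompoundSpec("ethylbenzene", 7.6, 1.1, 0.8),
            ],
            odor_mu=6.2,
        ),
        cat(
            "hydrocarbon_tanks",
            140,
            [
                CompoundSpec("toluene", 8.4, 1.1, 0.9),
                CompoundSpec("xylene", 8.0, 1.1, 0.8),
                CompoundSpec("benzene", 6.9, 1.2, 0.7),
            ],
        ),
        cat(
            "wwtp",
            160,
            [
                CompoundSpec("hydrogen_sulfide", 7.4, 1.2, 0.9),
                CompoundSpec("ammonia", 8.2, 1.0, 0.85),
                CompoundSpec("limonene", 6.8, 1.1, 0.6),
            ],
            odor_mu=5.2,
        ),
        cat(
            "biofuel",
            85,
            [
                CompoundSpec("limonene", 7.6, 1.0, 0.9),
                CompoundSpec("ammonia", 7.4, 1.1, 0.7),
            ],
            odor_mu=5.0,
        ),
        cat(
            "biomass",
            170,
            [
                CompoundSpec("limonene", 7.9, 1.1, 0.9),
                CompoundSpec("formaldehyde", 5.4, 1.0, 0.6),
                CompoundSpec("ammonia", 7.2, 1.1, 0.7),
            ],
            odor_mu=5.3,
        ),
        cat(
            "bitumen",
            150,
            [
                CompoundSpec("toluene", 8.0, 1.0, 0.85),
                CompoundSpec("xylene", 7.8, 1.0, 0.8),
                CompoundSpec("hydrogen_sulfide", 6.4, 1.2, 0.6),
                CompoundSpec("benzene", 6.4, 1.2, 0.5),
            ],
            odor_mu=5.8,
        ),
    ]
    assert sum(c.n_samples for c in categories) == 1035
    panel = PanelSpec(
        n_panelists=8,
        spec_n_y=TruncatedGaussianSpec(mu=5.0, sigma=3.0, lower=1.0, upper=12.0),
        spec_f_s=TruncatedGaussianSpec(mu=180.0, sigma=90.0, lower=40.0, upper=400.0),
        spec_n_pr=TruncatedGaussianSpec(mu=9.5, sigma=2.0, lower=6.0, upper=14.0),
    )
    return ScenarioSpec(categories=categories, panel=panel, master_seed=master_seed)


# ---------------------------------------------------------------------------
# CSV export (same dialects the core readers consume)


def write_dataset_csvs(dataset: GeneratedDataset, out_dir, tox_frame: pd.DataFrame | None = None) -> dict[str, str]:
    """Write samples/odor/survey/presentations (and optional tox) CSVs.

    Returns the mapping of logical name -> written path.  The files use
    exactly the dialects :mod:`olfrisk.core` reads, so generated data
    exercises the real I/O path.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "samples": os.path.join(out_dir, "samples.csv"),
        "odor": os.path.join(out_dir, "odor.csv"),
        "survey": os.path.join(out_dir, "survey.csv"),
        "presentations": os.path.join(out_dir, "presentations.csv"),
    }

    chem_rows = [
        {
            "sample_id": s.sample_id,
            "category": s.category,
            "compound_id": m.compound_id,
            "concentration": m.concentration,
            "unit": "µg/m³",
        }
        for s in dataset.samples
        for m in s.measurements
    ]
    pd.DataFrame(
        chem_rows,
        columns=["sample_id", "category", "compound_id", "concentration", "unit"],
    ).to_csv(paths["samples"], index=False)

    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "category": s.category,
                "odor_concentration": s.odor_concentration,
            }
            for s in dataset.samples
        ]
    ).to_csv(paths["odor"], index=False)

    pd.DataFrame(
        [
            {
                "panelist_id": p.panelist_id,
                "working_years": p.working_years,
                "samples_per_year": p.samples_per_year,
            }
            for p in dataset.survey
        ]
    ).to_csv(paths["survey"], index=False)

    pres_rows = [
        {
            "panelist_id": p.panelist_id,
            "sample_id": f"analysis-{i:03d}",
            "n_presentations": n,
        }
        for p in dataset.survey
        for i, n in enumerate(p.presentations_per_sample)
    ]
    pd.DataFrame(
        pres_rows, columns=["panelist_id", "sample_id", "n_presentations"]
    ).to_csv(paths["presentations"], index=False)

    if tox_frame is not None:
        paths["tox"] = os.path.join(out_dir, "tox.csv")
        tox_frame.to_csv(paths["tox"], index=False)
    return paths
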