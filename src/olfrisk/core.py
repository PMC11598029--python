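"""Domain types, unit canonicalization and the toxicology lookup.

Every concentration in the package is stored in µg/m³.  This matches the
basis of the inhalation unit risk (IUR, excess lifetime cancer risk per
µg/m³ of continuous exposure) so that hazard quotients and risk products
never mix units: the single conversion point is data ingest.

Occupational exposure limits (OELs) come in two flavours relevant here:
a short-term (15-min) limit, which matches the seconds-long intermittent
exposure of an olfactometric panelist, and an 8-h time-weighted average,
kept as a conservative fallback for compounds that have no short-term
value (8-h limits are lower, so using them overestimates the hazard
quotient).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CompoundMeasurement",
    "SampleRecord",
    "ToxProfile",
    "ToxTable",
    "PanelistRecord",
    "LabConstants",
    "canonicalize_concentration",
    "load_tox_table",
    "read_tox_csv",
    "read_samples",
    "read_survey",
    "OEL_SHORT_TERM",
    "OEL_TWA_8H",
]

log = logging.getLogger(__name__)

OEL_SHORT_TERM = "short_term_15min"
OEL_TWA_8H = "twa_8h"

#: accepted unit spellings -> multiplicative factor to µg/m³
_UNIT_TO_UG = {
    "µg/m³": 1.0,
    "µg/m3": 1.0,
    "ug/m³": 1.0,
    "ug/m3": 1.0,
    "mg/m³": 1000.0,
    "mg/m3": 1000.0,
}

#: accepted IUR unit spellings -> factor to per-(µg/m³)
_IUR_UNIT_TO_PER_UG = {
    "per_ug_m3": 1.0,
    "per (µg/m³)": 1.0,
    "1/(µg/m³)": 1.0,
    "per_mg_m3": 1e-3,
    "per (mg/m³)": 1e-3,
    "1/(mg/m³)": 1e-3,
}


def canonicalize_concentration(value: float, unit: str) -> float:
    """Convert a concentration to µg/m³.

    Parameters
    ----------
    value
        Non-negative concentration in ``unit``.
    unit
        One of the accepted spellings of mg/m³ or µg/m³.

    Returns
    -------
    float
        The concentration in µg/m³ (idempotent when already µg/m³).
    """
    try:
        factor = _UNIT_TO_UG[str(unit).strip()]
    except KeyError:
        raise ValueError(f"unknown concentration unit: {unit!r}") from None
    value = float(value)
    if value < 0:
        raise ValueError(f"concentration must be >= 0, got {value}")
    return value * factor


@dataclass(frozen=True)
class CompoundMeasurement:
    """One chemical concentration measured in one sample (canonical µg/m³)."""

    compound_id: str
    concentration: float  # µg/m³
    original_unit: str = "µg/m³"

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(
                f"{self.compound_id}: concentration must be >= 0, "
                f"got {self.concentration}"
            )

    @classmethod
    def from_raw(cls, compound_id: str, value: float, unit: str) -> "CompoundMeasurement":
        """Build a measurement from a raw value, converting units exactly once."""
        return cls(compound_id, canonicalize_concentration(value, unit), unit)


@dataclass
class SampleRecord:
    """One olfactometric sample: category, odor concentration, chemistry.

    ``odor_concentration`` is C_od in ou_E/m³ — the number of neutral-air
    dilutions needed to bring the sample to its detection threshold.
    ``measurements`` is empty for samples that were analysed
    olfactometrically but not chemically characterized.
    """

    sample_id: str
    category: str
    odor_concentration: float  # ou_E/m³
    measurements: list[CompoundMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.odor_concentration <= 0:
            raise ValueError(
                f"sample {self.sample_id}: odor_concentration must be > 0, "
                f"got {self.odor_concentration}"
            )

    @property
    def is_characterized(self) -> bool:
        return len(self.measurements) > 0


@dataclass
class ToxProfile:
    """Toxicological reference values for one compound.

    ``oel_value`` is the active OEL in µg/m³ and ``oel_kind`` says whether
    it is the short-term (15-min) limit or the 8-h TWA fallback.  When both
    kinds are supplied the short-term one is active and the 8-h value is
    retained in ``twa_fallback``.  A missing ``iur`` marks a non-carcinogen.
    """

    compound_id: str
    oel_value: float | None = None  # µg/m³
    oel_kind: str | None = None
    iur: float | None = None  # per (µg/m³)
    twa_fallback: float | None = None  # µg/m³
    source_note: str = ""

    def __post_init__(self) -> None:
        if self.oel_value is not None and self.oel_value <= 0:
            raise ValueError(f"{self.compound_id}: OEL must be > 0")
        if self.iur is not None and self.iur < 0:
            raise ValueError(f"{self.compound_id}: IUR must be >= 0")

    @property
    def has_oel(self) -> bool:
        return self.oel_value is not None

    @property
    def is_carcinogen(self) -> bool:
        return self.iur is not None and self.iur > 0

    @property
    def usable(self) -> bool:
        """Whether the profile contributes to at least one risk metric."""
        return self.has_oel or self.is_carcinogen


@dataclass
class ToxTable:
    """Mapping compound_id -> ToxProfile plus load diagnostics.

    ``rejected`` lists rows that failed validation (with a reason);
    ``unusable`` lists loaded compounds carrying neither an OEL nor an
    IUR, which are excluded from both risk metrics but never silently
    dropped.
    """

    profiles: dict[str, ToxProfile] = field(default_factory=dict)
    rejected: list[dict] = field(default_factory=list)

    def __getitem__(self, compound_id: str) -> ToxProfile:
        return self.profiles[compound_id]

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self.profiles

    def __len__(self) -> int:
        return len(self.profiles)

    def get(self, compound_id: str) -> ToxProfile | None:
        return self.profiles.get(compound_id)

    @property
    def unusable(self) -> list[str]:
        return [cid for cid, p in self.profiles.items() if not p.usable]


@dataclass
class PanelistRecord:
    """Exposure survey entry for one panelist.

    working_years is N_Y (exposure duration), samples_per_year is F_S
    (exposure frequency) and presentations_per_sample collects the
    observed N_PR counts over the panelist's analyses.
    """

    panelist_id: str
    working_years: float
    samples_per_year: float
    presentations_per_sample: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.working_years <= 0:
            raise ValueError(f"{self.panelist_id}: working_years must be > 0")
        if self.samples_per_year <= 0:
            raise ValueError(f"{self.panelist_id}: samples_per_year must be > 0")
        if any(n < 1 for n in self.presentations_per_sample):
            raise ValueError(
                f"{self.panelist_id}: every presentation count must be >= 1"
            )


@dataclass
class LabConstants:
    """Laboratory and regulatory constants that are not randomized.

    rounds_per_sample (N_R) and inhalation_time_s (IT, conservatively set
    to the olfactometer presentation time) are fixed by the laboratory
    set-up.  averaging_time_days_per_year (AT = 365 d/yr) and
    lifetime_years (LT = 70 yr) follow the U.S. EPA convention for
    lifetime cancer-risk averaging.  safety_factor_k defaults to 10
    (maximum admissible panel deviation x confirmation doubling) and
    delta_z_max to 5, the retrospective-screening bound.
    """

    rounds_per_sample: int = 3
    inhalation_time_s: float = 3.0
    safety_factor_k: float = 10.0
    averaging_time_days_per_year: float = 365.0
    lifetime_years: float = 70.0
    delta_z_max: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "rounds_per_sample",
            "inhalation_time_s",
            "safety_factor_k",
            "averaging_time_days_per_year",
            "lifetime_years",
            "delta_z_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"LabConstants.{name} must be > 0")


# ---------------------------------------------------------------------------
# toxicology table loading


def _parse_optional(value) -> float | None:
    if value is None or (isinstance(value, str) and not value.strip()):
        return None
    if pd.isna(value):
        return None
    return float(value)


def load_tox_table(rows: pd.DataFrame) -> ToxTable:
    """Build the toxicology lookup from tabular records.

    Expected columns: compound_id, oel_value, oel_unit, oel_kind
    (short_term_15min or twa_8h), iur, iur_unit, source_note.  A compound
    may appear on several rows (one per OEL kind); the short-term value
    becomes the active OEL and an 8-h value is kept as fallback metadata.
    Rows with a non-positive OEL or an unknown unit are rejected with a
    diagnostic; compounds with neither OEL nor IUR are loaded but flagged
    unusable.
    """
    table = ToxTable()
    parsed: dict[str, dict[str, float | None]] = {}
    notes: dict[str, list[str]] = {}

    for _, row in rows.iterrows():
        cid = str(row["compound_id"]).strip()
        try:
            oel_raw = _parse_optional(row.get("oel_value"))
            oel_kind = row.get("oel_kind")
            oel_kind = None if (oel_kind is None or pd.isna(oel_kind) or not str(oel_kind).strip()) else str(oel_kind).strip()
            oel = None
            if oel_raw is not None:
                if oel_raw <= 0:
                    raise ValueError(f"OEL must be > 0, got {oel_raw}")
                if oel_kind not in (OEL_SHORT_TERM, OEL_TWA_8H):
                    raise ValueError(f"unknown oel_kind: {oel_kind!r}")
                oel = canonicalize_concentration(oel_raw, row["oel_unit"])
            iur = _parse_optional(row.get("iur"))
            if iur is not None:
                if iur < 0:
                    raise ValueError(f"IUR must be >= 0, got {iur}")
                iur_unit = str(row.get("iur_unit", "per_ug_m3")).strip() or "per_ug_m3"
                try:
                    iur *= _IUR_UNIT_TO_PER_UG[iur_unit]
                except KeyError:
                    raise ValueError(f"unknown iur_unit: {iur_unit!r}") from None
        except (ValueError, KeyError) as exc:
            table.rejected.append({"compound_id": cid, "reason": str(exc)})
            log.warning("rejected tox row for %s: %s", cid, exc)
            continue

        entry = parsed.setdefault(cid, {"short": None, "twa": None, "iur": None})
        if oel is not None:
            entry["short" if oel_kind == OEL_SHORT_TERM else "twa"] = oel
        if iur is not None:
            entry["iur"] = iur
        note = row.get("source_note")
        if note is not None and not pd.isna(note) and str(note).strip():
            notes.setdefault(cid, []).append(str(note).strip())

    for cid, entry in parsed.items():
        if entry["short"] is not None:
            oel_value, oel_kind = entry["short"], OEL_SHORT_TERM
            fallback = entry["twa"]
        elif entry["twa"] is not None:
            oel_value, oel_kind = entry["twa"], OEL_TWA_8H
            fallback = None
        else:
            oel_value = oel_kind = fallback = None
        profile = ToxProfile(
            compound_id=cid,
            oel_value=oel_value,
            oel_kind=oel_kind,
            iur=entry["iur"],
            twa_fallback=fallback,
            source_note="; ".join(notes.get(cid, [])),
        )
        if not profile.usable:
            log.warning("compound %s has neither OEL nor IUR; flagged unusable", cid)
        table.profiles[cid] = profile
    return table


def read_tox_csv(path) -> ToxTable:
    """Read a toxicology CSV (see :func:`load_tox_table` for columns)."""
    return load_tox_table(pd.read_csv(path))


# ---------------------------------------------------------------------------
# sample and survey readers


def read_samples(samples_csv, odor_csv) -> list[SampleRecord]:
    """Read samples from the long-format chemistry CSV plus the odor CSV.

    samples_csv columns: sample_id, category, compound_id, concentration,
    unit (one row per detected compound; samples without chemistry simply
    have no rows here).  odor_csv columns: sample_id, odor_concentration
    — one row per olfactometric sample, including uncharacterized ones;
    it also carries the category so uncharacterized samples keep theirs.
    """
    odor = pd.read_csv(odor_csv)
    chem = pd.read_csv(samples_csv)
    if odor["sample_id"].duplicated().any():
        dup = odor.loc[odor["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in odor table: {dup!r}")

    by_sample: dict[str, list[CompoundMeasurement]] = {}
    categories: dict[str, str] = {}
    for _, row in chem.iterrows():
        sid = str(row["sample_id"])
        by_sample.setdefault(sid, []).append(
            CompoundMeasurement.from_raw(
                str(row["compound_id"]), float(row["concentration"]), str(row["unit"])
            )
        )
        categories[sid] = str(row["category"])

    records = []
    for _, row in odor.iterrows():
        sid = str(row["sample_id"])
        category = str(row["category"]) if "category" in odor.columns else categories.get(sid, "")
        records.append(
            SampleRecord(
                sample_id=sid,
                category=category,
                odor_concentration=float(row["odor_concentration"]),
                measurements=by_sample.get(sid, []),
            )
        )
    known = {r.sample_id for r in records}
    orphans = set(by_sample) - known
    if orphans:
        raise ValueError(
            f"chemistry rows reference samples missing from the odor table: {sorted(orphans)[:5]}"
        )
    return records


def read_survey(survey_csv, presentations_csv) -> list[PanelistRecord]:
    """Read the panelist survey and its per-analysis presentation counts.

    survey_csv columns: panelist_id, working_years, samples_per_year.
    presentations_csv columns: panelist_id, sample_id, n_presentations.
    """
    survey = pd.read_csv(survey_csv)
    pres = pd.read_csv(presentations_csv)
    counts: dict[str, list[int]] = {}
    for _, row in pres.iterrows():
        counts.setdefault(str(row["panelist_id"]), []).append(int(row["n_presentations"]))
    return [
        PanelistRecord(
            panelist_id=str(row["panelist_id"]),
            working_years=float(row["working_years"]),
            samples_per_year=float(row["samples_per_year"]),
            presentations_per_sample=counts.get(str(row["panelist_id"]), []),
        )
        for _, row in survey.iterrows()
    ]
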