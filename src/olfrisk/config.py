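"""Run configuration: a single YAML file drives every CLI command.

Exactly one input source must be configured: either the five real-data
CSV paths (``data:`` section) or a synthetic scenario (``scenario:``,
which may be the string ``default`` or a full inline scenario
description).  All simulation defaults (iterations 1000, percentile 95,
HI threshold 1, IR threshold 1e-5, k 10, N_R 3, IT 3 s, AT 365, LT 70,
ΔZ_max 5) are overridable and echoed into output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .core import LabConstants
from .distributions import TruncatedGaussianSpec
from .synthetic import (
    CategorySpec,
    CompoundSpec,
    PanelSpec,
    ScenarioSpec,
    default_scenario,
)

__all__ = ["DataPaths", "RunConfig", "load_config"]


@dataclass
class DataPaths:
    samples: str
    odor: str
    tox: str
    survey: str
    presentations: str


@dataclass
class RunConfig:
    data: DataPaths | None = None
    scenario: ScenarioSpec | None = None
    iterations: int = 1000
    master_seed: int = 0
    percentile_used: float = 95.0
    hi_threshold: float = 1.0
    ir_threshold: float = 1e-5
    replicate_count: int = 5
    sensitivity_tolerance: float = 0.05
    constants: LabConstants = field(default_factory=LabConstants)

    def __post_init__(self) -> None:
        if (self.data is None) == (self.scenario is None):
            raise ValueError(
                "exactly one of a data section and a scenario must be configured"
            )
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.hi_threshold <= 0 or self.ir_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if not (0 < self.percentile_used < 100):
            raise ValueError("percentile_used must lie in (0, 100)")

    def metadata(self) -> dict:
        """Flat echo of the configuration for output provenance."""
        meta = {
            "iterations": self.iterations,
            "master_seed": self.master_seed,
            "percentile_used": self.percentile_used,
            "hi_threshold": self.hi_threshold,
            "ir_threshold": self.ir_threshold,
            "replicate_count": self.replicate_count,
            "sensitivity_tolerance": self.sensitivity_tolerance,
            "input_mode": "data" if self.data is not None else "scenario",
        }
        meta.update({f"constants.{k}": v for k, v in asdict(self.constants).items()})
        return meta


def _parse_spec(node: dict, context: str) -> TruncatedGaussianSpec:
    try:
        return TruncatedGaussianSpec(
            mu=float(node["mu"]),
            sigma=float(node["sigma"]),
            lower=float(node["lower"]),
            upper=float(node["upper"]),
        )
    except KeyError as exc:
        raise ValueError(f"{context}: missing field {exc}") from None


def _parse_scenario(node, master_seed: int) -> ScenarioSpec:
    if isinstance(node, str):
        if node == "default":
            return default_scenario(master_seed)
        raise ValueError(f"unknown scenario name: {node!r}")
    categories = [
        CategorySpec(
            name=cat["name"],
            n_samples=int(cat["n_samples"]),
            chem_fraction=float(cat.get("chem_fraction", 0.25)),
            compounds=[
                CompoundSpec(
                    compound_id=c["compound_id"],
                    log_mean=float(c["log_mean"]),
                    log_sd=float(c["log_sd"]),
                    detection_prob=float(c.get("detection_prob", 1.0)),
                    max_concentration=(
                        float(c["max_concentration"])
                        if "max_concentration" in c
                        else None
                    ),
                )
                for c in cat["compounds"]
            ],
            odor_log_mean=float(cat.get("odor_log_mean", 5.5)),
            odor_log_sd=float(cat.get("odor_log_sd", 0.8)),
        )
        for cat in node["categories"]
    ]
    panel_node = node["panel"]
    panel = PanelSpec(
        n_panelists=int(panel_node["n_panelists"]),
        spec_n_y=_parse_spec(panel_node["n_y"], "panel.n_y"),
        spec_f_s=_parse_spec(panel_node["f_s"], "panel.f_s"),
        spec_n_pr=_parse_spec(panel_node["n_pr"], "panel.n_pr"),
        obs_per_panelist=int(panel_node.get("obs_per_panelist", 20)),
    )
    return ScenarioSpec(categories=categories, panel=panel, master_seed=master_seed)


def load_config(path, seed_override: int | None = None) -> RunConfig:
    """Load a YAML run configuration, optionally overriding the seed."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a mapping")
    master_seed = int(raw.get("master_seed", 0))
    if seed_override is not None:
        master_seed = int(seed_override)

    data = None
    if "data" in raw:
        d = raw["data"]
        try:
            data = DataPaths(
                samples=d["samples"],
                odor=d["odor"],
                tox=d["tox"],
                survey=d["survey"],
                presentations=d["presentations"],
            )
        except KeyError as exc:
            raise ValueError(f"data section: missing path {exc}") from None

    scenario = None
    if "scenario" in raw:
        scenario = _parse_scenario(raw["scenario"], master_seed)

    constants_kwargs = raw.get("constants", {}) or {}
    constants = LabConstants(**constants_kwargs)

    return RunConfig(
        data=data,
        scenario=scenario,
        iterations=int(raw.get("iterations", 1000)),
        master_seed=master_seed,
        percentile_used=float(raw.get("percentile_used", 95.0)),
        hi_threshold=float(raw.get("hi_threshold", 1.0)),
        ir_threshold=float(raw.get("ir_threshold", 1e-5)),
        replicate_count=int(raw.get("replicate_count", 5)),
        sensitivity_tolerance=float(raw.get("sensitivity_tolerance", 0.05)),
        constants=constants,
    )
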