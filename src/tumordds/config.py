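"""Scenario configuration: validated settings for one reproducible run."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from pathlib import Path
from typing import Any

import yaml


@dataclass
class ScenarioConfig:
    """All knobs of one delivery scenario.

    Lengths in meters, times in seconds, concentrations in mol/m³.
    ``c0`` is the injected dose as drug-equivalent plasma concentration
    (``None`` calibrates it so the first conventional-chemotherapy cycle
    kills ``calibration_kill`` of tumor cells).  ``overrides`` are dotted
    SI parameter paths applied to the literature defaults.
    """

    stage: int = 1
    # geometry
    domain_width: float = 2e-3
    domain_height: float = 2e-3
    nx: int = 64
    ny: int = 64
    tumor_radius: float = 5e-4
    seed: int = 0
    n_trunk_points: int = 7
    n_sprouts: int = 14
    vessel_mask_path: str | None = None
    mask_pixel_size: float | None = None
    network_csv_path: str | None = None
    # nanoparticle design
    np_primary_diameter: float | None = 20e-9
    np_secondary_diameter: float | None = 5e-9
    pore_diameter: float = 200e-9
    k_rel: float = 2.1e-6          # two-stage drug release, 1/s
    k_rel1: float = 1e-3           # three-stage: secondary NP release, 1/s
    k_rel2: float = 2.1e-6         # three-stage: drug release, 1/s
    # dosing and schedule
    c0: float | None = None
    calibration_kill: float = 0.3678
    t_end: float = 96.0 * 3600.0
    n_cycles: int = 5
    break_months: float = 1.0
    # solver
    dt0: float = 0.25
    steps_per_phase: int = 48
    free_drug_vascular_exchange: bool = False
    np_lymphatic_drainage: bool = True
    # parameter overrides (dotted SI paths)
    overrides: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        if self.stage not in (1, 2, 3):
            raise ValueError("stage must be 1, 2 or 3")
        if self.stage >= 2 and not self.np_primary_diameter:
            raise ValueError("stage 2/3 requires np_primary_diameter")
        if self.stage == 3 and not self.np_secondary_diameter:
            raise ValueError("stage 3 requires np_secondary_diameter")
        if min(self.domain_width, self.domain_height) <= 0:
            raise ValueError("domain dimensions must be > 0")
        if self.nx < 3 or self.ny < 3:
            raise ValueError("need nx, ny >= 3")
        if not 0 <= self.tumor_radius < 0.5 * min(self.domain_width,
                                                  self.domain_height):
            raise ValueError("tumor must fit strictly inside the domain")
        if self.t_end <= 0 or self.n_cycles < 1 or self.break_months < 0:
            raise ValueError("invalid schedule")
        for name in ("k_rel", "k_rel1", "k_rel2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.c0 is not None and self.c0 <= 0:
            raise ValueError("c0 must be > 0")
        for path_attr in ("vessel_mask_path", "network_csv_path"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{path_attr}: {p}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


def parse_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML scenario configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return ScenarioConfig.from_dict(data)


def write_config(cfg: ScenarioConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
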