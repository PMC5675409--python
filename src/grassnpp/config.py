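"""Pipeline configuration: one YAML file with per-stage blocks.

Every model constant is surfaced here with its standard value as default:
the 0.475 biomass-to-carbon coefficient, eps_max of 0.542 (grassland) and
0.429 (shrub) gC/MJ, the 0.001/0.95 FPAR bounds, the 0.5 PAR fraction, IDW
power 2 and the Angstrom-Prescott a=0.25 / b=0.50 coefficients.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import yaml

from .errors import ConfigError
from .synthetic import WorldConfig

__all__ = ["PipelineConfig", "load_config", "default_config"]


@dataclass
class PipelineConfig:
    world: WorldConfig = field(default_factory=WorldConfig)
    interpolation_power: float = 2.0
    angstrom_a: float = 0.25
    angstrom_b: float = 0.50
    latitude: float = 44.0
    eps_max: dict = field(default_factory=lambda: {"grassland": 0.542, "shrub": 0.429})
    fpar_min: float = 0.001
    fpar_max: float = 0.95
    bucket_capacity_mm: float = 100.0
    calib_pct_lo: float = 5.0
    calib_pct_hi: float = 95.0
    validation_through_month: int = 7
    attribution_alpha: float = 0.05
    attribution_fdr: bool = False
    hist_bin_width: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.fpar_min < self.fpar_max <= 1):
            raise ConfigError("need 0 <= fpar_min < fpar_max <= 1")
        if self.interpolation_power <= 0:
            raise ConfigError("interpolation power must be positive")
        if not (0 <= self.calib_pct_lo < self.calib_pct_hi <= 100):
            raise ConfigError("calibration percentiles must satisfy 0 <= lo < hi <= 100")
        if not (1 <= self.validation_through_month <= 12):
            raise ConfigError("validation through_month must be in 1..12")
        for name, value in self.eps_max.items():
            if value <= 0:
                raise ConfigError(f"eps_max[{name}] must be positive")

    def to_dict(self) -> dict:
        d = {
            "world": asdict(self.world),
            "interpolation": {"power": self.interpolation_power},
            "solar": {"angstrom_a": self.angstrom_a, "angstrom_b": self.angstrom_b},
            "site": {"latitude": self.latitude},
            "casa": {
                "eps_max": dict(self.eps_max),
                "fpar_min": self.fpar_min,
                "fpar_max": self.fpar_max,
                "bucket_capacity_mm": self.bucket_capacity_mm,
                "calib_percentiles": [self.calib_pct_lo, self.calib_pct_hi],
            },
            "validation": {"through_month": self.validation_through_month},
            "attribution": {"alpha": self.attribution_alpha,
                            "fdr": self.attribution_fdr,
                            "hist_bin_width": self.hist_bin_width},
        }
        d["world"]["grid_shape"] = list(self.world.grid_shape)
        d["world"]["county_blocks"] = list(self.world.county_blocks)
        return d

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


_KNOWN_BLOCKS = {"world", "interpolation", "solar", "site", "casa",
                 "validation", "attribution"}


def default_config() -> PipelineConfig:
    return PipelineConfig()


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Load and schema-validate the YAML pipeline configuration."""
    if not os.path.exists(path):
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _KNOWN_BLOCKS
    if unknown:
        raise ConfigError(f"unknown config blocks: {sorted(unknown)}")

    world_kwargs = dict(raw.get("world") or {})
    if "grid_shape" in world_kwargs:
        world_kwargs["grid_shape"] = tuple(world_kwargs["grid_shape"])
    if "county_blocks" in world_kwargs:
        world_kwargs["county_blocks"] = tuple(world_kwargs["county_blocks"])
    try:
        world = WorldConfig(**world_kwargs)
    except TypeError as exc:
        raise ConfigError(f"invalid world block: {exc}") from exc

    interp = raw.get("interpolation") or {}
    solar = raw.get("solar") or {}
    site = raw.get("site") or {}
    casa = raw.get("casa") or {}
    val = raw.get("validation") or {}
    attr = raw.get("attribution") or {}
    pcts = casa.get("calib_percentiles", [5.0, 95.0])
    return PipelineConfig(
        world=world,
        interpolation_power=float(interp.get("power", 2.0)),
        angstrom_a=float(solar.get("angstrom_a", 0.25)),
        angstrom_b=float(solar.get("angstrom_b", 0.50)),
        latitude=float(site.get("latitude", world.latitude)),
        eps_max=dict(casa.get("eps_max", {"grassland": 0.542, "shrub": 0.429})),
        fpar_min=float(casa.get("fpar_min", 0.001)),
        fpar_max=float(casa.get("fpar_max", 0.95)),
        bucket_capacity_mm=float(casa.get("bucket_capacity_mm", 100.0)),
        calib_pct_lo=float(pcts[0]),
        calib_pct_hi=float(pcts[1]),
        validation_through_month=int(val.get("through_month", 7)),
        attribution_alpha=float(attr.get("alpha", 0.05)),
        attribution_fdr=bool(attr.get("fdr", False)),
        hist_bin_width=float(attr.get("hist_bin_width", 0.1)),
    )
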