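"""Run configuration: YAML round-trip, defaults, validation."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields, is_dataclass
from pathlib import Path

import yaml

from .bsa_statistics import ScanConfig
from .variant_screen import FilterThresholds, ScreenConfig


class ConfigError(ValueError):
    """Invalid or unreadable run configuration."""


@dataclass
class SimParams:
    """Simulator section; defaults mirror the study design (30+30 bulks,
    fertility grades 3-4 fertile / 0-1 sterile, pooled depth 10-100x)."""

    n_chrom: int = 3
    chrom_len_bp: int = 10_000_000
    marker_spacing_bp: int = 10_000
    pop_size: int = 200
    bulk_size: int = 30
    f_grades: tuple[int, ...] = (3, 4)
    s_grades: tuple[int, ...] = (0, 1)
    depth_low: int = 10
    depth_high: int = 100
    error_rate: float = 0.001
    contaminant_fraction: float = 0.0
    recomb_rate: float = 4e-8
    qtl_chrom: str = "chr01"
    qtl_pos: int = 5_000_000
    grade_dist_carrier: tuple[float, ...] = (0.02, 0.08, 0.20, 0.35, 0.35)
    grade_dist_noncarrier: tuple[float, ...] = (0.60, 0.30, 0.08, 0.02, 0.00)


@dataclass
class CallParams:
    min_run: int = 10
    min_methods: int = 2


@dataclass
class RunConfig:
    seed: int = 0
    simulate: bool = True
    vcf: str | None = None
    annotation: str | None = None
    sample_roles: dict = field(
        default_factory=lambda: {
            "donor": "P596",
            "recurrent": "P1318",
            "fbulk": "F_bulk",
            "sbulk": "S_bulk",
        }
    )
    sim: SimParams = field(default_factory=SimParams)
    filter_thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    depth_min: int = 10
    depth_max: int = 100
    depth_samples: tuple[str, ...] = ("fbulk", "sbulk")
    scan: ScanConfig = field(default_factory=ScanConfig)
    call: CallParams = field(default_factory=CallParams)

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(
            thresholds=self.filter_thresholds,
            depth_min=self.depth_min,
            depth_max=self.depth_max,
            depth_samples=tuple(self.depth_samples),
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _coerce(cls, data: dict):
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping for {cls.__name__}, got {type(data).__name__}")
    known = {f.name for f in fields(cls)}
    for key in data:
        if key not in known:
            raise ConfigError(f"unknown config key {key!r} in {cls.__name__}")
    # rebuild nested dataclasses and tuple-typed fields from YAML lists
    obj = cls()
    for key, value in data.items():
        current = getattr(obj, key)
        if is_dataclass(current) and isinstance(value, dict):
            value = _coerce(type(current), value)
        elif isinstance(current, tuple) and isinstance(value, list):
            value = tuple(value)
        setattr(obj, key, value)
    return obj


def validate_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Load, default-fill, and range-check a run config.

    An empty (or absent) file yields the full-default config.  Out-of-range
    values raise ConfigError with a message naming the offending key.
    """
    if data is None:
        if path is None:
            data = {}
        else:
            path = Path(path)
            if not path.exists():
                raise ConfigError(f"config file not found: {path}")
            try:
                data = yaml.safe_load(path.read_text()) or {}
            except yaml.YAMLError as exc:
                raise ConfigError(f"config is not valid YAML: {exc}") from exc
    try:
        cfg = _coerce(RunConfig, data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc

    try:
        # ScanConfig validates in __post_init__ only when constructed fresh
        ScanConfig(**asdict(cfg.scan))
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"scan: {exc}") from exc
    if cfg.sim.bulk_size < 1:
        raise ConfigError("sim.bulk_size must be >= 1")
    if cfg.sim.pop_size < 2 * cfg.sim.bulk_size:
        raise ConfigError("sim.pop_size must be at least twice the bulk size")
    if not 0 < cfg.depth_min <= cfg.depth_max:
        raise ConfigError("need 0 < depth_min <= depth_max")
    if cfg.call.min_run < 1:
        raise ConfigError("call.min_run must be >= 1")
    if cfg.call.min_methods < 1:
        raise ConfigError("call.min_methods must be >= 1")
    if not cfg.simulate and not cfg.vcf:
        raise ConfigError("either simulate: true or a vcf path is required")
    return cfg


def write_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_listify(cfg.to_dict()), sort_keys=False))


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj
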