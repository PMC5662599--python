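"""Pipeline configuration: YAML/JSON parsing, defaulting and validation.

A config names exactly one input source — a block of file paths or a
synthetic-generation block — plus optional per-stage parameter blocks.
Unknown keys are rejected so typos fail loudly at validation time.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .ratio import RatioConfig
from .synthetic import SyntheticCellParams


class ConfigError(ValueError):
    """A named configuration validation failure."""


@dataclass
class InputPaths:
    movie_tiff: str
    trajectories_csv: str | None = None
    masks_tiff: str | None = None


@dataclass
class PolarityBlock:
    axis_source: str = "from_migration"   # or "annotated"
    lookahead: int = 1
    annotated_direction: float | None = None  # degrees, for axis_source=annotated
    region_a: list[int] | None = None     # [row0, row1, col0, col1] box
    region_b: list[int] | None = None


@dataclass
class ProtrusionBlock:
    body_opening_radius: float = 3.0   # µm
    min_length: float = 4.5            # µm, strict threshold
    bin_width: float = 20.0            # degrees
    lookahead: int = 1


@dataclass
class MotilityBlock:
    group_label: str = "default"


@dataclass
class PipelineConfig:
    output_dir: str = "runs"
    rng_seed: int = 0
    log_level: str = "INFO"
    input: InputPaths | None = None
    synthetic: SyntheticCellParams | None = None
    ratio: RatioConfig = field(default_factory=RatioConfig)
    polarity: PolarityBlock = field(default_factory=PolarityBlock)
    protrusion: ProtrusionBlock = field(default_factory=ProtrusionBlock)
    motility: MotilityBlock = field(default_factory=MotilityBlock)

    def __post_init__(self) -> None:
        if (self.input is None) == (self.synthetic is None):
            raise ConfigError(
                "exactly one of 'input' and 'synthetic' must be present")
        if self.polarity.axis_source not in ("from_migration", "annotated"):
            raise ConfigError("polarity.axis_source must be "
                              "'from_migration' or 'annotated'")
        if self.polarity.axis_source == "annotated" and \
                self.polarity.annotated_direction is None:
            raise ConfigError("annotated axis_source needs "
                              "polarity.annotated_direction")


def _build(cls, block: dict, where: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(block, dict):
        raise ConfigError(f"{where} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    coerced = dict(block)
    if "image_shape" in coerced and coerced["image_shape"] is not None:
        coerced["image_shape"] = tuple(coerced["image_shape"])
    try:
        return cls(**coerced)
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


_BLOCKS = {
    "input": InputPaths,
    "synthetic": SyntheticCellParams,
    "ratio": RatioConfig,
    "polarity": PolarityBlock,
    "protrusion": ProtrusionBlock,
    "motility": MotilityBlock,
}
_SCALARS = {"output_dir", "rng_seed", "log_level"}


def parse_config(data: dict) -> PipelineConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - set(_BLOCKS) - _SCALARS
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs: dict = {k: data[k] for k in _SCALARS if k in data}
    for key, cls in _BLOCKS.items():
        if key in data and data[key] is not None:
            kwargs[key] = _build(cls, data[key], key)
    return PipelineConfig(**kwargs)


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML or JSON pipeline config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    config = parse_config(data)
    if config.input is not None:
        for name in ("movie_tiff", "trajectories_csv", "masks_tiff"):
            value = getattr(config.input, name)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"input.{name} does not exist: {value}")
    return config
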