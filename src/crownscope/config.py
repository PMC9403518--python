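"""Run configuration: defaults, strict YAML loading, seed fan-out.

Every field defaults to the reference protocol's setting (256 px tiles,
learning rate 0.001, 100 epochs, batch size 4, early-stop patience 10,
50% IoU acceptance threshold).  Unknown or mistyped YAML keys are rejected
rather than silently ignored, so a typo like ``learning_rte`` cannot
quietly fall back to a default.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .raster_prep import BandCombination
from .resunet import ModelConfig


@dataclass
class RunConfig:
    combo: str = "RGB-CHM"
    tile_size: int = 256
    min_window: int = 20
    mean_window: int = 5
    max_height: float = 5.0
    augment: bool = True
    base_width: int = 64
    encoder_depth: int = 4
    blocks_per_stage: int = 1
    learning_rate: float = 0.001
    max_epochs: int = 100
    batch_size: int = 4
    patience: int = 10
    val_fraction: float = 0.2
    threshold: float = 0.5
    iou_threshold: float = 50.0
    min_crown_pixels: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        # resolves the combination (validating the name) and its layer count
        self.combo = BandCombination.from_name(self.combo).name

    @property
    def band_combination(self) -> BandCombination:
        return BandCombination.from_name(self.combo)

    @property
    def layers(self) -> int:
        return self.band_combination.layers

    def model_config(self, in_layers: int | None = None) -> ModelConfig:
        return ModelConfig(
            in_layers=self.layers if in_layers is None else in_layers,
            base_width=self.base_width,
            encoder_depth=self.encoder_depth,
            blocks_per_stage=self.blocks_per_stage,
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            batch_size=self.batch_size,
            patience=self.patience,
            val_fraction=self.val_fraction,
            seed=self.stage_seed("train"),
        )

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the run seed."""
        return (int(self.seed) * 1_000_003 + zlib.crc32(stage.encode())) % 2**31

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def load_config(path_or_mapping) -> RunConfig:
    """Build a :class:`RunConfig` from YAML, rejecting unknown/mistyped keys."""
    if isinstance(path_or_mapping, (str, Path)):
        raw = yaml.safe_load(Path(path_or_mapping).read_text())
    else:
        raw = path_or_mapping
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config must be a mapping, got {type(raw).__name__}")
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - set(fields))
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {unknown}")
    coerced = {}
    for key, value in raw.items():
        ftype = fields[key].type
        try:
            coerced[key] = _coerce(value, ftype, key)
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"config key {key!r}: {exc}") from exc
    return RunConfig(**coerced)


def _coerce(value, ftype: str, key: str):
    ftype = ftype if isinstance(ftype, str) else getattr(ftype, "__name__", str(ftype))
    if ftype == "bool":
        if not isinstance(value, bool):
            raise TypeError(f"expected bool, got {value!r}")
        return value
    if ftype == "int":
        if isinstance(value, bool) or not isinstance(value, int):
            raise TypeError(f"expected int, got {value!r}")
        return value
    if ftype == "float":
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise TypeError(f"expected number, got {value!r}")
        return float(value)
    if ftype == "str":
        if not isinstance(value, str):
            raise TypeError(f"expected string, got {value!r}")
        return value
    return value
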