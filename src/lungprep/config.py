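"""Run configuration: defaults, YAML loading, and flag overrides.

Precedence is flags > config file > defaults.  Unknown keys are rejected by
name so typos never silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ValidationError
from .mask_qc import QCConfig
from .roi_filters import FilterConfig

logger = logging.getLogger(__name__)

_OUTPUT_FORMATS = {"png", "tif", "tiff"}


@dataclass
class PipelineConfig:
    normalization: bool = True
    contrast_low_pct: float = 1.0
    contrast_high_pct: float = 99.0
    otsu_bins: int = 256
    se_size: int = 5
    morph_iterations: int = 3
    small_object_frac: float = 0.001
    filters: FilterConfig = field(default_factory=FilterConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    output_format: str = "png"
    log_level: str = "INFO"
    seed: int = 0

    def validate(self) -> None:
        if self.se_size < 1 or self.se_size % 2 == 0:
            raise ValidationError(f"se_size must be odd and >= 1, got {self.se_size}")
        if self.morph_iterations < 1:
            raise ValidationError("morph_iterations must be >= 1")
        if not (0.0 <= self.contrast_low_pct < self.contrast_high_pct <= 100.0):
            raise ValidationError("need 0 <= contrast_low_pct < contrast_high_pct <= 100")
        if self.otsu_bins < 2:
            raise ValidationError("otsu_bins must be >= 2")
        if not (0.0 <= self.small_object_frac < 1.0):
            raise ValidationError("small_object_frac must be in [0, 1)")
        if self.output_format not in _OUTPUT_FORMATS:
            raise ValidationError(
                f"output_format must be one of {sorted(_OUTPUT_FORMATS)}"
            )
        self.filters.validate()
        self.qc.validate()


_TOP_FIELDS = {f.name: f for f in dataclasses.fields(PipelineConfig)}
_FILTER_FIELDS = {f.name for f in dataclasses.fields(FilterConfig)}
_QC_FIELDS = {f.name for f in dataclasses.fields(QCConfig)}


def _apply(cfg: PipelineConfig, data: dict[str, Any], source: str) -> None:
    unknown: list[str] = []
    for key, value in data.items():
        if value is None:
            continue
        if key == "filters" and isinstance(value, dict):
            for k, v in value.items():
                if k not in _FILTER_FIELDS:
                    unknown.append(f"filters.{k}")
                elif v is not None:
                    setattr(cfg.filters, k, v)
        elif key == "qc" and isinstance(value, dict):
            for k, v in value.items():
                if k not in _QC_FIELDS:
                    unknown.append(f"qc.{k}")
                elif v is not None:
                    setattr(cfg.qc, k, tuple(v) if k == "weights" else v)
        elif key in _TOP_FIELDS and key not in ("filters", "qc"):
            setattr(cfg, key, value)
        elif key in _FILTER_FIELDS:
            setattr(cfg.filters, key, value)
        elif key in _QC_FIELDS:
            setattr(cfg.qc, key, tuple(value) if key == "weights" else value)
        else:
            unknown.append(key)
    if unknown:
        raise ValidationError(f"unknown {source} keys: {', '.join(sorted(unknown))}")


def load_config(
    path: str | Path | None = None, overrides: dict[str, Any] | None = None
) -> PipelineConfig:
    """Build the effective config: defaults <- YAML file <- flag overrides."""
    cfg = PipelineConfig()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        _apply(cfg, data, f"config-file ({path})")
    if overrides:
        _apply(cfg, overrides, "override")
    cfg.validate()
    logger.info("effective config: %s", config_to_dict(cfg))
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict[str, Any]:
    d = dataclasses.asdict(cfg)
    d["qc"]["weights"] = list(d["qc"]["weights"])
    return d


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write the resolved config next to run outputs for provenance."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
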