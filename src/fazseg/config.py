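"""Pipeline configuration: defaults, YAML loading, validation.

All tunable knobs of the pipeline live here, grouped by stage.  Radii
given as ``None`` are resolved from the image width at run time so the
same configuration transfers between rasters of different resolution.
Unknown keys in a YAML file are rejected rather than ignored, and the
full resolved configuration is embedded in every report.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class TophatConfig:
    #: disc radius in px; None -> round(width/32)
    selem_radius: int | None = None


@dataclass(frozen=True)
class CannyConfig:
    sigma: float = 1.0
    low_frac: float = 0.66
    high_frac: float = 1.33


@dataclass(frozen=True)
class MorphConfig:
    #: closure disc radius in px; None -> round(width/64)
    close_radius: int | None = None
    #: opening disc radius in px; None -> round(width/53)
    open_radius: int | None = None


@dataclass(frozen=True)
class FpConfig:
    border_margin_frac: float = 0.05
    max_center_offset_frac: float = 0.8
    min_solidity: float = 0.3


@dataclass(frozen=True)
class GrowConfig:
    tolerance_frac: float = 0.3
    seed_erosion_radius: int = 3
    max_iterations: int = 100
    #: floor on the acceptance half-width, as a fraction of the mean
    #: intensity of the enhanced image; guards against the degeneracy of
    #: the multiplicative interval when the region average tends to zero
    abs_floor_frac: float = 0.18


_SECTIONS = {
    "tophat": TophatConfig,
    "canny": CannyConfig,
    "morph": MorphConfig,
    "fp": FpConfig,
    "grow": GrowConfig,
}


@dataclass(frozen=True)
class PipelineConfig:
    """Full parameter set of the segmentation pipeline."""

    tophat: TophatConfig = field(default_factory=TophatConfig)
    canny: CannyConfig = field(default_factory=CannyConfig)
    morph: MorphConfig = field(default_factory=MorphConfig)
    fp: FpConfig = field(default_factory=FpConfig)
    grow: GrowConfig = field(default_factory=GrowConfig)

    def __post_init__(self) -> None:
        c = self.canny
        if not (c.sigma > 0 and 0 < c.low_frac < c.high_frac):
            raise ParameterError("canny: need sigma > 0 and 0 < low_frac < high_frac")
        f = self.fp
        if not (0 <= f.border_margin_frac < 0.5 and 0 < f.max_center_offset_frac <= 1
                and 0 <= f.min_solidity <= 1):
            raise ParameterError("fp: threshold out of range")
        g = self.grow
        if not (0 < g.tolerance_frac < 1 and g.seed_erosion_radius >= 1
                and g.max_iterations >= 1 and g.abs_floor_frac >= 0):
            raise ParameterError("grow: parameter out of range")
        for name in ("tophat.selem_radius", "morph.close_radius", "morph.open_radius"):
            sec, key = name.split(".")
            v = getattr(getattr(self, sec), key)
            if v is not None and v < 1:
                raise ParameterError(f"{name} must be >= 1")

    def resolved(self, width: int) -> "PipelineConfig":
        """Return a copy with all width-relative radii made concrete."""
        return dataclasses.replace(
            self,
            tophat=TophatConfig(self.tophat.selem_radius or max(1, round(width / 32))),
            morph=MorphConfig(
                self.morph.close_radius or max(1, round(width / 64)),
                self.morph.open_radius or max(1, round(width / 53)),
            ),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - set(_SECTIONS)
        if unknown:
            raise ParameterError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for sec, typ in _SECTIONS.items():
            if sec not in data:
                continue
            body = data[sec] or {}
            valid = {f.name for f in dataclasses.fields(typ)}
            bad = set(body) - valid
            if bad:
                raise ParameterError(f"unknown keys in [{sec}]: {sorted(bad)}")
            kwargs[sec] = typ(**body)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ParameterError("config file must contain a mapping")
        return cls.from_dict(data)
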