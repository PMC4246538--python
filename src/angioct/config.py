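"""JSON pipeline configuration with strict validation.

Unknown keys are rejected at load time, and every numeric field is
validated by the owning parameter dataclass, so a typo fails fast
instead of silently running with defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .phantom import CTSimParams, TreeParams
from .segmentation import MSParams

__all__ = ["VOIConfig", "SegmentationConfig", "PipelineConfig", "load_config"]


@dataclass
class VOIConfig:
    tibia_seeds: list[list[int]] = field(default_factory=list)
    femur_seeds: list[list[int]] = field(default_factory=list)
    closing_radius: int = 30
    capsule_scale: float = 2.5
    band_width_voxels: float = 10.0
    coarse_high_fraction: float = 0.6
    n_shells: int = 4

    def __post_init__(self) -> None:
        if self.closing_radius < 0:
            raise ValueError("closing_radius must be >= 0")
        if self.capsule_scale <= 0:
            raise ValueError("capsule_scale must be positive")
        if not 0 < self.coarse_high_fraction < 1:
            raise ValueError("coarse_high_fraction must be in (0, 1)")
        if self.n_shells < 1:
            raise ValueError("n_shells must be >= 1")


@dataclass
class SegmentationConfig:
    method: str = "mslat"
    alpha: float = 1.0
    gt_threshold: float | None = None
    ms: MSParams = field(default_factory=MSParams)
    add_mask: str | None = None  # optional manual-correction mask paths
    remove_mask: str | None = None

    def __post_init__(self) -> None:
        if self.method not in ("gt", "lat", "ms", "mslat"):
            raise ValueError(f"unknown segmentation method '{self.method}'")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass
class PipelineConfig:
    image: str = ""
    voxel_size: float | None = None  # μm; required only for TIFF input
    out_dir: str = "angioct_out"
    seed: int = 0
    voi: VOIConfig = field(default_factory=VOIConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    bin_width_um: float = 15.0
    tree: TreeParams | None = None  # only used by `simulate`
    ct: CTSimParams | None = None


def _from_dict(cls, data: dict):
    if not isinstance(data, dict):
        raise ValueError(f"expected an object for {cls.__name__}, got {type(data).__name__}")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown key(s) for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = names[key].type
        if key == "voi":
            value = _from_dict(VOIConfig, value)
        elif key == "segmentation":
            value = _from_dict(SegmentationConfig, value)
        elif key == "ms":
            value = _from_dict(MSParams, value)
        elif key == "tree" and value is not None:
            value = _from_dict(TreeParams, value)
        elif key == "ct" and value is not None:
            value = _from_dict(CTSimParams, value)
        if isinstance(value, list) and key in ("domain_shape", "curving_angle_range",
                                               "branching_angle_range", "area_split_range",
                                               "scales"):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a pipeline configuration from JSON."""
    data = json.loads(Path(path).read_text())
    return _from_dict(PipelineConfig, data)


def config_to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)
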