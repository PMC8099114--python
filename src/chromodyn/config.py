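"""Validated run configuration shared by the CLI subcommands.

A single YAML file holds one section per subcommand plus a global seed; CLI
flags override file values. The schema is validated with pydantic so that a
malformed file fails with a diagnostic naming the offending key. The
defaults encode the pipeline's fixed analysis constants: CI intensity
threshold 0.25, 3D threshold 0.1, isotropic target spacing 0.368 um,
100x100 px ROIs, and the 30-60 s baseline window of the freezing scorer.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["RunConfig", "load_config"]


class GroupSection(BaseModel):
    n_cells: int = Field(gt=0)
    fraction_dynamic: float = Field(default=0.0, ge=0.0, le=1.0)
    dynamic_models: list[str] = ["isotropic_diffusion"]
    rate: float = Field(default=0.2, ge=0.0)


class SimulateSection(BaseModel):
    groups: dict[str, GroupSection] = {
        "control": GroupSection(n_cells=10, fraction_dynamic=0.1),
        "cocktail": GroupSection(n_cells=10, fraction_dynamic=0.7),
    }
    times: list[float] = [-60.0, 0.0, 60.0, 120.0]
    treatment_time: float = 0.0
    frame: list[int] = [5, 48, 48]
    voxel_size: list[float] = [1.0, 0.215, 0.215]
    line_width: float = 1.5

    @field_validator("times")
    @classmethod
    def _times_increasing(cls, v):
        if any(b <= a for a, b in zip(v[:-1], v[1:])):
            raise ValueError("times must be strictly increasing")
        return v


class GISection(BaseModel):
    roi_size: list[int] = [100, 100]


class CISection(BaseModel):
    threshold: float = Field(default=0.25, gt=0.0, lt=1.0)
    background_method: str = "percentile"
    background_percentile: float = Field(default=5.0, ge=0.0, lt=100.0)
    scheme: str = "slice_scheme"
    roi_size: list[int] = [100, 100]


class Eigen3DSection(BaseModel):
    threshold: float = Field(default=0.1, gt=0.0, lt=1.0)
    target_spacing_um: float = Field(default=0.368, gt=0.0)


class PipelineSection(BaseModel):
    metric: str = "ci"
    t_pre: float | None = None
    t_post: float | None = None
    scheme: str = "slice_scheme"


class FreezeSection(BaseModel):
    pixel_delta_threshold: float = Field(default=25.0, ge=0.0)
    motion_count_threshold: int = Field(default=50, ge=0)
    min_bout_s: float = Field(default=1.0, gt=0.0)
    baseline_s: list[float] = [30.0, 60.0]


class RunConfig(BaseModel):
    """Full resolved configuration; round-trips losslessly through YAML."""

    seed: int = 0
    simulate: SimulateSection = SimulateSection()
    gi: GISection = GISection()
    ci: CISection = CISection()
    eigen3d: Eigen3DSection = Eigen3DSection()
    pipeline: PipelineSection = PipelineSection()
    freeze: FreezeSection = FreezeSection()

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; None gives the defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)
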