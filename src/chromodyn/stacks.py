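"""Image containers and TIFF I/O.

Conventions used throughout the package: arrays are indexed ``(z, y, x)``
(2D images ``(y, x)``), 0-based, with pixel centers at integer coordinates.
Physical sizes are in micrometres, times in minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "Image2D", "read_stack", "write_stack"]


@dataclass(frozen=True)
class ImageStack:
    """A 3D fluorescence intensity grid for one nucleus at one time point.

    Parameters
    ----------
    voxels
        Non-negative float array of shape ``(z, y, x)``.
    voxel_size
        Physical voxel edge lengths ``(z, y, x)`` in micrometres.
    time
        Acquisition time in minutes (relative to the experiment's reference
        point, e.g. treatment onset).
    channel
        ``"pan"`` for pan-nucleosome labels (H2B::mCherry-like) or
        ``"photolabel"`` for photoactivated fiducials (H2B::PaGFP-like).
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    time: float = 0.0
    channel: str = "pan"
    padded: bool = False

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3:
            raise ValueError(f"voxels must be 3D (z, y, x), got ndim={vox.ndim}")
        if vox.shape[0] < 1:
            raise ValueError("stack needs at least one z-plane")
        if np.any(vox < 0):
            raise ValueError("intensities must be non-negative")
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size must be three strictly positive lengths")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "voxel_size", tuple(float(s) for s in self.voxel_size))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def with_voxels(self, voxels: np.ndarray, voxel_size=None) -> "ImageStack":
        return replace(
            self,
            voxels=voxels,
            voxel_size=self.voxel_size if voxel_size is None else voxel_size,
        )


@dataclass(frozen=True)
class Image2D:
    """A single 2D image derived from a stack (brightest section or MIP)."""

    pixels: np.ndarray
    pixel_size: float = 1.0
    provenance: str = "unknown"
    padded: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2D (y, x), got ndim={px.ndim}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, **kw) -> "Image2D":
        return replace(self, pixels=pixels, **kw)


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as a multi-page TIFF with a JSON sidecar of metadata.

    The sidecar (``<path>.json``) records voxel size, time and channel so that
    stacks round-trip losslessly even though plain TIFF tags cannot hold them.
    """
    path = Path(path)
    tifffile.imwrite(path, stack.voxels.astype(np.float32))
    meta = {
        "voxel_size_zyx_um": list(stack.voxel_size),
        "time_min": stack.time,
        "channel": stack.channel,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float] | None = None,
    time: float | None = None,
    channel: str | None = None,
) -> ImageStack:
    """Read a multi-page TIFF; explicit arguments override sidecar metadata."""
    path = Path(path)
    voxels = np.asarray(tifffile.imread(path), dtype=float)
    if voxels.ndim == 2:
        voxels = voxels[None]
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return ImageStack(
        voxels=voxels,
        voxel_size=tuple(voxel_size or meta.get("voxel_size_zyx_um", (1.0, 1.0, 1.0))),
        time=time if time is not None else float(meta.get("time_min", 0.0)),
        channel=channel or meta.get("channel", "pan"),
    )
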