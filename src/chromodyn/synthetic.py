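"""Synthetic nuclei, photolabel fiducials and behavior videos with ground truth.

This module emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised against known truth:

* pan-nucleosome channel images whose in-nucleus texture ranges from a
  homogeneous fill to a clumped, granular field of bright foci;
* thin photolabeled line fiducials inside elliptical nuclei that evolve by
  rigid rotation, isotropic diffusion with boundary reflection, or a
  deterministic directed flow;
* rendering through an anisotropic Gaussian point-spread function with shot
  (Poisson) and read (Gaussian) noise;
* whole cohorts of cells split into treatment groups with differing
  fractions of dynamic nuclei;
* behavior videos with scheduled motion and no-motion epochs.

All generators are pure functions of their configuration and seed.
Label evolution operates on "quanta": each labeled pixel is split into
sub-pixel point masses that are transformed exactly and re-deposited onto
the grid bilinearly, so total label mass is conserved up to boundary
clipping and rigid rotations compose exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .freezing import BehaviorVideo
from .stacks import ImageStack

__all__ = [
    "NucleusGeometry",
    "DynamicsParams",
    "RenderParams",
    "CohortGroup",
    "CohortConfig",
    "CellTruth",
    "CohortTruth",
    "Cohort",
    "make_pan_nucleus",
    "make_line_label",
    "evolve_label",
    "simulate_cohort",
    "simulate_behavior_video",
]

DYNAMICS_MODELS = ("stable", "rigid_rotation", "isotropic_diffusion", "directed_flow")


@dataclass(frozen=True)
class NucleusGeometry:
    """An elliptical (2D) nucleus footprint in pixel coordinates.

    ``center`` and ``semi_axes`` are (y, x) in pixels; ``orientation`` is the
    in-plane rotation of the major axis in radians. The axial (z) extent of
    the rendered nucleus is derived from the minor semi-axis and the voxel
    anisotropy at render time.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if len(self.center) != 2 or len(self.semi_axes) != 2:
            raise ValueError("center and semi_axes must be 2D (y, x)")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi_axes must be strictly positive")

    def contains(self, yx: np.ndarray) -> np.ndarray:
        """Boolean membership test for points of shape (..., 2)."""
        u = self._to_unit(np.asarray(yx, dtype=float))
        return (u**2).sum(axis=-1) <= 1.0

    def _to_unit(self, yx: np.ndarray) -> np.ndarray:
        d = yx - np.asarray(self.center)
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        # rotate into the ellipse frame, then scale axes to the unit circle
        rot = np.array([[c, -s], [s, c]])
        return (d @ rot.T) / np.asarray(self.semi_axes)

    def _from_unit(self, u: np.ndarray) -> np.ndarray:
        c, s = np.cos(self.orientation), np.sin(self.orientation)
        rot = np.array([[c, s], [-s, c]])
        return (u * np.asarray(self.semi_axes)) @ rot.T + np.asarray(self.center)


@dataclass(frozen=True)
class DynamicsParams:
    """How a photolabel evolves over time.

    ``rate`` is per-minute: radians/min for ``rigid_rotation``, a diffusion
    coefficient in px^2/min for ``isotropic_diffusion``, and a drift speed in
    px/min (at the reference radius) for ``directed_flow``. ``axis`` selects
    the rotation axis for 3D masks ("z", "y" or "x"); 2D masks always rotate
    in-plane.
    """

    model: str = "stable"
    rate: float = 0.0
    seed: int = 0
    axis: str = "z"

    def __post_init__(self) -> None:
        if self.model not in DYNAMICS_MODELS:
            raise ValueError(
                f"unknown dynamics model {self.model!r}; expected one of {DYNAMICS_MODELS}"
            )
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.axis not in ("z", "y", "x"):
            raise ValueError("axis must be 'z', 'y' or 'x'")


@dataclass(frozen=True)
class RenderParams:
    """Optics and camera model for rendering stacks.

    The PSF is an anisotropic Gaussian; two-photon PSFs are submicron
    laterally but extend to roughly 2 um axially, so the physical axial
    width must be at least the lateral one. Shot noise is Poisson at
    ``poisson_peak`` expected photons for unit intensity (None disables it);
    read noise is additive Gaussian with ``gaussian_sd`` (intensity units).
    """

    shape: tuple[int, int, int] = (7, 64, 64)
    voxel_size: tuple[float, float, float] = (1.0, 0.215, 0.215)  # um (z, y, x)
    psf_sigma_xy: float = 1.0  # pixels
    psf_sigma_z: float = 0.9  # voxels
    background: float = 0.02
    poisson_peak: float | None = 200.0
    gaussian_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma_xy < 0 or self.psf_sigma_z < 0:
            raise ValueError("PSF widths must be >= 0")
        if any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.psf_sigma_z * self.voxel_size[0] < self.psf_sigma_xy * self.voxel_size[2] - 1e-9:
            raise ValueError("axial PSF extent must be >= lateral extent (physical units)")


def _check_geometry_in_frame(geometry: NucleusGeometry, render: RenderParams) -> None:
    margin = 3.0 * render.psf_sigma_xy
    a = max(geometry.semi_axes)
    cy, cx = geometry.center
    H, W = render.shape[1], render.shape[2]
    if cy - a - margin < 0 or cx - a - margin < 0 or cy + a + margin > H - 1 or cx + a + margin > W - 1:
        raise ValueError("nucleus (plus rendering margin) does not fit inside the frame")


def _ellipsoid_profile(geometry: NucleusGeometry, render: RenderParams) -> np.ndarray:
    """Per-plane relative cross-section scale of the nucleus ellipsoid.

    The axial semi-axis equals the minor in-plane semi-axis converted to
    voxels via the voxel anisotropy, centred on the middle plane.
    """
    nz = render.shape[0]
    semi_z = min(geometry.semi_axes) * render.voxel_size[2] / render.voxel_size[0]
    z = np.arange(nz, dtype=float) - (nz - 1) / 2.0
    frac = 1.0 - (z / max(semi_z, 0.5)) ** 2
    return np.sqrt(np.clip(frac, 0.0, None))


def _ellipse_mask(geometry: NucleusGeometry, shape_yx: tuple[int, int], scale: float = 1.0) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape_yx[0], 0 : shape_yx[1]]
    pts = np.stack([yy, xx], axis=-1).astype(float)
    u = geometry._to_unit(pts.reshape(-1, 2)).reshape(shape_yx + (2,))
    return (u**2).sum(axis=-1) <= scale**2


def _apply_optics_and_noise(ideal: np.ndarray, render: RenderParams, rng: np.random.Generator) -> np.ndarray:
    img = ideal
    if render.psf_sigma_xy > 0 or render.psf_sigma_z > 0:
        img = ndimage.gaussian_filter(
            img, sigma=(render.psf_sigma_z, render.psf_sigma_xy, render.psf_sigma_xy)
        )
    img = img + render.background
    if render.poisson_peak:
        img = rng.poisson(np.clip(img, 0, None) * render.poisson_peak) / render.poisson_peak
    if render.gaussian_sd > 0:
        img = img + rng.normal(0.0, render.gaussian_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def make_pan_nucleus(
    geometry: NucleusGeometry,
    granularity: float,
    render: RenderParams,
    time: float = 0.0,
) -> ImageStack:
    """Render a pan-nucleosome channel stack with controllable granularity.

    ``granularity`` interpolates between a homogeneous chromatin fill (0)
    and a maximally clumped field of Gaussian foci of 3-8 px diameter (1):
    the in-nucleus intensity is ``(1 - g) + g * B`` where ``B`` is a random
    blob field normalized to unit in-nucleus mean. Spatial clumpiness (and
    hence the Granularity Index) increases monotonically with ``g``.
    """
    if not (0.0 <= granularity <= 1.0):
        raise ValueError("granularity must lie in [0, 1]")
    _check_geometry_in_frame(geometry, render)
    rng = np.random.default_rng(render.seed)
    nz, H, W = render.shape
    mask = _ellipse_mask(geometry, (H, W))
    if granularity > 0:
        area = np.pi * geometry.semi_axes[0] * geometry.semi_axes[1]
        n_blobs = max(3, int(round(0.03 * area)))
        u = rng.normal(size=(n_blobs, 2))
        r = np.sqrt(rng.uniform(size=n_blobs))  # uniform over the ellipse
        centers = geometry._from_unit(u / np.linalg.norm(u, axis=1, keepdims=True) * r[:, None])
        sigmas = rng.uniform(1.3, 3.4, size=n_blobs)  # FWHM ~ 3-8 px
        yy, xx = np.mgrid[0:H, 0:W].astype(float)
        blob = np.zeros((H, W))
        for (cy, cx), s in zip(centers, sigmas):
            blob += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2))
        mean_in = blob[mask].mean()
        if mean_in <= 0:
            blob_norm = np.ones((H, W))
        else:
            blob_norm = blob / mean_in
        texture = (1.0 - granularity) + granularity * blob_norm
    else:
        texture = np.ones((H, W))
    plane = np.where(mask, texture, 0.0)
    profile = _ellipsoid_profile(geometry, render)
    ideal = profile[:, None, None] * plane[None, :, :]
    voxels = _apply_optics_and_noise(ideal, render, rng)
    return ImageStack(voxels=voxels, voxel_size=render.voxel_size, time=time, channel="pan")


def make_line_label(
    geometry: NucleusGeometry,
    line_width: float,
    orientation: float,
    render: RenderParams,
    time: float = 0.0,
    amplitude: float = 1.0,
) -> tuple[np.ndarray, ImageStack]:
    """Photolabel a thin line across a nucleus and render it.

    The line passes through the nucleus centre at the given orientation,
    clipped to the ellipse interior, and lives on a single focal plane (the
    middle z-plane); the PSF then extends it axially. Returns the
    ground-truth 2D mask (float in [0, 1]) and the rendered stack.
    """
    if line_width < 1:
        raise ValueError("line_width must be >= 1 px")
    _check_geometry_in_frame(geometry, render)
    rng = np.random.default_rng(render.seed)
    nz, H, W = render.shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    cy, cx = geometry.center
    # perpendicular distance to the infinite line through the centre
    ny, nx = np.cos(orientation), -np.sin(orientation)  # unit normal
    dist = np.abs((yy - cy) * ny + (xx - cx) * nx)
    inside = _ellipse_mask(geometry, (H, W))
    mask = ((dist <= line_width / 2.0) & inside).astype(float)
    ideal = np.zeros((nz, H, W))
    ideal[nz // 2] = amplitude * mask
    voxels = _apply_optics_and_noise(ideal, render, rng)
    return mask, ImageStack(
        voxels=voxels, voxel_size=render.voxel_size, time=time, channel="photolabel"
    )


# ---------------------------------------------------------------------------
# label evolution on quanta


def _mask_to_quanta(mask: np.ndarray, oversample: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Split each labeled pixel into ``oversample**d`` equal point masses."""
    coords = np.argwhere(mask > 0).astype(float)
    weights = mask[mask > 0].astype(float)
    d = mask.ndim
    offs = (np.arange(oversample) + 0.5) / oversample - 0.5
    grids = np.meshgrid(*([offs] * d), indexing="ij")
    sub = np.stack([g.ravel() for g in grids], axis=-1)  # (k, d)
    pts = (coords[:, None, :] + sub[None, :, :]).reshape(-1, d)
    w = np.repeat(weights / sub.shape[0], sub.shape[0])
    return pts, w


def _deposit(pts: np.ndarray, w: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Bilinear (cloud-in-cell) deposition of point masses onto a grid."""
    d = pts.shape[1]
    base = np.floor(pts).astype(int)
    frac = pts - base
    out = np.zeros(shape)
    for corner in range(2**d):
        bits = [(corner >> k) & 1 for k in range(d)]
        idx = base + np.array(bits)
        weight = w.copy()
        for k, b in enumerate(bits):
            weight = weight * (frac[:, k] if b else 1.0 - frac[:, k])
        ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
        np.add.at(out, tuple(idx[ok].T), weight[ok])
    return out


def _rotation_matrix(d: int, angle: float, axis: str) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    if d == 2:
        return np.array([[c, -s], [s, c]])
    # 3D, axes ordered (z, y, x)
    plane = {"z": (1, 2), "x": (0, 1), "y": (0, 2)}[axis]
    rot = np.eye(3)
    i, j = plane
    rot[i, i], rot[i, j], rot[j, i], rot[j, j] = c, -s, s, c
    return rot


def _reflect_into_ellipse(pts: np.ndarray, geometry: NucleusGeometry) -> np.ndarray:
    """Radially reflect 2D points at the ellipse boundary (in unit coords)."""
    u = geometry._to_unit(pts)
    r = np.linalg.norm(u, axis=1)
    out = r > 1.0
    if np.any(out):
        # mirror the overshoot back inside; clip pathological overshoots
        r_new = np.clip(2.0 - r[out], 0.0, 1.0)
        u[out] = u[out] / r[out, None] * r_new[:, None]
    return geometry._from_unit(u)


def evolve_label(
    label_mask: np.ndarray,
    dynamics: DynamicsParams,
    dt: float,
    geometry: NucleusGeometry | None = None,
    rng: np.random.Generator | None = None,
    oversample: int = 2,
) -> np.ndarray:
    """Advance a label mask by ``dt`` minutes under the given dynamics.

    The mask (2D or 3D, float) is decomposed into sub-pixel quanta which are
    transformed and re-deposited bilinearly:

    * ``stable`` — returned unchanged;
    * ``rigid_rotation`` — exact rotation by ``rate*dt`` about the
      brightness-weighted centroid (so rotations compose exactly);
    * ``isotropic_diffusion`` — per-axis Gaussian steps of variance
      ``2*rate*dt``, reflected at the nucleus ellipse boundary when a
      ``geometry`` is supplied (2D only), else clipped at the frame;
    * ``directed_flow`` — a deterministic swirl-plus-shear displacement
      field of magnitude ``rate*dt`` at the label's RMS radius.

    Total label mass is conserved up to boundary clipping.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    mask = np.asarray(label_mask, dtype=float)
    if dynamics.model == "stable" or dt == 0 or dynamics.rate == 0:
        return mask.copy()
    if not np.any(mask > 0):
        return mask.copy()
    pts, w = _mask_to_quanta(mask, oversample=oversample)
    centroid = (w[:, None] * pts).sum(axis=0) / w.sum()
    d = mask.ndim

    if dynamics.model == "rigid_rotation":
        rot = _rotation_matrix(d, dynamics.rate * dt, dynamics.axis)
        pts = (pts - centroid) @ rot.T + centroid
    elif dynamics.model == "isotropic_diffusion":
        if rng is None:
            rng = np.random.default_rng(dynamics.seed)
        step_sd = np.sqrt(2.0 * dynamics.rate * dt)
        pts = pts + rng.normal(0.0, step_sd, size=pts.shape)
        if geometry is not None and d == 2:
            pts = _reflect_into_ellipse(pts, geometry)
    elif dynamics.model == "directed_flow":
        off = pts - centroid
        r = np.linalg.norm(off, axis=1)
        r_ref = max(np.sqrt(np.average(r**2, weights=w)), 1e-6)
        mag = dynamics.rate * dt
        if d == 2:
            swirl = np.column_stack([-off[:, 1], off[:, 0]]) / r_ref
            shear = np.column_stack([off[:, 1], np.zeros_like(r)]) / r_ref
        else:
            swirl = np.column_stack([np.zeros_like(r), -off[:, 2], off[:, 1]]) / r_ref
            shear = np.column_stack([np.zeros_like(r), off[:, 2], np.zeros_like(r)]) / r_ref
        pts = pts + mag * (0.7 * swirl + 0.3 * shear)
        if geometry is not None and d == 2:
            pts = _reflect_into_ellipse(pts, geometry)
    pts = np.clip(pts, 0.0, np.array(mask.shape, dtype=float) - 1.0)
    return _deposit(pts, w, mask.shape)


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortGroup:
    """One treatment group of a simulated cohort.

    ``fraction_dynamic`` is the probability that a cell starts reorganizing
    its label at the treatment time point; dynamic cells draw their model
    from ``dynamic_models`` (uniformly) with rate ``rate``.
    """

    n_cells: int
    fraction_dynamic: float = 0.0
    dynamic_models: tuple[str, ...] = ("isotropic_diffusion",)
    rate: float = 0.2

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("group must contain at least one cell")
        if not (0.0 <= self.fraction_dynamic <= 1.0):
            raise ValueError("fraction_dynamic must lie in [0, 1]")
        for m in self.dynamic_models:
            if m not in DYNAMICS_MODELS or m == "stable":
                raise ValueError(f"invalid dynamic model {m!r}")


@dataclass(frozen=True)
class CohortConfig:
    groups: dict[str, CohortGroup]
    times: tuple[float, ...] = (-60.0, 0.0, 60.0, 120.0)
    treatment_time: float = 0.0
    line_width: float = 1.5
    render: RenderParams = field(default_factory=RenderParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        t = np.asarray(self.times, dtype=float)
        if t.size < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")


@dataclass(frozen=True)
class CellTruth:
    cell_id: str
    group: str
    geometry: NucleusGeometry
    dynamics: DynamicsParams
    line_orientation: float
    masks: tuple[np.ndarray, ...]  # ground-truth label mask per time point


@dataclass(frozen=True)
class CohortTruth:
    cells: tuple[CellTruth, ...]
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise ValueError("cell_ids must be unique")

    def group_of(self) -> dict[str, str]:
        return {c.cell_id: c.group for c in self.cells}


@dataclass(frozen=True)
class Cohort:
    """Simulated per-cell time-lapse stacks plus their ground truth."""

    stacks: dict[str, list[ImageStack]]
    truth: CohortTruth


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Simulate a multi-group photolabel time-lapse cohort.

    Every cell carries a thin-line photolabel that is stable before the
    treatment time point. From the treatment onward, each cell is dynamic
    with its group's ``fraction_dynamic`` probability, evolving by the drawn
    model; all other cells stay stable throughout (as in control groups
    where label lines persist). Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    nz, H, W = config.render.shape
    cells: list[CellTruth] = []
    stacks: dict[str, list[ImageStack]] = {}
    times = tuple(float(t) for t in config.times)

    for group_name, group in config.groups.items():
        for i in range(group.n_cells):
            cell_id = f"{group_name}_{i:03d}"
            cy = H / 2.0 + rng.uniform(-2, 2)
            cx = W / 2.0 + rng.uniform(-2, 2)
            a = rng.uniform(0.24, 0.30) * min(H, W)
            b = rng.uniform(0.75, 0.95) * a
            geom = NucleusGeometry(center=(cy, cx), semi_axes=(a, b), orientation=rng.uniform(0, np.pi))
            orient = rng.uniform(0, np.pi)
            is_dyn = rng.random() < group.fraction_dynamic
            model = (
                group.dynamic_models[rng.integers(len(group.dynamic_models))]
                if is_dyn
                else "stable"
            )
            dyn = DynamicsParams(
                model=model, rate=group.rate if is_dyn else 0.0, seed=int(rng.integers(2**31))
            )
            render = dataclasses.replace(config.render, seed=int(rng.integers(2**31)))
            mask0, stack0 = make_line_label(
                geom, config.line_width, orient, render, time=times[0]
            )
            masks = [mask0]
            cell_stacks = [stack0]
            evo_rng = np.random.default_rng(dyn.seed)
            for t_prev, t_now in zip(times[:-1], times[1:]):
                active_dt = max(0.0, t_now - max(t_prev, config.treatment_time))
                mask = evolve_label(
                    masks[-1], dyn, active_dt, geometry=geom, rng=evo_rng
                )
                masks.append(mask)
                render_t = dataclasses.replace(
                    config.render, seed=int(rng.integers(2**31))
                )
                ideal = np.zeros((nz, H, W))
                ideal[nz // 2] = mask
                vox = _apply_optics_and_noise(
                    ideal, render_t, np.random.default_rng(render_t.seed)
                )
                cell_stacks.append(
                    ImageStack(
                        voxels=vox,
                        voxel_size=render_t.voxel_size,
                        time=t_now,
                        channel="photolabel",
                    )
                )
            cells.append(
                CellTruth(
                    cell_id=cell_id,
                    group=group_name,
                    geometry=geom,
                    dynamics=dyn,
                    line_orientation=orient,
                    masks=tuple(masks),
                )
            )
            stacks[cell_id] = cell_stacks
    return Cohort(stacks=stacks, truth=CohortTruth(cells=tuple(cells), times=times))


# ---------------------------------------------------------------------------
# behavior videos


def simulate_behavior_video(
    duration_s: float,
    fps: float,
    motion_schedule: list[tuple[float, float, bool]],
    frame_size: tuple[int, int] = (64, 64),
    seed: int = 0,
    noise_sd: float = 1.0,
    periods: list[tuple[str, float, float]] | None = None,
) -> tuple[BehaviorVideo, list[tuple[float, float, bool]]]:
    """Render a grayscale behavior video with known motion epochs.

    ``motion_schedule`` lists non-overlapping ``(start_s, end_s, moving)``
    intervals; time not covered by any interval is still. During moving
    epochs the textured scene translates by ~2 px/frame, changing many
    pixels well above typical frame-difference thresholds; still epochs
    contain only Gaussian sensor noise of ``noise_sd`` grey levels.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    sched = sorted((float(a), float(b), bool(m)) for a, b, m in motion_schedule)
    for (a, b, _m) in sched:
        if not (0 <= a < b <= duration_s):
            raise ValueError("schedule intervals must lie within the video duration")
    for (_, b1, _), (a2, _, _) in zip(sched[:-1], sched[1:]):
        if a2 < b1:
            raise ValueError("schedule intervals must not overlap")

    rng = np.random.default_rng(seed)
    H, W = frame_size
    scene = ndimage.gaussian_filter(rng.uniform(0, 255, size=(H, W)), 1.5)
    scene = 30 + 190 * (scene - scene.min()) / (np.ptp(scene) + 1e-12)

    n_frames = int(round(duration_s * fps))
    frames = np.empty((n_frames, H, W), dtype=np.uint8)
    shift = 0
    for i in range(n_frames):
        t = i / fps
        moving = any(a <= t < b and m for a, b, m in sched)
        if moving and i > 0:
            shift += 2
        frame = np.roll(scene, shift, axis=1)
        frame = frame + rng.normal(0.0, noise_sd, size=(H, W))
        frames[i] = np.clip(frame, 0, 255).astype(np.uint8)
    if periods is None:
        periods = (
            [("baseline", 30.0, 60.0)] if duration_s >= 60 else [("all", 0.0, duration_s)]
        )
    video = BehaviorVideo(frames=frames, fps=fps, event_schedule=tuple(periods))
    return video, sched
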