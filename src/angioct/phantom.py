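"""Digital vascular-tree phantoms and simulated μCT volumes.

A phantom is a random binary tree of curved cylindrical vessel
segments.  Each segment is a polyline of center points with a constant
radius; at a bifurcation the parent's cross-sectional area is conserved
exactly (``π r_p² = π r_c1² + π r_c2²``), so vessel diameter decreases
towards the leaves.  Curving and branching angles are drawn uniformly
from configurable ranges, the minimum radius is one voxel (so the
thinnest vessels have a diameter of two voxels), and all randomness
flows through an explicit seed so that regeneration is bit-identical.

The ground-truth geometry (centerline points + radii) is kept alongside
the voxelized mask, which makes the phantoms usable as an accuracy
oracle for segmentation and thickness measurement.

A simulated CT acquisition degrades the voxelized truth with Gaussian
blur (partial-volume effect) and additive Gaussian noise.  A separate
bone phantom provides two bright bone-like bodies around a joint gap to
exercise the anatomical VOI pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import ScalarVolume

__all__ = [
    "TreeParams",
    "CTSimParams",
    "BonePhantomParams",
    "VesselSegment",
    "VesselTree",
    "generate_tree",
    "voxelize_tree",
    "simulate_ct",
    "generate_bone_phantom",
    "make_phantom",
]

_AREA_RTOL = 1e-6


@dataclass
class TreeParams:
    """Parameters of the random vascular-tree generator.

    All lengths in μm, all angles in degrees.  ``min_radius`` defaults
    to one voxel so the minimum vessel diameter is two voxels (24 μm at
    the default 12 μm voxel size).
    """

    domain_shape: tuple[int, int, int] = (200, 200, 200)
    voxel_size: float = 12.0
    root_radius: float = 72.0
    min_radius: float | None = None
    step_length: float = 24.0
    curving_angle_range: tuple[float, float] = (0.0, 20.0)
    branching_angle_range: tuple[float, float] = (30.0, 70.0)
    branch_probability_per_step: float = 0.05
    # child cross-sectional area fraction is drawn uniformly in this range
    area_split_range: tuple[float, float] = (0.3, 0.7)
    max_depth: int = 8
    max_steps_per_segment: int = 2000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_radius is None:
            self.min_radius = float(self.voxel_size)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.min_radius < self.voxel_size:
            raise ValueError(
                f"min_radius ({self.min_radius}) must be >= voxel_size "
                f"({self.voxel_size}) so the minimum diameter spans two voxels"
            )
        if self.root_radius < self.min_radius:
            raise ValueError(
                f"root_radius ({self.root_radius}) must be >= min_radius ({self.min_radius})"
            )
        for name, (lo, hi) in (
            ("curving_angle_range", self.curving_angle_range),
            ("branching_angle_range", self.branching_angle_range),
        ):
            if not (0.0 <= lo <= hi < 90.0):
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi < 90, got {(lo, hi)}")
        if not 0.0 <= self.branch_probability_per_step <= 1.0:
            raise ValueError("branch_probability_per_step must be in [0, 1]")
        lo, hi = self.area_split_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("area_split_range must lie strictly inside (0, 1)")
        if self.step_length <= 0:
            raise ValueError("step_length must be positive")

    @property
    def extent_um(self) -> np.ndarray:
        """Physical position of the last voxel center per axis (μm)."""
        return (np.asarray(self.domain_shape) - 1) * self.voxel_size


@dataclass
class CTSimParams:
    """Degradation applied to a voxelized truth to emulate a μCT scan.

    Defaults: blur σ of one voxel (12 μm) and noise σ of 10% of the
    vessel/background contrast, chosen to reproduce the qualitative
    partial-volume behaviour of real scans (thin-vessel intensities are
    strongly reduced, sub-4-voxel thickness is overestimated).
    """

    vessel_intensity: float = 500.0
    background_intensity: float = 100.0
    blur_sigma: float = 12.0
    noise_sigma: float = 40.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.vessel_intensity > self.background_intensity:
            raise ValueError("vessel_intensity must exceed background_intensity")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("blur_sigma and noise_sigma must be >= 0")

    @property
    def contrast(self) -> float:
        return self.vessel_intensity - self.background_intensity


@dataclass
class VesselSegment:
    """One unbranched vessel segment: a centerline polyline with radius."""

    points: np.ndarray  # (n, 3) centerline points in μm, (z, y, x)
    radii: np.ndarray  # (n,) local radius in μm
    parent: int | None  # index of the parent segment, None for the root


@dataclass
class VesselTree:
    """Ground-truth phantom geometry: segments with parent links."""

    segments: list[VesselSegment]
    params: TreeParams | None = field(default=None, repr=False)

    def centerline_samples(self, spacing: float | None = None) -> tuple[np.ndarray, np.ndarray]:
        """All centerline points with their true diameters.

        When ``spacing`` is given, each polyline is resampled so that
        consecutive samples are at most ``spacing`` μm apart (useful for
        rasterization and for nearest-point thickness matching).
        """
        pts, dia = [], []
        for seg in self.segments:
            p, r = seg.points, seg.radii
            if spacing is not None and len(p) > 1:
                p, r = _densify(p, r, spacing)
            pts.append(p)
            dia.append(2.0 * r)
        return np.concatenate(pts, axis=0), np.concatenate(dia, axis=0)

    def to_records(self) -> list[dict]:
        return [
            {
                "segment": i,
                "parent": seg.parent,
                "points_um": np.asarray(seg.points).tolist(),
                "radii_um": np.asarray(seg.radii).tolist(),
            }
            for i, seg in enumerate(self.segments)
        ]

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_records()))

    def save_csv(self, path: str | Path) -> None:
        """Flat per-point table: segment, parent, z/y/x (μm), radius (μm)."""
        lines = ["segment,parent,z_um,y_um,x_um,radius_um"]
        for i, seg in enumerate(self.segments):
            parent = "" if seg.parent is None else seg.parent
            for (z, y, x), r in zip(seg.points, seg.radii):
                lines.append(f"{i},{parent},{z:.3f},{y:.3f},{x:.3f},{r:.3f}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load_json(cls, path: str | Path) -> "VesselTree":
        segs = [
            VesselSegment(
                np.asarray(rec["points_um"], dtype=float),
                np.asarray(rec["radii_um"], dtype=float),
                rec["parent"],
            )
            for rec in json.loads(Path(path).read_text())
        ]
        return cls(segs)


def _densify(points: np.ndarray, radii: np.ndarray, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline so consecutive samples are <= spacing apart."""
    out_p = [points[:1]]
    out_r = [radii[:1]]
    for a, b, ra, rb in zip(points[:-1], points[1:], radii[:-1], radii[1:]):
        d = float(np.linalg.norm(b - a))
        n = max(1, int(np.ceil(d / spacing)))
        t = np.arange(1, n + 1, dtype=float)[:, None] / n
        out_p.append(a[None, :] * (1 - t) + b[None, :] * t)
        out_r.append(ra * (1 - t[:, 0]) + rb * t[:, 0])
    return np.concatenate(out_p), np.concatenate(out_r)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perpendicular(direction: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random unit vector perpendicular to ``direction``."""
    while True:
        v = rng.normal(size=3)
        v -= v @ direction * direction
        n = np.linalg.norm(v)
        if n > 1e-8:
            return v / n


def _rotate(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about the unit vector ``axis``."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1 - c)


def generate_tree(params: TreeParams) -> VesselTree:
    """Grow a random vascular tree inside the voxel domain.

    The root starts at the center of the ``z = margin`` face pointing in
    +z.  Each step advances by ``step_length`` along a direction bent by
    a uniformly drawn curving angle about a random perpendicular axis.
    With probability ``branch_probability_per_step`` the segment ends in
    a bifurcation whose child radii conserve cross-sectional area; a
    bifurcation that would create a child thinner than ``min_radius`` is
    rejected and growth continues.  Segments terminate when the next
    center (with its radius margin) would leave the domain.
    """
    rng = np.random.default_rng(params.rng_seed)
    extent = params.extent_um
    margin_lo = lambda r: r
    margin_hi = lambda r: extent - r
    if np.any(margin_hi(params.root_radius) <= margin_lo(params.root_radius)):
        raise ValueError("domain too small for root_radius")

    root_start = np.array([params.root_radius, extent[1] / 2.0, extent[2] / 2.0])
    segments: list[VesselSegment] = []
    # (start point, direction, radius, depth, parent id)
    stack = [(root_start, np.array([1.0, 0.0, 0.0]), params.root_radius, 0, None)]
    c_lo, c_hi = np.deg2rad(params.curving_angle_range)
    b_lo, b_hi = np.deg2rad(params.branching_angle_range)

    while stack:
        start, direction, radius, depth, parent = stack.pop()
        pts = [start]
        d = direction.copy()
        children: list[tuple[np.ndarray, float]] = []
        for _ in range(params.max_steps_per_segment):
            axis = _perpendicular(d, rng)
            d = _unit(_rotate(d, axis, rng.uniform(c_lo, c_hi)))
            nxt = pts[-1] + d * params.step_length
            if np.any(nxt < margin_lo(radius)) or np.any(nxt > margin_hi(radius)):
                break
            pts.append(nxt)
            if depth < params.max_depth and rng.uniform() < params.branch_probability_per_step:
                u = rng.uniform(*params.area_split_range)
                r1, r2 = radius * np.sqrt(u), radius * np.sqrt(1.0 - u)
                if min(r1, r2) >= params.min_radius:
                    half = 0.5 * rng.uniform(b_lo, b_hi)
                    b_axis = _perpendicular(d, rng)
                    children = [
                        (_unit(_rotate(d, b_axis, half)), r1),
                        (_unit(_rotate(d, b_axis, -half)), r2),
                    ]
                    break
        points = np.asarray(pts)
        seg_id = len(segments)
        segments.append(VesselSegment(points, np.full(len(points), radius), parent))
        for child_dir, child_r in children:
            stack.append((points[-1].copy(), child_dir, child_r, depth + 1, seg_id))
    return VesselTree(segments, params)


def voxelize_tree(tree: VesselTree, domain_shape: tuple[int, int, int] | None = None,
                  voxel_size: float | None = None) -> np.ndarray:
    """Rasterize a tree to a boolean mask (union-of-balls rule).

    A voxel is foreground iff its center lies within the local radius
    (closed ball, ``<=``) of some densified centerline sample.  The
    centerline is resampled at half-voxel spacing first, which keeps the
    rasterized tube 26-connected.
    """
    if tree.params is not None:
        domain_shape = domain_shape or tree.params.domain_shape
        voxel_size = voxel_size or tree.params.voxel_size
    if domain_shape is None or voxel_size is None:
        raise ValueError("domain_shape and voxel_size required for a tree without params")
    shape = tuple(int(n) for n in domain_shape)
    mask = np.zeros(shape, dtype=bool)
    if not tree.segments:
        return mask
    pts, dia = tree.centerline_samples(spacing=0.5 * voxel_size)
    radii = 0.5 * dia
    centers_vox = pts / voxel_size
    r_vox = radii / voxel_size
    for (cz, cy, cx), rv in zip(centers_vox, r_vox):
        lo = [max(0, int(np.floor(c - rv))) for c in (cz, cy, cx)]
        hi = [min(n - 1, int(np.ceil(c + rv))) for c, n in zip((cz, cy, cx), shape)]
        if any(l > h for l, h in zip(lo, hi)):
            continue
        zz = np.arange(lo[0], hi[0] + 1, dtype=float) - cz
        yy = np.arange(lo[1], hi[1] + 1, dtype=float) - cy
        xx = np.arange(lo[2], hi[2] + 1, dtype=float) - cx
        d2 = zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
        sub = mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        sub |= d2 <= rv * rv
    return mask


def simulate_ct(true_mask: np.ndarray, params: CTSimParams, voxel_size: float) -> ScalarVolume:
    """Degrade a ground-truth mask into a simulated CT volume.

    Output = Gaussian blur of the intensity-coded mask plus additive
    Gaussian noise; identical seed gives a bit-identical volume.
    """
    img = np.where(true_mask, params.vessel_intensity, params.background_intensity).astype(np.float32)
    if params.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, params.blur_sigma / voxel_size)
    if params.noise_sigma > 0:
        rng = np.random.default_rng(params.rng_seed)
        img = img + rng.normal(0.0, params.noise_sigma, size=img.shape).astype(np.float32)
    return ScalarVolume(img, voxel_size)


def make_phantom(tree_params: TreeParams, sim_params: CTSimParams
                 ) -> tuple[VesselTree, np.ndarray, ScalarVolume]:
    """Convenience: generate, voxelize and degrade one phantom."""
    tree = generate_tree(tree_params)
    mask = voxelize_tree(tree)
    vol = simulate_ct(mask, sim_params, tree_params.voxel_size)
    return tree, mask, vol


@dataclass
class BonePhantomParams:
    """Two bright bone-like cylinders ("tibia" and "femur") separated by
    a joint gap, rendered at bone intensity comparable to the vessel
    intensity (as in real contrast-enhanced scans, where bone and
    Microfil-filled vessels have similar CT values).

    ``artifact_amplitude`` adds a bright exponential intensity halo next
    to the bone surface, a crude stand-in for beam-hardening bias.
    """

    gap_voxels: int = 24
    body_radius_fraction: float = 0.35  # of the smaller lateral extent
    bone_intensity: float = 500.0
    sim: CTSimParams = field(default_factory=CTSimParams)
    artifact_amplitude: float = 0.0
    artifact_decay_voxels: float = 4.0

    def __post_init__(self) -> None:
        if self.gap_voxels <= 0:
            raise ValueError("bone bodies overlap: gap_voxels must be positive")


def generate_bone_phantom(domain_shape: tuple[int, int, int], voxel_size: float,
                          params: BonePhantomParams,
                          vessel_mask: np.ndarray | None = None
                          ) -> tuple[np.ndarray, np.ndarray, ScalarVolume]:
    """Build (tibia-like mask, femur-like mask, simulated volume).

    The bodies are axis-aligned cylinders along z with rounded radii
    (femur slightly thicker), separated by ``gap_voxels`` empty slices
    around the mid-plane.  Optional vessels are overlaid at the vessel
    intensity before degradation.
    """
    nz, ny, nx = (int(n) for n in domain_shape)
    half_gap = params.gap_voxels / 2.0
    zc = (nz - 1) / 2.0
    z = np.arange(nz)[:, None, None]
    y = np.arange(ny)[None, :, None] - (ny - 1) / 2.0
    x = np.arange(nx)[None, None, :] - (nx - 1) / 2.0
    r_base = params.body_radius_fraction * min(ny, nx)
    rho2 = y ** 2 + x ** 2
    tibia = (z < zc - half_gap) & (rho2 <= r_base ** 2)
    femur = (z > zc + half_gap) & (rho2 <= (1.15 * r_base) ** 2)
    if (tibia & femur).any():
        raise ValueError("bone bodies overlap")

    sim = params.sim
    img = np.full(domain_shape, sim.background_intensity, dtype=np.float32)
    bone = tibia | femur
    img[bone] = params.bone_intensity
    if vessel_mask is not None:
        img[np.asarray(vessel_mask, dtype=bool) & ~bone] = sim.vessel_intensity
    if params.artifact_amplitude > 0:
        dist = ndimage.distance_transform_edt(~bone)
        halo = params.artifact_amplitude * np.exp(-dist / params.artifact_decay_voxels)
        img[~bone] += halo[~bone].astype(np.float32)
    if sim.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sim.blur_sigma / voxel_size)
    if sim.noise_sigma > 0:
        rng = np.random.default_rng(sim.rng_seed)
        img = img + rng.normal(0.0, sim.noise_sigma, size=img.shape).astype(np.float32)
    return tibia, femur, ScalarVolume(img, voxel_size)


def check_area_conservation(tree: VesselTree, rtol: float = _AREA_RTOL) -> bool:
    """True iff every bifurcation conserves cross-sectional area."""
    children: dict[int, list[float]] = {}
    for seg in tree.segments:
        if seg.parent is not None:
            children.setdefault(seg.parent, []).append(float(seg.radii[0]))
    for pid, child_r in children.items():
        rp = float(tree.segments[pid].radii[-1])
        if not np.isclose(rp ** 2, sum(r * r for r in child_r), rtol=rtol):
            return False
    return True
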