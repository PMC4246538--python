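"""Anatomical volumes of interest around a joint.

The analysis VOI is built by virtually removing bone: after a coarse
mask of the larger vessels (to keep bone region growing from leaking
into them), tibia and femur are segmented by adaptive-threshold volume
growing.  Their union VOI_TF is morphologically closed with a large
ball into VOI_TFC, and the knee joint cavity is the largest connected
component of

    VOI_KJC = VOI_TFC \\ VOI_TF .

A bounding sphere centered at the VOI_KJC centroid, scaled by an
empirical factor (default 2.5), approximates the joint capsule
(VOI_Capsule); it is split into four concentric shells for regional
morphometry and into a near-bone band (VOI_2S) and its complement
(VOI_1S) for the hybrid segmentation.

Morphological closing with large radii is computed via Euclidean
distance transforms, which is exactly equivalent to dilation/erosion
with the discrete ball structuring element {offset : |offset| ≤ r} but
orders of magnitude faster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import ScalarVolume

__all__ = [
    "VOISet",
    "coarse_vessel_mask",
    "segment_bone",
    "knee_joint_cavity",
    "capsule_voi",
    "concentric_shells",
    "split_segmentation_vois",
    "ball_closing",
    "build_voi_set",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VOISet:
    """All anatomical masks and the capsule sphere geometry.

    ``shells[0]`` is the central sphere VOI_1; ``shells[-1]`` the outer
    shell VOI_4.  ``capsule_center`` is in μm, ``(z, y, x)``.
    """

    voi_tf: np.ndarray
    voi_tfc: np.ndarray
    voi_kjc: np.ndarray
    capsule_center: tuple[float, float, float]
    capsule_radius: float
    voi_capsule: np.ndarray
    shells: list[np.ndarray] = field(default_factory=list)
    voi_1s: np.ndarray | None = None
    voi_2s: np.ndarray | None = None


def _dilate_ball(mask: np.ndarray, radius: float) -> np.ndarray:
    """Dilation with the discrete ball {|offset| <= radius} (via EDT)."""
    if not mask.any():
        return mask.copy()
    return ndimage.distance_transform_edt(~mask) <= radius


def _erode_ball(mask: np.ndarray, radius: float) -> np.ndarray:
    """Erosion with the discrete ball {|offset| <= radius} (via EDT)."""
    if not mask.any():
        return mask.copy()
    return ndimage.distance_transform_edt(mask) > radius


def ball_closing(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological closing with a ball, padded so the border behaves
    as if the mask were embedded in an infinite background."""
    r = int(radius)
    if r <= 0:
        return np.asarray(mask, dtype=bool).copy()
    padded = np.pad(np.asarray(mask, dtype=bool), r, mode="constant")
    closed = _erode_ball(_dilate_ball(padded, r), r)
    sl = (slice(r, -r),) * 3
    return closed[sl]


def coarse_vessel_mask(volume: ScalarVolume, high_fraction: float = 0.6,
                       bone_seeds: list[tuple[int, int, int]] | None = None) -> np.ndarray:
    """Coarse mask of the brightest structures (the larger vessels).

    Thresholds at ``high_fraction`` of the robust maximum (99.9th
    percentile), then drops connected components that contain a bone
    seed (those belong to bone, which is handled separately).  A volume
    without appreciable dynamic range yields an empty mask.
    """
    data = np.asarray(volume.data)
    p50 = float(np.percentile(data, 50.0))
    robust_max = float(np.percentile(data, 99.9))
    if robust_max <= p50 or (robust_max - p50) < 1e-6 * max(abs(robust_max), 1.0):
        return np.zeros(volume.shape, dtype=bool)
    mask = data >= high_fraction * robust_max
    if bone_seeds:
        labels, _ = ndimage.label(mask, structure=_STRUCT26)
        drop = {int(labels[tuple(s)]) for s in bone_seeds}
        drop.discard(0)
        if drop:
            mask &= ~np.isin(labels, sorted(drop))
    return mask


def segment_bone(volume: ScalarVolume, seed_points: list[tuple[int, int, int]],
                 blocked: np.ndarray | None = None, closing_radius: int = 3,
                 max_iter: int = 10, tol: float = 1e-3) -> np.ndarray:
    """Adaptive-threshold volume growing for bone, plus closing.

    Starting from a threshold halfway between the volume median and its
    robust maximum, the 26-connected region containing the seeds is
    grown and the threshold re-estimated as μ_region − 2 σ_region until
    stable.  The region never enters ``blocked`` (the coarse vessel
    mask), and a morphological closing fills intracortical gaps.
    """
    data = np.asarray(volume.data, dtype=float)
    blocked = np.zeros(volume.shape, dtype=bool) if blocked is None else np.asarray(blocked, dtype=bool)
    seeds = [tuple(int(c) for c in s) for s in seed_points]
    if not seeds:
        raise ValueError("at least one bone seed point is required")
    t = 0.5 * (float(np.percentile(data, 50.0)) + float(np.percentile(data, 99.9)))
    low = [s for s in seeds if data[s] < t]
    if low:
        raise ValueError(
            f"bone seed(s) {low} lie below the initial bone threshold {t:.1f}; "
            "seeds must be placed inside bright bone"
        )
    region = None
    for _ in range(max_iter):
        cand = (data >= t) & ~blocked
        labels, _ = ndimage.label(cand, structure=_STRUCT26)
        seed_labels = {int(labels[s]) for s in seeds}
        seed_labels.discard(0)
        if not seed_labels:
            raise ValueError("bone seeds fell below the adaptive threshold; segmentation is empty")
        region = np.isin(labels, sorted(seed_labels))
        vals = data[region]
        t_new = float(vals.mean() - 2.0 * vals.std())
        if abs(t_new - t) <= tol * max(abs(t), 1.0):
            t = t_new
            break
        t = t_new
    closed = ball_closing(region, closing_radius)
    return closed & ~blocked


def knee_joint_cavity(voi_tf: np.ndarray, closing_radius: int) -> np.ndarray:
    """Largest 26-connected component of closing(VOI_TF) \\ VOI_TF."""
    voi_tf = np.asarray(voi_tf, dtype=bool)
    closed = ball_closing(voi_tf, closing_radius)
    diff = closed & ~voi_tf
    if not diff.any():
        raise ValueError("no cavity found; increase closing radius")
    labels, n = ndimage.label(diff, structure=_STRUCT26)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def _radial_distance_um(shape: tuple[int, int, int], center_um: np.ndarray,
                        voxel_size: float) -> np.ndarray:
    z = np.arange(shape[0]) * voxel_size - center_um[0]
    y = np.arange(shape[1]) * voxel_size - center_um[1]
    x = np.arange(shape[2]) * voxel_size - center_um[2]
    return np.sqrt(z[:, None, None] ** 2 + y[None, :, None] ** 2 + x[None, None, :] ** 2)


def capsule_voi(voi_kjc: np.ndarray, voxel_size: float, scale: float = 2.5,
                bone: np.ndarray | None = None
                ) -> tuple[tuple[float, float, float], float, np.ndarray]:
    """Joint-capsule sphere from the cavity bounding sphere.

    The bounding sphere sits at the voxel-count centroid of VOI_KJC and
    has radius R0 = max distance to a cavity voxel center; the capsule
    radius is ``scale × R0`` (default 2.5).  The capsule mask is the
    sphere clipped to the image domain, minus bone.
    """
    voi_kjc = np.asarray(voi_kjc, dtype=bool)
    if not voi_kjc.any():
        raise ValueError("empty knee joint cavity")
    idx = np.argwhere(voi_kjc).astype(float)
    center_vox = idx.mean(axis=0)
    center_um = center_vox * voxel_size
    r0 = float(np.sqrt(((idx - center_vox) ** 2).sum(axis=1).max()) * voxel_size)
    if r0 <= 0:
        raise ValueError("degenerate cavity: bounding-sphere radius is zero")
    radius = scale * r0
    dist = _radial_distance_um(voi_kjc.shape, center_um, voxel_size)
    mask = dist <= radius
    if bone is not None:
        mask &= ~np.asarray(bone, dtype=bool)
    return tuple(center_um), radius, mask


def concentric_shells(capsule_center: tuple[float, float, float], capsule_radius: float,
                      shape: tuple[int, int, int], voxel_size: float,
                      bone: np.ndarray | None = None, n_shells: int = 4,
                      fractions: tuple[float, ...] | None = None) -> list[np.ndarray]:
    """Partition the capsule into concentric shells (minus bone).

    Shell k covers radial distances in ((k−1)·R/n, k·R/n] by default
    (shell 1 is the central sphere and includes the center); custom
    boundary ``fractions`` of the capsule radius may be given.  The
    shells are pairwise disjoint and their union is exactly the
    capsule-minus-bone mask.
    """
    if fractions is None:
        fractions = tuple((k + 1) / n_shells for k in range(n_shells))
    if len(fractions) != n_shells or abs(fractions[-1] - 1.0) > 1e-12:
        raise ValueError("fractions must have n_shells entries ending at 1.0")
    dist = _radial_distance_um(shape, np.asarray(capsule_center, dtype=float), voxel_size)
    keep = dist <= capsule_radius
    if bone is not None:
        keep &= ~np.asarray(bone, dtype=bool)
    shells = []
    prev = -np.inf
    for f in fractions:
        r = f * capsule_radius
        shells.append(keep & (dist > prev) & (dist <= r))
        prev = r
    return shells


def split_segmentation_vois(capsule: np.ndarray, bone: np.ndarray | None,
                            band_width_voxels: float) -> tuple[np.ndarray, np.ndarray]:
    """Split the capsule into VOI_1S (away from bone) and VOI_2S (the
    band within ``band_width_voxels`` of the bone surface).

    LAT is used in VOI_1S, MS in VOI_2S where beam hardening corrupts
    intensities.
    """
    capsule = np.asarray(capsule, dtype=bool)
    if bone is None or not np.asarray(bone, dtype=bool).any() or band_width_voxels <= 0:
        return capsule.copy(), np.zeros(capsule.shape, dtype=bool)
    bone = np.asarray(bone, dtype=bool)
    dist = ndimage.distance_transform_edt(~bone)
    voi_2s = capsule & (dist <= band_width_voxels)
    voi_1s = capsule & ~voi_2s
    return voi_1s, voi_2s


def build_voi_set(volume: ScalarVolume,
                  tibia_seeds: list[tuple[int, int, int]],
                  femur_seeds: list[tuple[int, int, int]],
                  closing_radius: int = 30,
                  capsule_scale: float = 2.5,
                  band_width_voxels: float = 10.0,
                  coarse_high_fraction: float = 0.6,
                  n_shells: int = 4) -> VOISet:
    """Run the full preparative pipeline on a bone-containing volume."""
    all_seeds = list(tibia_seeds) + list(femur_seeds)
    coarse = coarse_vessel_mask(volume, coarse_high_fraction, bone_seeds=all_seeds)
    voi_tf = segment_bone(volume, all_seeds, blocked=coarse)
    voi_tfc = ball_closing(voi_tf, closing_radius)
    voi_kjc = knee_joint_cavity(voi_tf, closing_radius)
    center, radius, capsule = capsule_voi(voi_kjc, volume.spacing, capsule_scale, bone=voi_tf)
    shells = concentric_shells(center, radius, volume.shape, volume.spacing,
                               bone=voi_tf, n_shells=n_shells)
    voi_1s, voi_2s = split_segmentation_vois(capsule, voi_tf, band_width_voxels)
    return VOISet(voi_tf=voi_tf, voi_tfc=voi_tfc, voi_kjc=voi_kjc,
                  capsule_center=center, capsule_radius=radius, voi_capsule=capsule,
                  shells=shells, voi_1s=voi_1s, voi_2s=voi_2s)
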