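"""Vascular morphometry on binary vessel masks.

Direct (model-free) parameters:

* ``TV``   — tissue volume of the VOI (mm³)
* ``VV``   — vessel volume (mm³), ``VV/TV`` in %
* ``VS``   — vessel surface (mm²), from a marching-cubes isosurface
* ``V.Th3D`` — direct vessel thickness (μm): twice the Euclidean
  distance-transform value at centerline (skeleton) voxels, averaged

Rod-model parameters, assuming cylindrical vessels (the trabecular
rod-model transplanted to vasculature):

* ``V.Th2D = 4·VV/VS``
* ``V.N2D  = sqrt((4/π)·(VV/TV)) / V.Th2D``
* ``V.Sp2D = V.Th2D · (sqrt((4/π)·(TV/VV)) − 1)``

For an ideal circular cylinder ``4·V/S`` equals the true diameter,
which anchors the 2D thickness to the 3D one.

Connectivity convention: vessels are 26-connected, background
6-connected (the standard complementary pairing in 3D).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

__all__ = [
    "MorphometryResult",
    "volume_density",
    "vessel_surface",
    "centerline",
    "thickness_3d",
    "rod_model",
    "rod_model_slicewise",
    "count_components",
    "quantify",
    "per_voi_report",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class MorphometryResult:
    """All vascular parameters for one VOI."""

    label: str
    tv: float  # mm3
    vv: float  # mm3
    vv_tv: float  # %
    vs: float  # mm2
    v_th_3d: float | None  # μm
    v_th_2d: float | None  # μm
    v_sp_2d: float | None  # mm
    v_n_2d: float | None  # 1/mm
    component_count: int
    hist_edges_um: np.ndarray | None = field(default=None, repr=False)
    hist_volume_mm3: np.ndarray | None = field(default=None, repr=False)

    def to_row(self) -> dict:
        return {
            "voi": self.label, "TV_mm3": self.tv, "VV_mm3": self.vv,
            "VV_TV_pct": self.vv_tv, "VS_mm2": self.vs, "V.Th3D_um": self.v_th_3d,
            "V.Th2D_um": self.v_th_2d, "V.Sp2D_mm": self.v_sp_2d,
            "V.N2D_per_mm": self.v_n_2d, "components": self.component_count,
        }


def volume_density(mask: np.ndarray, voi: np.ndarray, voxel_size: float
                   ) -> tuple[float, float, float]:
    """(TV mm³, VV mm³, VV/TV %) from voxel counts."""
    voi = np.asarray(voi, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    n_voi = int(voi.sum())
    if n_voi == 0:
        raise ValueError("empty VOI")
    vox_mm3 = (voxel_size * 1e-3) ** 3
    n_vessel = int((mask & voi).sum())
    tv = n_voi * vox_mm3
    vv = n_vessel * vox_mm3
    return tv, vv, 100.0 * vv / tv


def vessel_surface(mask: np.ndarray, voxel_size: float,
                   presmooth_sigma: float = 1.0) -> float:
    """Vessel surface in mm² from a marching-cubes isosurface at 0.5.

    The mask is zero-padded so surfaces at the domain border are closed.
    A light Gaussian pre-smoothing (default σ = 1 voxel) removes the
    staircase bias of meshing raw binary data (a digital ball of radius
    20 voxels measures within 1% of 4πr² instead of ~8% above it) while
    two-voxel-diameter tubes still cross the 0.5 level.  With
    ``presmooth_sigma=0`` the raw binary mesh is produced (one isolated
    voxel then becomes an octahedron of area ≈ 1.73 voxel faces).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    pad = 1 + int(np.ceil(2 * presmooth_sigma))
    padded = np.pad(mask, pad).astype(np.float32)
    if presmooth_sigma > 0:
        padded = ndimage.gaussian_filter(padded, presmooth_sigma)
        if padded.max() <= 0.5:  # structure thinner than the smoothing kernel
            padded = np.pad(mask, pad).astype(np.float32)
    sp = voxel_size * 1e-3
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=(sp, sp, sp))
    return float(measure.mesh_surface_area(verts, faces))


def centerline(mask: np.ndarray) -> np.ndarray:
    """3D thinning (Lee et al.) that keeps one voxel per component.

    The raw thinning can erase small blobs with even side lengths
    outright (there is no center voxel to settle on); any 26-connected
    component left without a skeleton voxel gets its innermost voxel
    (distance-transform maximum) back, so the skeleton preserves the
    component count.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    skel = morphology.skeletonize(mask) > 0
    labels, n = ndimage.label(mask, structure=_STRUCT26)
    present = np.unique(labels[skel])
    missing = np.setdiff1d(np.arange(1, n + 1), present)
    if missing.size:
        edt = ndimage.distance_transform_edt(mask)
        for lab in missing:
            comp = labels == lab
            idx = np.unravel_index(np.argmax(np.where(comp, edt, -1.0)), mask.shape)
            skel[idx] = True
    return skel


def thickness_3d(mask: np.ndarray, skeleton: np.ndarray, voxel_size: float,
                 bin_width_um: float = 15.0
                 ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Direct 3D thickness from the distance transform at the skeleton.

    Local thickness at a centerline voxel is twice its Euclidean
    distance to the nearest background voxel.  Returns the mean
    thickness (μm), the per-skeleton-voxel thicknesses, and a histogram
    attributing each vessel voxel's volume to its nearest centerline
    voxel's thickness bin (bin edges start at 0, default width one
    scanner voxel = 15 μm); the per-bin volumes sum to VV.
    """
    mask = np.asarray(mask, dtype=bool)
    skeleton = np.asarray(skeleton, dtype=bool)
    if not skeleton.any():
        raise ValueError("empty skeleton: thickness is undefined")
    if (skeleton & ~mask).any():
        raise ValueError("skeleton must be a subset of the mask")
    edt = ndimage.distance_transform_edt(mask, sampling=voxel_size)
    th_skel = 2.0 * edt[skeleton]
    # attribute every vessel voxel to its nearest skeleton voxel
    inds = ndimage.distance_transform_edt(~skeleton, return_indices=True, return_distances=False)
    near = tuple(ind[mask] for ind in inds)
    th_of_nearest = 2.0 * edt[near]
    edges = np.arange(0.0, th_skel.max() + bin_width_um, bin_width_um)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width_um])
    vox_mm3 = (voxel_size * 1e-3) ** 3
    which = np.clip(np.digitize(th_of_nearest, edges) - 1, 0, len(edges) - 2)
    vol_per_bin = np.bincount(which, minlength=len(edges) - 1).astype(float) * vox_mm3
    return float(th_skel.mean()), th_skel, edges, vol_per_bin


def rod_model(vv: float, tv: float, vs: float) -> tuple[float, float, float]:
    """Rod-model thickness/spacing/number from VV, TV (mm³) and VS (mm²).

    Returns ``(V.Th2D μm, V.Sp2D mm, V.N2D 1/mm)``.
    """
    if vs <= 0 or vv <= 0:
        raise ValueError("rod model requires positive vessel volume and surface")
    if tv <= 0 or vv > tv:
        raise ValueError("require 0 < VV <= TV")
    th_mm = 4.0 * vv / vs
    n_per_mm = np.sqrt((4.0 / np.pi) * (vv / tv)) / th_mm
    sp_mm = th_mm * (np.sqrt((4.0 / np.pi) * (tv / vv)) - 1.0)
    return th_mm * 1e3, float(sp_mm), float(n_per_mm)


def rod_model_slicewise(mask: np.ndarray, voi: np.ndarray, voxel_size: float,
                        axis: int = 0) -> tuple[float, float, float]:
    """Slice-by-slice rod-model variant, averaged over axial slices.

    Per slice the 2D analogues use vessel area and Crofton perimeter
    (``V.Th = 4·A/P`` equals the diameter for circular cross sections);
    slice values are averaged weighted by slice tissue area.
    """
    mask = np.asarray(mask, dtype=bool)
    voi = np.asarray(voi, dtype=bool)
    px_mm = voxel_size * 1e-3
    ths, sps, ns, weights = [], [], [], []
    for k in range(mask.shape[axis]):
        sl = [slice(None)] * 3
        sl[axis] = k
        m = mask[tuple(sl)] & voi[tuple(sl)]
        t = voi[tuple(sl)]
        n_t = int(t.sum())
        if n_t == 0 or not m.any():
            continue
        area = m.sum() * px_mm ** 2
        ta = n_t * px_mm ** 2
        per = float(measure.perimeter_crofton(m, directions=4)) * px_mm
        if per <= 0:
            continue
        th = 4.0 * area / per
        ths.append(th)
        ns.append(np.sqrt((4.0 / np.pi) * (area / ta)) / th)
        sps.append(th * (np.sqrt((4.0 / np.pi) * (ta / area)) - 1.0))
        weights.append(ta)
    if not weights:
        raise ValueError("no slice contains vessel voxels")
    w = np.asarray(weights)
    avg = lambda v: float(np.average(np.asarray(v), weights=w))
    return avg(ths) * 1e3, avg(sps), avg(ns)


def count_components(mask: np.ndarray) -> int:
    """Number of 26-connected components."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0
    _, n = ndimage.label(mask, structure=_STRUCT26)
    return int(n)


def quantify(mask: np.ndarray, voi: np.ndarray, voxel_size: float,
             label: str = "VOI", bin_width_um: float = 15.0) -> MorphometryResult:
    """Compute the full parameter set for one VOI."""
    voi = np.asarray(voi, dtype=bool)
    m = np.asarray(mask, dtype=bool) & voi
    if not voi.any():
        # e.g. an outer shell fully clipped by the image domain or bone
        warnings.warn(f"{label}: empty VOI; reporting zero volumes")
        return MorphometryResult(label=label, tv=0.0, vv=0.0, vv_tv=0.0, vs=0.0,
                                 v_th_3d=None, v_th_2d=None, v_sp_2d=None,
                                 v_n_2d=None, component_count=0)
    tv, vv, vv_tv = volume_density(m, voi, voxel_size)
    vs = vessel_surface(m, voxel_size)
    ncomp = count_components(m)
    v_th3d = v_th2d = v_sp2d = v_n2d = None
    edges = vols = None
    if m.any():
        skel = centerline(m)
        if skel.any():
            v_th3d, _, edges, vols = thickness_3d(m, skel, voxel_size, bin_width_um)
        if vs > 0:
            v_th2d, v_sp2d, v_n2d = rod_model(vv, tv, vs)
    else:
        warnings.warn(f"{label}: empty vessel mask; thickness parameters undefined")
    return MorphometryResult(label=label, tv=tv, vv=vv, vv_tv=vv_tv, vs=vs,
                             v_th_3d=v_th3d, v_th_2d=v_th2d, v_sp_2d=v_sp2d,
                             v_n_2d=v_n2d, component_count=ncomp,
                             hist_edges_um=edges, hist_volume_mm3=vols)


def per_voi_report(mask: np.ndarray, vois, voxel_size: float,
                   bin_width_um: float = 15.0, normalize_hist: bool = False
                   ) -> list[MorphometryResult]:
    """One result per concentric shell plus one for the whole capsule.

    ``vois`` is a :class:`~angioct.voi.VOISet` or an object with
    ``shells`` and ``voi_capsule`` attributes.  With ``normalize_hist``
    the per-bin histogram volumes are divided by the VOI's TV.
    """
    results = []
    for i, shell in enumerate(vois.shells, start=1):
        results.append(quantify(mask, shell, voxel_size, label=f"VOI_{i}",
                                bin_width_um=bin_width_um))
    results.append(quantify(mask, vois.voi_capsule, voxel_size, label="VOI_Capsule",
                            bin_width_um=bin_width_um))
    if normalize_hist:
        for r in results:
            if r.hist_volume_mm3 is not None and r.tv > 0:
                r.hist_volume_mm3 = r.hist_volume_mm3 / r.tv
    return results
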