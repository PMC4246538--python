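"""Vessel segmentation: global threshold (GT), local-adaptive-threshold
volume growing (LAT), multi-scale Hessian vesselness (MS), and their
hybrid combination (MSLAT).

The LAT classifier computes two thresholds from soft-tissue statistics,

    T_low  = μ_ST + 2 σ_ST
    T_high = 0.65 · H_max

where μ_ST, σ_ST come from a Gaussian fitted to the dominant
(soft-tissue) mode of the VOI intensity histogram and H_max is a robust
maximum intensity.  Voxels ≥ T_high are vessel seeds; voxels in
[T_low, T_high) are accepted when the coefficient of variation of their
26-neighbourhood satisfies σ/μ < α·τ with τ = σ_ST/μ_ST and α = 1; the
final mask is the seed-connected part of the accepted set (volume
growing).  LAT uses intensity homogeneity only — no shape prior — which
preserves vessel connectivity but tends to include the blurred halo
around vessels.

The MS filter assumes bright cylindrical vessels and evaluates, at each
Gaussian smoothing scale, the eigenvalue response

    λc = min(−λ2, −λ3),   λ1 ≥ λ2 ≥ λ3
    R_s = λc · exp(−λ1² / (2 (α_i λc)²)),  α1 = 0.5 (λ1 ≤ 0), α2 = 2 (λ1 > 0)

and zero where λc ≤ 0; the per-voxel maximum over scales is kept and a
two-class K-means on the response separates vessel from background.
The leading λc factor follows the common ITK formulation; a flag
evaluates the bare exponential instead.

The hybrid MSLAT applies LAT away from bone (VOI_1S) and MS in the band
near bone (VOI_2S) where beam hardening defeats intensity criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .volume import ScalarVolume

__all__ = [
    "SoftTissueStats",
    "LATParams",
    "MSParams",
    "fit_soft_tissue",
    "lat_thresholds",
    "lat_segment",
    "vesselness_response",
    "multiscale_enhance",
    "ms_segment",
    "gt_segment",
    "mslat_segment",
    "apply_corrections",
]


@dataclass
class SoftTissueStats:
    """Soft-tissue intensity statistics inside the analysis VOI."""

    mu_st: float
    sigma_st: float
    h_max: float

    def __post_init__(self) -> None:
        if not (self.sigma_st > 0 and self.mu_st > 0):
            raise ValueError("mu_st and sigma_st must be positive")
        if not self.h_max > self.mu_st:
            raise ValueError("h_max must exceed mu_st")

    @property
    def tau(self) -> float:
        """Soft-tissue coefficient of variation τ = σ_ST / μ_ST."""
        return self.sigma_st / self.mu_st


@dataclass
class LATParams:
    alpha: float = 1.0
    t_low: float = 0.0
    t_high: float = 1.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not self.t_low < self.t_high:
            raise ValueError(
                f"insufficient vessel contrast: t_low ({self.t_low}) >= t_high ({self.t_high})"
            )


@dataclass
class MSParams:
    """Multi-scale filter parameters; ``scales`` are Gaussian σ in μm.

    The default ladder of 1–4 voxels covers vessel radii of roughly one
    to four voxels.
    """

    alpha1: float = 0.5
    alpha2: float = 2.0
    scales: tuple[float, ...] | None = None  # μm; None -> {1,2,3,4} voxels
    use_lambda_c_multiplier: bool = True

    def __post_init__(self) -> None:
        if not (self.alpha1 > 0 and self.alpha2 > 0):
            raise ValueError("alpha1 and alpha2 must be positive")
        if self.scales is not None:
            s = tuple(float(v) for v in self.scales)
            if len(s) == 0 or any(b <= a for a, b in zip(s, s[1:])) or s[0] <= 0:
                raise ValueError("scales must be a non-empty ascending positive sequence")
            self.scales = s

    def scales_um(self, voxel_size: float) -> tuple[float, ...]:
        if self.scales is not None:
            return self.scales
        return tuple(k * voxel_size for k in (1.0, 2.0, 3.0, 4.0))


def _gaussian(x, a, mu, sigma):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_soft_tissue(volume: ScalarVolume, voi: np.ndarray, n_bins: int = 256,
                    h_max_percentile: float = 99.9) -> SoftTissueStats:
    """Estimate soft-tissue statistics from the VOI histogram.

    A Gaussian is fitted to the dominant histogram mode (soft tissue is
    by far the most abundant class in a joint capsule), giving μ_ST and
    σ_ST.  H_max is the robust maximum intensity in the VOI (99.9th
    percentile), used as the reference for the upper vessel threshold.
    """
    vals = np.asarray(volume.data)[np.asarray(voi, dtype=bool)].astype(float)
    if vals.size < 1000:
        raise ValueError(f"VOI too small for histogram fitting ({vals.size} voxels < 1000)")
    if np.ptp(vals) == 0:
        raise ValueError("degenerate histogram: VOI intensities are constant")
    counts, edges = np.histogram(vals, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(counts))
    # contiguous run of bins around the peak with substantial counts
    lo = peak
    while lo > 0 and counts[lo - 1] >= 0.2 * counts[peak]:
        lo -= 1
    hi = peak
    while hi < n_bins - 1 and counts[hi + 1] >= 0.2 * counts[peak]:
        hi += 1
    sel = slice(lo, hi + 1)
    width0 = max(edges[1] - edges[0], 0.5 * (edges[hi + 1] - edges[lo]))
    try:
        popt, _ = optimize.curve_fit(
            _gaussian, centers[sel], counts[sel],
            p0=(counts[peak], centers[peak], width0), maxfev=2000,
        )
        mu, sigma = float(popt[1]), abs(float(popt[2]))
    except (RuntimeError, TypeError):
        # degenerate peak (fewer bins than fit parameters): fall back to
        # the peak location and its half-width
        mu, sigma = float(centers[peak]), float(width0)
    if sigma <= 0:
        sigma = float(width0)
    h_max = float(np.percentile(vals, h_max_percentile))
    return SoftTissueStats(mu_st=mu, sigma_st=sigma, h_max=h_max)


def lat_thresholds(stats: SoftTissueStats, alpha: float = 1.0) -> LATParams:
    """T_low = μ_ST + 2σ_ST, T_high = 0.65·H_max."""
    return LATParams(alpha=alpha, t_low=stats.mu_st + 2.0 * stats.sigma_st,
                     t_high=0.65 * stats.h_max)


def neighbourhood_stats(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD over each voxel's 26-neighbourhood (center excluded).

    Border voxels use reflected values.  The SD is the population SD of
    the 26 neighbours.
    """
    data = np.asarray(data, dtype=np.float64)
    s1 = ndimage.uniform_filter(data, size=3, mode="reflect") * 27.0 - data
    s2 = ndimage.uniform_filter(data * data, size=3, mode="reflect") * 27.0 - data * data
    mean = s1 / 26.0
    var = np.maximum(s2 / 26.0 - mean * mean, 0.0)
    return mean, np.sqrt(var)


def lat_segment(volume: ScalarVolume, voi: np.ndarray, params: LATParams,
                stats: SoftTissueStats) -> np.ndarray:
    """Local-adaptive-threshold volume growing inside a VOI.

    Seeds are voxels ≥ T_high; candidate voxels in [T_low, T_high) are
    accepted when their 26-neighbourhood satisfies σ/μ < α·τ (strict;
    equality is soft tissue).  The result is the union of 26-connected
    components of the accepted set that contain a seed.
    """
    voi = np.asarray(voi, dtype=bool)
    data = np.asarray(volume.data)
    seeds = (data >= params.t_high) & voi
    if not seeds.any():
        warnings.warn("LAT: no seed voxels above T_high; returning empty mask")
        return np.zeros(voi.shape, dtype=bool)
    mid = (data >= params.t_low) & (data < params.t_high) & voi
    if mid.any():
        mean, sd = neighbourhood_stats(data)
        accept = mid & (mean > 0) & (sd < params.alpha * stats.tau * mean)
    else:
        accept = mid
    candidate = seeds | accept
    labels, _ = ndimage.label(candidate, structure=np.ones((3, 3, 3), dtype=bool))
    keep = np.unique(labels[seeds])
    grown = np.isin(labels, keep[keep > 0])
    return grown & candidate


def vesselness_response(l1, l2, l3, params: MSParams | None = None):
    """Sato-type eigenvalue response for bright tubular structures.

    Accepts scalars or arrays; eigenvalues must be ordered λ1 ≥ λ2 ≥ λ3.
    Returns 0 where λc = min(−λ2, −λ3) ≤ 0 (non-tubular / dark), else a
    Gaussian penalty on λ1 with sharper decay for λ1 ≤ 0, optionally
    multiplied by λc.
    """
    params = params or MSParams()
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    l3 = np.asarray(l3, dtype=float)
    lc = np.minimum(-l2, -l3)
    alpha = np.where(l1 <= 0, params.alpha1, params.alpha2)
    denom = 2.0 * (alpha * lc) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        resp = np.exp(-np.where(denom > 0, (l1 * l1) / np.where(denom > 0, denom, 1.0),
                                np.inf))
    if params.use_lambda_c_multiplier:
        resp = resp * lc
    resp = np.where((lc > 0) & (denom > 0), resp, 0.0)
    if resp.ndim == 0:
        return float(resp)
    return resp


def _eigvalsh3(h11, h12, h13, h22, h23, h33):
    """Closed-form eigenvalues of symmetric 3x3 matrices, vectorized.

    Returns (λ1, λ2, λ3) sorted descending by signed value.  Uses the
    trigonometric solution for the characteristic cubic; accurate to a
    few ulps for the well-conditioned Hessians that occur here.
    """
    h11, h12, h13, h22, h23, h33 = (np.asarray(a, dtype=np.float64)
                                    for a in (h11, h12, h13, h22, h23, h33))
    p1 = h12 * h12 + h13 * h13 + h23 * h23
    q = (h11 + h22 + h33) / 3.0
    p2 = (h11 - q) ** 2 + (h22 - q) ** 2 + (h33 - q) ** 2 + 2.0 * p1
    p = np.sqrt(np.maximum(p2 / 6.0, 0.0))
    safe_p = np.where(p > 0, p, 1.0)
    b11, b22, b33 = (h11 - q) / safe_p, (h22 - q) / safe_p, (h33 - q) / safe_p
    b12, b13, b23 = h12 / safe_p, h13 / safe_p, h23 / safe_p
    detb = (b11 * (b22 * b33 - b23 * b23)
            - b12 * (b12 * b33 - b23 * b13)
            + b13 * (b12 * b23 - b22 * b13))
    r = np.clip(detb / 2.0, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    e_hi = q + 2.0 * p * np.cos(phi)
    e_lo = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    e_mid = 3.0 * q - e_hi - e_lo
    return e_hi, e_mid, e_lo


def _hessian_central(smoothed: np.ndarray) -> tuple[np.ndarray, ...]:
    """Hessian components by central differences with reflect padding.

    Derivatives are taken in voxel units (spacing 1); the response only
    depends on eigenvalue ratios, plus an overall λc factor common to
    all voxels of a scale.
    """
    pad = np.pad(smoothed, 1, mode="reflect")

    def d(arr, axis):
        sl_hi = [slice(1, -1)] * 3
        sl_lo = [slice(1, -1)] * 3
        sl_hi[axis] = slice(2, None)
        sl_lo[axis] = slice(None, -2)
        return 0.5 * (arr[tuple(sl_hi)] - arr[tuple(sl_lo)])

    grads = [d(pad, ax) for ax in range(3)]
    grads_p = [np.pad(g, 1, mode="reflect") for g in grads]
    h = {}
    for i in range(3):
        for j in range(i, 3):
            h[(i, j)] = d(grads_p[i], j)
    return h[(0, 0)], h[(0, 1)], h[(0, 2)], h[(1, 1)], h[(1, 2)], h[(2, 2)]


def multiscale_enhance(volume: ScalarVolume, voi: np.ndarray,
                       params: MSParams | None = None) -> ScalarVolume:
    """Multi-scale vesselness enhancement.

    For each scale σ the volume is Gaussian-smoothed, Hessian
    eigenvalues are computed per voxel, and the tubularity response is
    evaluated; the output keeps the per-voxel maximum over scales and is
    zero outside the VOI.
    """
    params = params or MSParams()
    voi = np.asarray(voi, dtype=bool)
    data = np.asarray(volume.data, dtype=np.float64)
    out = np.zeros(volume.shape, dtype=np.float64)
    if not voi.any():
        return ScalarVolume(out, volume.spacing)
    # compute on the VOI bounding box only (padded by the largest kernel)
    scales_vox = [s / volume.spacing for s in params.scales_um(volume.spacing)]
    pad = int(np.ceil(4 * max(scales_vox))) + 2
    idx = np.nonzero(voi)
    lo = [max(0, int(i.min()) - pad) for i in idx]
    hi = [min(n, int(i.max()) + pad + 1) for i, n in zip(idx, volume.shape)]
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub = data[box]
    best = np.zeros(sub.shape, dtype=np.float64)
    for s in scales_vox:
        smoothed = ndimage.gaussian_filter(sub, s)
        # σ²-normalized Hessian (scale-space normalization, as in the ITK
        # multi-scale filters): makes responses comparable across scales
        # and keeps small-scale noise from dominating the maximum
        h = tuple(s * s * c for c in _hessian_central(smoothed))
        l1, l2, l3 = _eigvalsh3(*h)
        np.maximum(best, vesselness_response(l1, l2, l3, params), out=best)
    out[box] = best
    out[~voi] = 0.0
    return ScalarVolume(out, volume.spacing)


def ms_segment(enhanced: ScalarVolume, voi: np.ndarray) -> np.ndarray:
    """Two-class K-means on the enhanced response inside the VOI.

    Cluster centers are initialized deterministically at the 10th and
    99th percentiles of the response; the higher-centroid cluster is
    vessel.  A flat response yields an empty mask with a warning.
    """
    from sklearn.cluster import KMeans

    voi = np.asarray(voi, dtype=bool)
    vals = np.asarray(enhanced.data)[voi].astype(np.float64)
    if vals.size == 0 or np.ptp(vals) == 0:
        warnings.warn("MS: response is flat inside the VOI; returning empty mask")
        return np.zeros(voi.shape, dtype=bool)
    c0, c1 = np.percentile(vals, 10.0), np.percentile(vals, 99.0)
    if c1 <= c0:
        c1 = float(vals.max())
        if c1 <= c0:
            warnings.warn("MS: degenerate response percentiles; returning empty mask")
            return np.zeros(voi.shape, dtype=bool)
    km = KMeans(n_clusters=2, init=np.array([[c0], [c1]]), n_init=1, random_state=0)
    labels = km.fit_predict(vals[:, None])
    vessel_label = int(np.argmax(km.cluster_centers_.ravel()))
    mask = np.zeros(voi.shape, dtype=bool)
    mask[voi] = labels == vessel_label
    return mask


def gt_segment(volume: ScalarVolume, voi: np.ndarray, threshold: float) -> np.ndarray:
    """Global threshold inside a VOI: vessel = intensity ≥ threshold."""
    return (np.asarray(volume.data) >= threshold) & np.asarray(voi, dtype=bool)


def mslat_segment(volume: ScalarVolume, voi_1s: np.ndarray, voi_2s: np.ndarray,
                  stats: SoftTissueStats, lat_params: LATParams | None = None,
                  ms_params: MSParams | None = None) -> np.ndarray:
    """Hybrid segmentation: LAT in VOI_1S, MS in VOI_2S, union.

    VOI_2S is the near-bone band where beam hardening makes intensity
    criteria unreliable and the shape-based MS filter performs better.
    """
    lat_params = lat_params or lat_thresholds(stats)
    lat_mask = lat_segment(volume, voi_1s, lat_params, stats)
    voi_2s = np.asarray(voi_2s, dtype=bool)
    if voi_2s.any():
        enhanced = multiscale_enhance(volume, voi_2s, ms_params)
        ms_mask = ms_segment(enhanced, voi_2s)
    else:
        ms_mask = np.zeros(voi_2s.shape, dtype=bool)
    return lat_mask | ms_mask


def apply_corrections(mask: np.ndarray, add: np.ndarray | None = None,
                      remove: np.ndarray | None = None) -> np.ndarray:
    """Apply externally supplied manual corrections: (mask ∪ add) \\ remove."""
    mask = np.asarray(mask, dtype=bool)
    add = np.zeros_like(mask) if add is None else np.asarray(add, dtype=bool)
    remove = np.zeros_like(mask) if remove is None else np.asarray(remove, dtype=bool)
    if (add & remove).any():
        raise ValueError("correction masks overlap: a voxel is both added and removed")
    return (mask | add) & ~remove
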