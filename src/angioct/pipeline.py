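"""End-to-end pipeline: bone removal → VOIs → vessel segmentation →
morphometry, with every intermediate mask, a provenance record and the
final reports written to an output directory.

Stage order: coarse vessel mask, bone segmentation, knee joint cavity,
capsule sphere, concentric shells, LAT/MS sub-VOIs, vessel
segmentation, optional manual corrections, per-VOI morphometry.  Any
stage failure aborts with the stage name; artifacts of completed
stages remain on disk, and the provenance JSON plus seeds suffice to
re-create the run exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, morphometry, segmentation, voi as voi_mod
from .config import PipelineConfig, config_to_dict
from .volume import ScalarVolume, read_mask, read_volume, write_mask

log = logging.getLogger("angioct.pipeline")

__all__ = ["run_pipeline"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig, volume: ScalarVolume | None = None) -> Path:
    """Run the full analysis; returns the output directory path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if volume is None:
        volume = read_volume(config.image, spacing=config.voxel_size)
    sp = volume.spacing

    def _save(mask, name):
        write_mask(mask, sp, out / f"{name}.mha")

    stage = "voi"
    try:
        vc = config.voi
        seeds = [tuple(s) for s in (list(vc.tibia_seeds) + list(vc.femur_seeds))]
        vois = voi_mod.build_voi_set(
            volume,
            [tuple(s) for s in vc.tibia_seeds], [tuple(s) for s in vc.femur_seeds],
            closing_radius=vc.closing_radius, capsule_scale=vc.capsule_scale,
            band_width_voxels=vc.band_width_voxels,
            coarse_high_fraction=vc.coarse_high_fraction, n_shells=vc.n_shells,
        )
        _save(vois.voi_tf, "voi_tf")
        _save(vois.voi_kjc, "voi_kjc")
        _save(vois.voi_capsule, "voi_capsule")
        for i, shell in enumerate(vois.shells, start=1):
            _save(shell, f"voi_{i}")
        _save(vois.voi_1s, "voi_1s")
        _save(vois.voi_2s, "voi_2s")
        log.info("VOIs built: capsule radius %.1f μm at %s", vois.capsule_radius,
                 tuple(round(c, 1) for c in vois.capsule_center))

        stage = "segmentation"
        sc = config.segmentation
        stats = segmentation.fit_soft_tissue(volume, vois.voi_capsule)
        lat_params = segmentation.lat_thresholds(stats, alpha=sc.alpha)
        log.info("soft tissue: μ=%.2f σ=%.2f H_max=%.2f → T_low=%.2f T_high=%.2f",
                 stats.mu_st, stats.sigma_st, stats.h_max, lat_params.t_low,
                 lat_params.t_high)
        if sc.method == "gt":
            thr = sc.gt_threshold if sc.gt_threshold is not None else lat_params.t_high
            mask = segmentation.gt_segment(volume, vois.voi_capsule, thr)
        elif sc.method == "lat":
            mask = segmentation.lat_segment(volume, vois.voi_capsule, lat_params, stats)
        elif sc.method == "ms":
            enhanced = segmentation.multiscale_enhance(volume, vois.voi_capsule, sc.ms)
            mask = segmentation.ms_segment(enhanced, vois.voi_capsule)
        else:  # mslat
            mask = segmentation.mslat_segment(volume, vois.voi_1s, vois.voi_2s,
                                              stats, lat_params, sc.ms)
        stage = "corrections"
        add = read_mask(sc.add_mask)[0] if sc.add_mask else None
        remove = read_mask(sc.remove_mask)[0] if sc.remove_mask else None
        if add is not None or remove is not None:
            mask = segmentation.apply_corrections(mask, add, remove)
        _save(mask, f"vessels_{sc.method}")

        stage = "morphometry"
        results = morphometry.per_voi_report(mask, vois, sp,
                                             bin_width_um=config.bin_width_um)
        frame = pd.DataFrame([r.to_row() for r in results])
        frame.to_csv(out / "morphometry.csv", index=False)
        hist_rows = []
        for r in results:
            if r.hist_edges_um is None:
                continue
            for lo, hi, v in zip(r.hist_edges_um[:-1], r.hist_edges_um[1:],
                                 r.hist_volume_mm3):
                hist_rows.append({"voi": r.label, "bin_lo_um": lo, "bin_hi_um": hi,
                                  "volume_mm3": v})
        pd.DataFrame(hist_rows).to_csv(out / "thickness_histogram.csv", index=False)

        provenance = {
            "angioct_version": __version__,
            "config": config_to_dict(config),
            "voxel_size_um": sp,
            "soft_tissue": {"mu_st": stats.mu_st, "sigma_st": stats.sigma_st,
                            "h_max": stats.h_max, "tau": stats.tau,
                            "t_low": lat_params.t_low, "t_high": lat_params.t_high},
            "capsule": {"center_um": list(vois.capsule_center),
                        "radius_um": vois.capsule_radius},
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=_jsonify))
        (out / "morphometry.json").write_text(
            json.dumps([_jsonify_row(r.to_row()) for r in results], indent=2))
    except (ValueError, RuntimeError) as exc:
        raise StageError(stage, exc) from exc
    return out


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _jsonify_row(row: dict) -> dict:
    return {k: (v.item() if isinstance(v, (np.floating, np.integer)) else v)
            for k, v in row.items()}
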