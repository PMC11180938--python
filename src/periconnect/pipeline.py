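"""End-to-end single-subject pipeline and run reproducibility plumbing.

``run_pipeline`` chains the stages on one subject: WMH parcellation by depth
and lobe, per-parcel probabilistic tractography to the WM/GM boundary,
nested low/medium/high ROI definition with regional rROIs, metric ratio
computation for thickness and the three SUVR maps, and (optionally) the
month-12 ratios inside the baseline ROIs.  Outputs are a tidy ratio table,
JSON sidecars with thresholds and surface sizes, and a manifest recording
the configuration, master seed and SHA-256 hashes of the written tables, so
identical config + seed reproduces byte-identical outputs.

Seeds are derived hierarchically (master -> parcel -> seed voxel), so
results do not depend on execution order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import connectivity as conn
from . import lesions, ratios as ratios_mod
from .phantom import (
    CORTICAL_REGIONS,
    LOBAR_WM_LABELS,
    TISSUE_LABELS,
    Phantom,
    PhantomConfig,
    make_followup,
    make_phantom,
)
from .volumes import Volume, write_volume

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "write_phantom", "load_run_config"]

_SUVR_METRICS = ("abeta", "tau", "sv2a")


@dataclass
class RunConfig:
    """All knobs for one pipeline run; serialized next to the outputs."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    samples_per_voxel: int = 5000
    step_mm: float | None = None
    max_steps: int = 2000
    curvature_threshold_deg: float = 80.0
    tau_low_percent: float = conn.LOW_THRESHOLD_PERCENT
    level_fractions: dict[str, float] = field(
        default_factory=lambda: dict(conn.LEVEL_FRACTIONS)
    )
    min_voxels: int = 10
    fwhm_mm: float = 5.0
    pv_threshold_mm: float = 10.0
    alpha: float = 0.05
    seed: int = 0
    include_followup: bool = True

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"]["lesion_specs"] = [list(s) for s in d["phantom"]["lesion_specs"]]
        return d


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    ph_raw = raw.pop("phantom", {})
    if "lesion_specs" in ph_raw:
        ph_raw["lesion_specs"] = [tuple(s) for s in ph_raw["lesion_specs"]]
    if "annual_change" in ph_raw:
        ph_raw["annual_change"] = tuple(ph_raw["annual_change"])
    cfg = RunConfig(phantom=PhantomConfig(**ph_raw), **raw)
    return cfg


@dataclass
class PipelineResult:
    ratio_table: pd.DataFrame
    roi_sets: dict[str, conn.RoiSet]
    parcels: lesions.WmhParcels
    sidecar: dict
    phantom: Phantom


def _parcel_seed(master: int, parcel_index: int) -> int:
    return int(np.random.SeedSequence([int(master), 7919, parcel_index]).generate_state(1)[0]
               % (2**31 - 1))


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full single-subject analysis on a synthetic phantom."""
    phantom = make_phantom(dataclasses.replace(config.phantom, seed=config.seed))
    tissue = phantom.tissue
    boundary = tissue.like((tissue.data == TISSUE_LABELS["wm_gm_boundary"]).astype(np.uint8))
    brain = tissue.like((tissue.data > 0).astype(np.uint8))
    ventricles = tissue.like((tissue.data == TISSUE_LABELS["ventricle"]).astype(np.uint8))
    cereb = tissue.like((tissue.data == TISSUE_LABELS["cerebellum_ref"]).astype(np.uint8))

    parcels = lesions.parcellate_wmh(
        phantom.wmh, ventricles, phantom.lobes, LOBAR_WM_LABELS,
        threshold_mm=config.pv_threshold_mm,
    )

    # boundary metrics: raw thickness + smoothed SUVR maps
    region_labels = phantom.region_labels()
    metrics: dict[str, ratios_mod.SurfaceMetric] = {
        "thickness": ratios_mod.SurfaceMetric(
            name="thickness",
            values=phantom.metrics["thickness"].data,
            boundary_mask=boundary.data > 0,
            spacing_mm=tissue.spacing,
            units="mm",
        )
    }
    for tracer in _SUVR_METRICS:
        raw = ratios_mod.suvr_map(phantom.metrics[tracer], cereb, boundary, name=tracer)
        metrics[tracer] = ratios_mod.surface_smooth(raw, fwhm_mm=config.fwhm_mm)

    followup_metric = None
    if config.include_followup:
        fup = make_followup(phantom)
        followup_metric = ratios_mod.SurfaceMetric(
            name="thickness",
            values=fup.metrics["thickness"].data,
            boundary_mask=boundary.data > 0,
            spacing_mm=tissue.spacing,
            units="mm",
            timepoint="month12",
        )

    # per-parcel tractography and ratios
    seed_masks: dict[str, np.ndarray] = {
        f"{depth}_{lobe}": mask for (depth, lobe), mask in parcels.parcels.items()
    }
    seed_masks["total_pWMH"] = parcels.total_pwmh
    seed_masks["total_dWMH"] = parcels.total_dwmh

    roi_sets: dict[str, conn.RoiSet] = {}
    all_records: list[ratios_mod.RatioRecord] = []
    sidecar: dict = {"parcels": {}, "config": config.to_jsonable()}
    subject = f"phantom-{config.seed}"
    for pi, (parcel_name, mask) in enumerate(sorted(seed_masks.items())):
        if not mask.any():
            continue
        params = conn.TrackingParams(
            samples_per_voxel=config.samples_per_voxel,
            step_mm=config.step_mm,
            max_steps=config.max_steps,
            curvature_threshold_deg=config.curvature_threshold_deg,
            seed=_parcel_seed(config.seed, pi),
        )
        cmap = conn.track(tissue.like(mask.astype(np.uint8)), phantom.field,
                          boundary, brain, params)
        roi_set = conn.build_roi_set(
            cmap, region_labels, CORTICAL_REGIONS,
            tau_low_percent=config.tau_low_percent,
            level_fractions=config.level_fractions,
        )
        roi_sets[parcel_name] = roi_set
        sidecar["parcels"][parcel_name] = {
            "total_streamlines": cmap.total_streamlines,
            "successes": cmap.successes,
            "levels": {
                lvl: {"threshold": lr.threshold, "surface_size": lr.size}
                for lvl, lr in roi_set.levels.items()
            },
        }
        for metric in metrics.values():
            recs = ratios_mod.regional_ratios(
                metric, roi_set, min_voxels=config.min_voxels,
                subject=subject, parcel=parcel_name,
            )
            all_records.extend(recs.values())
        if followup_metric is not None:
            recs = ratios_mod.longitudinal_ratio(
                roi_set, followup_metric, min_voxels=config.min_voxels,
                subject=subject, parcel=parcel_name,
            )
            all_records.extend(recs.values())

    table = pd.DataFrame(ratios_mod.records_to_rows(all_records))
    result = PipelineResult(
        ratio_table=table, roi_sets=roi_sets, parcels=parcels,
        sidecar=sidecar, phantom=phantom,
    )
    if out_dir is not None:
        _write_outputs(result, config, Path(out_dir))
    return result


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_outputs(result: PipelineResult, config: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    ratio_csv = out_dir / "ratios.csv"
    result.ratio_table.to_csv(ratio_csv, index=False)
    vol_csv = out_dir / "wmh_volumes.csv"
    pd.DataFrame([result.parcels.volumes_ml]).to_csv(vol_csv, index=False)
    sidecar_json = out_dir / "rois.json"
    sidecar_json.write_text(json.dumps(result.sidecar, indent=2, sort_keys=True))
    manifest = {
        "seed": config.seed,
        "config": config.to_jsonable(),
        "outputs": {
            p.name: _sha256(p) for p in (ratio_csv, vol_csv, sidecar_json)
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def write_phantom(phantom: Phantom, out_dir: str | Path) -> None:
    """Write all phantom volumes as NIfTI plus the truth record as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(phantom.tissue, out / "tissue.nii.gz")
    write_volume(phantom.lobes, out / "lobes.nii.gz")
    write_volume(phantom.wmh, out / "wmh.nii.gz")
    for name, vol in phantom.metrics.items():
        write_volume(vol, out / f"metric_{name}.nii.gz")
    affine = phantom.tissue.affine
    write_volume(Volume(phantom.truth.connected_mask.astype(np.uint8), affine),
                 out / "truth_connected.nii.gz")
    (out / "truth.json").write_text(json.dumps(phantom.truth.to_jsonable(), indent=2))
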