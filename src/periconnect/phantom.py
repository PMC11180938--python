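"""Synthetic brain phantom with planted ground truth.

The phantom is a concentric "onion" brain on a regular voxel grid: an
ellipsoidal ventricle system at the center, a white-matter (WM) shell around
it, a 1-3 voxel gray-matter ribbon at the outside, and the WM/GM boundary as
the layer of WM voxels 26-adjacent to the ribbon.  A small spherical
"cerebellum" reference compartment for SUVR normalization is carved out of the
inferior WM.  Six named cortical regions (frontal, temporal, parietal,
occipital, cingulate, insula) partition the ribbon and boundary by angular
sectors and para-midline bands; four lobar WM labels partition the white
matter.

The fiber orientation field is radial (local ventricle-to-cortex direction),
so probabilistic streamlines seeded inside a WM lesion propagate outward and
terminate in the patch of boundary directly overlying the lesion.  That patch
is the ground-truth "connected cortex": a boundary voxel belongs to it when
the ray from the radial origin through the voxel center passes through the
lesion.  Metric maps (cortical thickness, tracer uptake for amyloid, tau and
SV2A PET) take region-specific baseline values, multiplied by a planted
effect inside the true connected patch and by mean-one lognormal noise, so
every planted ROI/rROI ratio is recovered exactly by averaging over the truth
masks when the noise is switched off.

Cohorts emulate a memory-clinic study: per-subject demographics, WMH load,
per-metric true ratios drawn around the planted effect, and a cognitive score
generated from a linear model in the ratios and covariates.  A longitudinal
subset carries 12-month follow-up values with a planted faster decline of the
connected-cortex thickness ratio than of cognition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .connectivity import OrientationField
from .volumes import Volume

__all__ = [
    "PhantomConfig",
    "Phantom",
    "PhantomTruth",
    "CognitionModel",
    "Cohort",
    "LesionPlacementError",
    "TISSUE_LABELS",
    "CORTICAL_REGIONS",
    "LOBAR_WM_LABELS",
    "make_phantom",
    "make_cohort",
    "make_followup",
]

TISSUE_LABELS = {
    "background": 0,
    "ventricle": 1,
    "white_matter": 2,
    "gm_ribbon": 3,
    "wm_gm_boundary": 4,
    "cerebellum_ref": 5,
}

CORTICAL_REGIONS = {
    "frontal": 1,
    "temporal": 2,
    "parietal": 3,
    "occipital": 4,
    "cingulate": 5,
    "insula": 6,
}

#: Lobar white-matter labels (offset by 10 to stay disjoint from cortical ones).
LOBAR_WM_LABELS = {"frontal": 11, "temporal": 12, "parietal": 13, "occipital": 14}

METRICS = ("thickness", "abeta", "tau", "sv2a")

# Region-specific baseline values. Thickness in mm, uptake in arbitrary
# activity units (the cerebellum reference below turns them into SUVR).
_THICKNESS_BASE = {
    "frontal": 2.6,
    "temporal": 2.8,
    "parietal": 2.4,
    "occipital": 2.0,
    "cingulate": 2.5,
    "insula": 3.0,
}
_UPTAKE_BASE = {
    "abeta": {"frontal": 1.5, "temporal": 1.4, "parietal": 1.5, "occipital": 1.3,
              "cingulate": 1.6, "insula": 1.4},
    "tau": {"frontal": 1.2, "temporal": 1.7, "parietal": 1.5, "occipital": 1.2,
            "cingulate": 1.3, "insula": 1.3},
    "sv2a": {"frontal": 5.0, "temporal": 5.4, "parietal": 5.0, "occipital": 4.6,
             "cingulate": 5.2, "insula": 5.6},
}
_CEREBELLUM_UPTAKE = 1.0
_WM_UPTAKE = {"abeta": 1.8, "tau": 0.9, "sv2a": 2.5}


class LesionPlacementError(ValueError):
    """A lesion spec cannot be satisfied on the configured grid."""


@dataclass
class CognitionModel:
    """Linear model for the cohort cognitive score.

    ``score = intercept + sum_m beta[m] * ratio_m + beta_age*age +
    beta_education*education + beta_wmh*wmh_volume + N(0, residual_sd)``.

    The default slope on the amyloid ratio (-37.8 per unit ratio) mirrors the
    magnitude of the association between connected-cortex amyloid burden and
    memory scores seen in amyloid-positive clinical cohorts.
    """

    intercept: float = 65.0
    beta: dict[str, float] = field(
        default_factory=lambda: {"thickness": 0.0, "abeta": -37.8, "tau": 0.0, "sv2a": 0.0}
    )
    beta_age: float = -0.10
    beta_education: float = 0.30
    beta_wmh: float = -0.10
    residual_sd: float = 4.0


def _default_lesions() -> list[tuple[str, str, float]]:
    # One periventricular + one deep lesion per lobe -> all 8 WMH parcels.
    return [
        (lobe, depth, 4.0)
        for lobe in ("frontal", "temporal", "parietal", "occipital")
        for depth in ("periventricular", "deep")
    ]


@dataclass
class PhantomConfig:
    """Everything the generator needs; identical config + seed is bit-reproducible."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    seed: int = 0
    lesion_specs: list[tuple[str, str, float]] = field(default_factory=_default_lesions)
    #: Planted connected/unconnected ratio per metric (< 1 = lower in
    #: connected cortex). Defaults follow the effect sizes reported for
    #: WMH-connected cortex: mild thinning, amyloid excess, tau excess,
    #: synaptic density loss.
    metric_effects: dict[str, float] = field(
        default_factory=lambda: {"thickness": 0.95, "abeta": 1.045, "tau": 1.05, "sv2a": 0.92}
    )
    noise_sd_frac: float = 0.05
    #: Planted 12-month thickness change (mm) in (connected, unconnected) cortex.
    annual_change: tuple[float, float] = (-0.10, -0.02)
    #: Cohort sizes per diagnostic group.
    n_ad: int = 59
    n_mci: int = 27
    n_cn: int = 21
    cognition_model: CognitionModel = field(default_factory=CognitionModel)
    #: Between-subject SD of the true per-metric ratio in the cohort.
    cohort_ratio_sd: dict[str, float] = field(
        default_factory=lambda: {"thickness": 0.035, "abeta": 0.041, "tau": 0.10, "sv2a": 0.038}
    )
    #: Longitudinal sub-cohort: size, 12-month MMSE change (mean, sd) and
    #: 12-month thickness-ratio change (mean, sd).
    n_followup: int = 23
    mmse_change: tuple[float, float] = (-1.8, 3.0)
    ratio_change: tuple[float, float] = (-0.033, 0.02)
    #: Angular dispersion (degrees) of the phantom orientation field.
    dispersion_deg: float = 10.0
    #: Distance threshold (mm) separating periventricular from deep lesions.
    pv_threshold_mm: float = 10.0

    def validate(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid too small for the concentric geometry")
        for lobe, depth, radius in self.lesion_specs:
            if radius <= 0:
                raise ValueError(f"lesion radius must be > 0, got {radius}")
            if lobe not in LOBAR_WM_LABELS:
                raise ValueError(f"unknown lobe {lobe!r}")
            if depth not in ("periventricular", "deep"):
                raise ValueError(f"unknown depth class {depth!r}")
        for m, eff in self.metric_effects.items():
            if eff <= 0:
                raise ValueError(f"metric effect for {m} must be > 0")
        if self.noise_sd_frac < 0:
            raise ValueError("noise_sd_frac must be >= 0")
        if min(self.n_ad, self.n_mci, self.n_cn) < 0:
            raise ValueError("cohort sizes must be >= 0")


@dataclass
class PhantomTruth:
    """Ground truth planted by the generator."""

    #: Boundary mask of the union of per-lesion connected patches.
    connected_mask: np.ndarray
    #: Per-lesion connected patches, same order as ``lesion_specs``.
    lesion_patches: list[np.ndarray]
    #: Per-lesion binary masks.
    lesion_masks: list[np.ndarray]
    planted_effects: dict[str, float]
    annual_change: tuple[float, float]
    cognition: CognitionModel

    def to_jsonable(self) -> dict:
        return {
            "planted_effects": self.planted_effects,
            "annual_change": list(self.annual_change),
            "n_connected_boundary_voxels": int(self.connected_mask.sum()),
            "lesion_voxel_counts": [int(m.sum()) for m in self.lesion_masks],
            "cognition": dataclasses.asdict(self.cognition),
        }


@dataclass
class Phantom:
    """A complete synthetic subject."""

    tissue: Volume
    lobes: Volume
    wmh: Volume
    field: OrientationField
    metrics: dict[str, Volume]
    truth: PhantomTruth
    config: PhantomConfig
    timepoint: str = "baseline"

    @property
    def brain_mask(self) -> np.ndarray:
        return self.tissue.data > 0

    @property
    def boundary_mask(self) -> np.ndarray:
        return self.tissue.data == TISSUE_LABELS["wm_gm_boundary"]

    def region_labels(self) -> np.ndarray:
        """Cortical region labels (1..6) restricted to the boundary."""
        return np.where(self.boundary_mask, self.lobes.data, 0)

    def lobar_wm_labels(self) -> np.ndarray:
        labels = self.lobes.data
        return np.where(labels >= 10, labels, 0)


# ---------------------------------------------------------------------------
# geometry helpers


def _grid_coords_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _lognormal_noise(rng: np.random.Generator, sd_frac: float, shape) -> np.ndarray:
    """Multiplicative mean-one lognormal noise with SD/mean = sd_frac."""
    if sd_frac == 0:
        return np.ones(shape)
    s2 = np.log1p(sd_frac**2)
    return rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=shape)


def _cortical_region_of(dx, dy, dz):
    """Vectorized region assignment from mm offsets relative to the center."""
    r = np.sqrt(dx**2 + dy**2 + dz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        el = np.degrees(np.arcsin(np.clip(np.where(r > 0, dz / r, 0.0), -1, 1)))
    region = np.zeros(dx.shape, dtype=np.int16)
    absx = np.abs(dx)
    region[absx < 6.0] = CORTICAL_REGIONS["cingulate"]
    free = region == 0
    region[free & (absx < 14.0)] = CORTICAL_REGIONS["insula"]
    free = region == 0
    region[free & (el >= 40.0)] = CORTICAL_REGIONS["parietal"]
    free = region == 0
    region[free & (el <= -40.0)] = CORTICAL_REGIONS["temporal"]
    free = region == 0
    region[free & (dy >= 0)] = CORTICAL_REGIONS["frontal"]
    free = region == 0
    region[free] = CORTICAL_REGIONS["occipital"]
    return region


def _lobar_wm_of(dx, dy, dz):
    """4-way lobar WM labels: the cortical rule without the midline bands."""
    r = np.sqrt(dx**2 + dy**2 + dz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        el = np.degrees(np.arcsin(np.clip(np.where(r > 0, dz / r, 0.0), -1, 1)))
    lobe = np.zeros(dx.shape, dtype=np.int16)
    lobe[el >= 40.0] = LOBAR_WM_LABELS["parietal"]
    free = lobe == 0
    lobe[free & (el <= -40.0)] = LOBAR_WM_LABELS["temporal"]
    free = lobe == 0
    lobe[free & (dy >= 0)] = LOBAR_WM_LABELS["frontal"]
    free = lobe == 0
    lobe[free] = LOBAR_WM_LABELS["occipital"]
    return lobe


def _place_lesion(
    lobe: str,
    depth: str,
    radius: float,
    wm_mask: np.ndarray,
    lobar_wm: np.ndarray,
    vent_dist: np.ndarray,
    wm_interior_dist: np.ndarray,
    taken: np.ndarray,
    coords,
    spacing,
    pv_threshold: float,
) -> np.ndarray:
    """Deterministically pick a lesion center and rasterize a spherical lesion.

    Candidate centers must let the whole ball sit inside white matter
    (``wm_interior_dist >= radius``), avoid already-placed lesions, and meet
    the requested depth class relative to the ventricle distance map.
    """
    margin = 0.5 * min(spacing)
    fits = (wm_interior_dist >= radius + margin) & (lobar_wm == LOBAR_WM_LABELS[lobe]) & ~taken
    if depth == "deep":
        ok = fits & (vent_dist >= pv_threshold + radius + margin)
        # prefer the deepest-in-WM candidate
        score = np.where(ok, wm_interior_dist, -np.inf)
    else:
        ok = fits & (vent_dist < pv_threshold)
        # prefer candidates comfortably inside WM but still close to the ventricle
        score = np.where(ok, wm_interior_dist - 0.25 * vent_dist, -np.inf)
    if not ok.any():
        raise LesionPlacementError(
            f"no admissible center for a {depth} lesion of radius {radius} mm in the {lobe} lobe"
        )
    center_flat = int(np.argmax(score))  # deterministic tie-break: lowest flat index
    cidx = np.unravel_index(center_flat, wm_mask.shape)
    d2 = sum(((coords[a] - coords[a][cidx]) ** 2 for a in range(3)))
    lesion = (d2 <= radius**2) & wm_mask
    if not lesion.any():
        raise LesionPlacementError(f"lesion ({lobe}, {depth}, {radius} mm) rasterized empty")
    return lesion


def _connected_patch(
    boundary_mask: np.ndarray,
    lesion_mask: np.ndarray,
    center_mm: np.ndarray,
    spacing: np.ndarray,
) -> np.ndarray:
    """Boundary voxels radially overlying the lesion (the connected patch).

    Deterministic outward marching from a dense sub-voxel grid of start
    points inside every lesion voxel cube, following the phantom's own
    radial direction (evaluated, like the field, at the current voxel
    center); each path marks the first boundary voxel it enters.  This is
    the noise-free limit of the patch a dispersion-free tracker samples
    stochastically, since streamline start positions jitter uniformly over
    the same lesion cubes.
    """
    offs = np.linspace(-0.48, 0.48, 6)
    sub = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), -1).reshape(-1, 3)
    lesion_idx = np.argwhere(lesion_mask)
    pos = (lesion_idx[:, None, :] + sub[None, :, :]).reshape(-1, 3) * spacing
    step = 0.5 * float(min(spacing))
    shape_arr = np.asarray(boundary_mask.shape)
    max_steps = int(np.ceil(np.linalg.norm(shape_arr * spacing) / step)) + 2
    patch = np.zeros(boundary_mask.shape, dtype=bool)
    live = np.ones(len(pos), dtype=bool)
    for _ in range(max_steps):
        li = np.flatnonzero(live)
        if li.size == 0:
            break
        vox = np.rint(pos[li] / spacing).astype(int)
        vox = np.clip(vox, 0, shape_arr - 1)
        d = vox * spacing - center_mm
        norms = np.linalg.norm(d, axis=1)
        norms[norms == 0] = 1.0
        pos[li] += step * d / norms[:, None]
        nvox = np.rint(pos[li] / spacing).astype(int)
        inside = np.all((nvox >= 0) & (nvox < shape_arr), axis=1)
        live[li[~inside]] = False
        vi = nvox[inside]
        hit = boundary_mask[vi[:, 0], vi[:, 1], vi[:, 2]]
        if hit.any():
            hv = vi[hit]
            patch[hv[:, 0], hv[:, 1], hv[:, 2]] = True
            live[li[inside][hit]] = False
    return patch


# ---------------------------------------------------------------------------
# public constructors


def make_phantom(config: PhantomConfig) -> Phantom:
    """Build one synthetic subject with planted ground truth."""
    config.validate()
    shape = tuple(config.grid_shape)
    spacing = np.asarray(config.spacing_mm, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x9E3779B9]))

    coords = _grid_coords_mm(shape, spacing)
    half = (np.asarray(shape) - 1) / 2.0 * spacing
    center = half.copy()
    dx, dy, dz = (coords[a] - center[a] for a in range(3))

    brain_ax = 0.85 * half
    vent_ax = np.array([0.22, 0.32, 0.16]) * half
    rho_brain = np.sqrt((dx / brain_ax[0]) ** 2 + (dy / brain_ax[1]) ** 2 + (dz / brain_ax[2]) ** 2)
    rho_vent = np.sqrt((dx / vent_ax[0]) ** 2 + (dy / vent_ax[1]) ** 2 + (dz / vent_ax[2]) ** 2)

    ribbon_frac = 2.2 * float(max(spacing)) / float(min(brain_ax))
    brain = rho_brain <= 1.0
    ventricle = rho_vent <= 1.0
    ribbon = brain & (rho_brain > 1.0 - ribbon_frac) & ~ventricle
    wm = brain & ~ribbon & ~ventricle

    # cerebellum reference: a small sphere carved out of the inferior WM
    cereb_center = center + np.array([0.0, 0.0, -0.68 * brain_ax[2]])
    cereb_r = 0.16 * brain_ax[2]
    cereb = (
        (coords[0] - cereb_center[0]) ** 2
        + (coords[1] - cereb_center[1]) ** 2
        + (coords[2] - cereb_center[2]) ** 2
    ) <= cereb_r**2
    cereb &= wm
    wm &= ~cereb

    # WM/GM boundary: WM voxels 26-adjacent to the ribbon
    struct = np.ones((3, 3, 3), dtype=bool)
    boundary = wm & ndimage.binary_dilation(ribbon, structure=struct)
    wm_only = wm & ~boundary

    tissue = np.zeros(shape, dtype=np.int16)
    tissue[ventricle] = TISSUE_LABELS["ventricle"]
    tissue[wm_only] = TISSUE_LABELS["white_matter"]
    tissue[ribbon] = TISSUE_LABELS["gm_ribbon"]
    tissue[boundary] = TISSUE_LABELS["wm_gm_boundary"]
    tissue[cereb] = TISSUE_LABELS["cerebellum_ref"]

    # lobar labels: cortical regions on ribbon+boundary, WM lobes elsewhere in WM
    cortical = _cortical_region_of(dx, dy, dz)
    lobar_wm = _lobar_wm_of(dx, dy, dz)
    lobes = np.zeros(shape, dtype=np.int16)
    cortex_like = ribbon | boundary
    lobes[cortex_like] = cortical[cortex_like]
    lobes[wm_only] = lobar_wm[wm_only]

    n_boundary = int(boundary.sum())
    for name, lab in CORTICAL_REGIONS.items():
        frac = float((lobes[boundary] == lab).sum()) / max(n_boundary, 1)
        if frac < 0.01:
            raise LesionPlacementError(
                f"cortical region {name} holds {frac:.2%} of boundary voxels (< 1%)"
            )

    # lesion placement against the ventricle distance transform
    vent_dist = ndimage.distance_transform_edt(tissue != TISSUE_LABELS["ventricle"],
                                               sampling=spacing)
    wm_interior = ndimage.distance_transform_edt(
        tissue == TISSUE_LABELS["white_matter"], sampling=spacing
    )
    taken = np.zeros(shape, dtype=bool)
    lesion_masks: list[np.ndarray] = []
    for lobe, depth, radius in config.lesion_specs:
        lesion = _place_lesion(
            lobe, depth, radius, tissue == TISSUE_LABELS["white_matter"], lobar_wm,
            vent_dist, wm_interior, taken, coords, spacing, config.pv_threshold_mm,
        )
        dmin = float(vent_dist[lesion].min())
        if depth == "deep" and dmin < config.pv_threshold_mm:
            raise LesionPlacementError(
                f"deep lesion in {lobe} has min ventricle distance {dmin:.2f} mm < threshold"
            )
        if depth == "periventricular" and dmin >= config.pv_threshold_mm:
            raise LesionPlacementError(
                f"periventricular lesion in {lobe} has min ventricle distance {dmin:.2f} mm"
            )
        lesion_masks.append(lesion)
        taken |= ndimage.binary_dilation(lesion, structure=struct, iterations=2)

    wmh = np.zeros(shape, dtype=np.uint8)
    for lesion in lesion_masks:
        wmh[lesion] = 1

    # radial orientation field on WM + WMH + boundary
    support = (tissue == TISSUE_LABELS["white_matter"]) | boundary | (wmh > 0)
    rad = np.sqrt(dx**2 + dy**2 + dz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = np.stack([dx, dy, dz], axis=-1) / np.where(rad > 0, rad, 1.0)[..., None]
    dirs = dirs.astype(np.float32)
    dirs[~support] = 0.0
    dispersion = np.where(support, float(config.dispersion_deg), 0.0).astype(np.float32)
    field_ = OrientationField(directions=dirs, dispersion_deg=dispersion, support=support)

    # ground-truth connected patches
    patches = []
    for lesion in lesion_masks:
        patches.append(_connected_patch(boundary, lesion, center, spacing))
    connected = np.zeros(shape, dtype=bool)
    for p in patches:
        connected |= p

    # metric maps
    affine = np.diag([*spacing, 1.0])
    metrics: dict[str, Volume] = {}
    region_on_boundary = np.where(boundary, lobes, 0)
    thick = np.zeros(shape, dtype=np.float64)
    for name, lab in CORTICAL_REGIONS.items():
        thick[region_on_boundary == lab] = _THICKNESS_BASE[name]
    eff = config.metric_effects.get("thickness", 1.0)
    thick[connected] *= eff
    thick[boundary] *= _lognormal_noise(rng, config.noise_sd_frac, int(boundary.sum()))
    metrics["thickness"] = Volume(thick, affine)

    for tracer in ("abeta", "tau", "sv2a"):
        uptake = np.zeros(shape, dtype=np.float64)
        uptake[tissue == TISSUE_LABELS["cerebellum_ref"]] = _CEREBELLUM_UPTAKE
        uptake[tissue == TISSUE_LABELS["white_matter"]] = _WM_UPTAKE[tracer]
        for name, lab in CORTICAL_REGIONS.items():
            sel = cortex_like & (lobes == lab)
            uptake[sel] = _UPTAKE_BASE[tracer][name]
        uptake[connected] *= config.metric_effects.get(tracer, 1.0)
        nz = uptake > 0
        uptake[nz] *= _lognormal_noise(rng, config.noise_sd_frac, int(nz.sum()))
        metrics[tracer] = Volume(uptake, affine)

    truth = PhantomTruth(
        connected_mask=connected,
        lesion_patches=patches,
        lesion_masks=lesion_masks,
        planted_effects=dict(config.metric_effects),
        annual_change=tuple(config.annual_change),
        cognition=config.cognition_model,
    )
    return Phantom(
        tissue=Volume(tissue, affine),
        lobes=Volume(lobes, affine),
        wmh=Volume(wmh, affine),
        field=field_,
        metrics=metrics,
        truth=truth,
        config=config,
    )


def make_followup(phantom: Phantom, config: PhantomConfig | None = None) -> Phantom:
    """Month-12 copy of a phantom: planted thinning added to the thickness map.

    Geometry, lesions, orientation field and PET maps are unchanged; only the
    thickness map moves, by ``annual_change[0]`` mm inside the true connected
    patch and ``annual_change[1]`` mm elsewhere on the boundary, then fresh
    multiplicative noise.
    """
    cfg = config or phantom.config
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x51ED2701]))
    change_conn, change_unconn = cfg.annual_change
    boundary = phantom.boundary_mask
    connected = phantom.truth.connected_mask
    thick = phantom.metrics["thickness"].data.copy()
    thick[boundary] += change_unconn
    thick[connected] += change_conn - change_unconn
    thick[boundary] *= _lognormal_noise(rng, cfg.noise_sd_frac, int(boundary.sum()))
    if (thick[boundary] <= 0).any():
        thick[boundary] = np.maximum(thick[boundary], 1e-3)
    metrics = dict(phantom.metrics)
    metrics["thickness"] = phantom.metrics["thickness"].like(thick)
    return dataclasses.replace(phantom, metrics=metrics, timepoint="month12")


# ---------------------------------------------------------------------------
# cohort


@dataclass
class Cohort:
    """Subject table plus per-subject phantom configs (phantoms built lazily)."""

    table: pd.DataFrame
    subject_configs: list[PhantomConfig]

    def phantom(self, i: int) -> Phantom:
        return make_phantom(self.subject_configs[i])


_GROUP_AGE = {"AD": (70.7, 8.0), "MCI": (71.1, 7.0), "CN": (70.0, 8.0)}


def make_cohort(config: PhantomConfig) -> Cohort:
    """Generate a cohort table with planted ratios, covariates and scores.

    Diagnosis follows the clinical-dementia-rating convention: CDR > 0.5 is
    AD, CDR = 0.5 is MCI, CDR = 0 is cognitively normal.  The 12-month
    follow-up columns (``mmse_m12``, ``ratio_thickness_m12``) are filled for
    the first ``n_followup`` impaired (AD/MCI) subjects and NaN elsewhere.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xC0407]))
    groups = ["AD"] * config.n_ad + ["MCI"] * config.n_mci + ["CN"] * config.n_cn
    n = len(groups)
    cdr = {"AD": 1.0, "MCI": 0.5, "CN": 0.0}

    rows = []
    sub_cfgs: list[PhantomConfig] = []
    child_seeds = np.random.SeedSequence([int(config.seed), 0xC0407, 1]).generate_state(max(n, 1))
    model = config.cognition_model
    for i, grp in enumerate(groups):
        mu_a, sd_a = _GROUP_AGE[grp]
        age = float(rng.normal(mu_a, sd_a))
        edu = float(np.clip(rng.normal(10.7, 4.5), 0, None))
        wmh_vol = float(rng.lognormal(np.log(6.0), 0.8))
        ratios = {
            m: float(max(rng.normal(config.metric_effects.get(m, 1.0),
                                    config.cohort_ratio_sd.get(m, 0.0)), 1e-3))
            for m in METRICS
        }
        score = (
            model.intercept
            + sum(model.beta.get(m, 0.0) * ratios[m] for m in METRICS)
            + model.beta_age * age
            + model.beta_education * edu
            + model.beta_wmh * wmh_vol
            + (rng.normal(0.0, model.residual_sd) if model.residual_sd > 0 else 0.0)
        )
        mmse = float(np.clip(rng.normal(21.2, 6.6), 0, 30))
        rows.append(
            {
                "subject": f"sub-{i:03d}",
                "group": grp,
                "cdr": cdr[grp],
                "age": age,
                "education_yrs": edu,
                "wmh_volume_ml": wmh_vol,
                **{f"ratio_{m}": ratios[m] for m in METRICS},
                "score": float(score),
                "mmse": mmse,
                "mmse_m12": np.nan,
                "ratio_thickness_m12": np.nan,
            }
        )
        sub_cfg = dataclasses.replace(
            config,
            seed=int(child_seeds[i] % (2**31 - 1)),
            metric_effects=ratios,
            n_ad=0, n_mci=0, n_cn=0,
        )
        sub_cfgs.append(sub_cfg)

    table = pd.DataFrame(rows)
    impaired = table.index[table["group"].isin(["AD", "MCI"])][: config.n_followup]
    dm, ds = config.mmse_change
    rm, rs = config.ratio_change
    for idx in impaired:
        table.loc[idx, "mmse_m12"] = float(
            np.clip(table.loc[idx, "mmse"] + rng.normal(dm, ds), 0, 30)
        )
        table.loc[idx, "ratio_thickness_m12"] = float(
            table.loc[idx, "ratio_thickness"] + rng.normal(rm, rs)
        )
    return Cohort(table=table, subject_configs=sub_cfgs)
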