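"""Probabilistic streamline tracking from lesion seeds to the WM/GM boundary.

The tracker is a minimal voxel-space probabilistic streamline sampler over a
given per-voxel fiber orientation field.  Each seed voxel emits
``samples_per_voxel`` streamlines (default 5000) from uniformly jittered
start positions.  At every step the local principal direction is perturbed by
the local angular dispersion, sign-aligned with the previous step, and the
position advances by ``step_mm``.  A streamline succeeds on first entry into
a target (boundary) voxel, and fails on leaving the brain mask or the grid,
losing orientation support, exceeding the curvature threshold, or running out
of steps.  Success counts per boundary voxel, normalized by the total number
of emitted streamlines, form the connectivity probability map.

Connected-cortex ROIs are carved from the probability map at three nested
levels: a fixed low probability threshold (3.08e-5 percent of emitted
streamlines), then adaptive count thresholds chosen so the surface size
shrinks to 50% (medium) and 25% (high) of the low-level surface size.  The
reference rROI at each level is the remainder of the boundary; per cortical
region the rROI is the region's share of that global complement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .volumes import Volume, check_same_grid

__all__ = [
    "OrientationField",
    "TrackingParams",
    "ConnectivityMap",
    "RoiSet",
    "LevelRois",
    "track",
    "low_roi",
    "adaptive_roi",
    "define_rrois",
    "build_roi_set",
    "LOW_THRESHOLD_PERCENT",
    "LEVEL_FRACTIONS",
]

#: Fixed low-level threshold, as a *percent* of total emitted streamlines.
LOW_THRESHOLD_PERCENT = 3.08e-5
#: Adaptive surface-size targets relative to the low-level ROI.
LEVEL_FRACTIONS = {"medium": 0.5, "high": 0.25}


@dataclass
class OrientationField:
    """Per-voxel principal fiber direction and angular dispersion.

    ``directions`` has shape ``(X, Y, Z, 3)`` with unit vectors wherever
    ``support`` is True; ``dispersion_deg`` is the angular SD (degrees) of the
    direction perturbation applied at each tracking step.
    """

    directions: np.ndarray
    dispersion_deg: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        if self.directions.ndim != 4 or self.directions.shape[-1] != 3:
            raise ValueError("directions must have shape (X, Y, Z, 3)")
        if np.any(self.dispersion_deg < 0):
            raise ValueError("dispersion must be >= 0")
        norms = np.linalg.norm(self.directions[self.support], axis=-1)
        if norms.size and not np.allclose(norms, 1.0, atol=1e-4):
            raise ValueError("directions must be unit vectors on the support")


@dataclass
class TrackingParams:
    samples_per_voxel: int = 5000
    step_mm: float | None = None  # default: 0.5 x min voxel spacing
    max_steps: int = 2000
    curvature_threshold_deg: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_voxel < 1:
            raise ValueError("samples_per_voxel must be >= 1")
        if self.step_mm is not None and self.step_mm <= 0:
            raise ValueError("step_mm must be > 0")


@dataclass
class ConnectivityMap:
    """Streamline termination counts on the boundary plus exact accounting."""

    counts: np.ndarray  # int64 full-grid array, nonzero only on the boundary
    total_streamlines: int
    successes: int
    failures: int
    boundary_mask: np.ndarray
    affine: np.ndarray

    @property
    def probability(self) -> np.ndarray:
        return self.counts / float(self.total_streamlines)

    def to_volume(self) -> Volume:
        return Volume(self.counts, self.affine)


@dataclass
class LevelRois:
    roi: np.ndarray  # boundary-voxel mask
    threshold: float  # applied count threshold
    size: int  # boundary-voxel count ("surface size")
    regional_roi: dict[str, np.ndarray] = field(default_factory=dict)
    regional_rroi: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class RoiSet:
    levels: dict[str, LevelRois]
    boundary_mask: np.ndarray

    def rroi(self, level: str) -> np.ndarray:
        return self.boundary_mask & ~self.levels[level].roi


def _perturb(dirs: np.ndarray, sigma_rad: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rotate each unit vector by |N(0, sigma)| toward a uniform azimuth."""
    n = len(dirs)
    out = dirs.copy()
    active = sigma_rad > 0
    if not active.any():
        return out
    d = dirs[active]
    theta = np.abs(rng.normal(0.0, sigma_rad[active]))
    phi = rng.uniform(0.0, 2.0 * np.pi, size=len(d))
    # orthonormal basis per vector
    helper = np.where(np.abs(d[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    perp = np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2
    out[active] = np.cos(theta)[:, None] * d + np.sin(theta)[:, None] * perp
    return out


def track(
    seed: Volume,
    field: OrientationField,
    boundary: Volume,
    brain: Volume,
    params: TrackingParams | None = None,
) -> ConnectivityMap:
    """Sample streamlines from every seed voxel and count boundary terminations.

    Each seed voxel uses its own RNG substream derived from
    ``(params.seed, flat voxel index)``, so results are independent of seed
    ordering and adding seed voxels never changes the counts contributed by
    existing ones.
    """
    params = params or TrackingParams()
    check_same_grid(seed, boundary, brain, names=["seed", "boundary", "brain"])
    shape = seed.shape
    spacing = seed.spacing
    step = params.step_mm if params.step_mm is not None else 0.5 * float(min(spacing))

    seed_mask = seed.data > 0
    boundary_mask = boundary.data > 0
    brain_mask = brain.data > 0
    if not seed_mask.any():
        raise ValueError("seed mask is empty")
    if not boundary_mask.any():
        raise ValueError("boundary mask is empty")
    if not field.support[seed_mask].all():
        raise ValueError("orientation field undefined at one or more seed voxels")

    seeds_idx = np.argwhere(seed_mask)
    flat_ids = np.ravel_multi_index(seeds_idx.T, shape)
    nspv = params.samples_per_voxel
    cos_curv = np.cos(np.radians(params.curvature_threshold_deg))
    shape_arr = np.asarray(shape)

    counts = np.zeros(shape, dtype=np.int64)
    successes = 0
    failures = 0

    for vox, vid in zip(seeds_idx, flat_ids):
        rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), int(vid)]))
        pos = (vox[None, :] + rng.uniform(-0.5, 0.5, size=(nspv, 3))) * spacing
        prev_dir = np.zeros((nspv, 3))
        have_prev = np.zeros(nspv, dtype=bool)
        cur_vox = np.repeat(vox[None, :], nspv, axis=0)
        alive = np.ones(nspv, dtype=bool)

        for _ in range(params.max_steps):
            if not alive.any():
                break
            ai = np.flatnonzero(alive)
            vz = cur_vox[ai]
            base = field.directions[vz[:, 0], vz[:, 1], vz[:, 2]]
            sigma = np.radians(field.dispersion_deg[vz[:, 0], vz[:, 1], vz[:, 2]])
            d = _perturb(base, sigma, rng)
            # sign-align with the previous step (fiber directions are axial)
            hp = have_prev[ai]
            dots = np.einsum("ij,ij->i", d, prev_dir[ai])
            flip = hp & (dots < 0)
            d[flip] *= -1.0
            dots = np.abs(dots)
            # curvature failure
            curved = hp & (dots < cos_curv)
            if curved.any():
                failures += int(curved.sum())
                alive[ai[curved]] = False
                keep = ~curved
                ai = ai[keep]
                d = d[keep]
                if ai.size == 0:
                    continue
            pos[ai] += step * d
            prev_dir[ai] = d
            have_prev[ai] = True
            nvox = np.rint(pos[ai] / spacing).astype(int)
            inside = np.all((nvox >= 0) & (nvox < shape_arr), axis=1)
            nvox_c = np.clip(nvox, 0, shape_arr - 1)
            in_brain = inside & brain_mask[nvox_c[:, 0], nvox_c[:, 1], nvox_c[:, 2]]
            hit = in_brain & boundary_mask[nvox_c[:, 0], nvox_c[:, 1], nvox_c[:, 2]]
            supported = in_brain & field.support[nvox_c[:, 0], nvox_c[:, 1], nvox_c[:, 2]]
            dead = ~in_brain | (~hit & ~supported)
            if hit.any():
                hv = nvox_c[hit]
                np.add.at(counts, (hv[:, 0], hv[:, 1], hv[:, 2]), 1)
                successes += int(hit.sum())
                alive[ai[hit]] = False
            if dead.any():
                failures += int(dead.sum())
                alive[ai[dead]] = False
            moved = ~hit & ~dead
            cur_vox[ai[moved]] = nvox_c[moved]
        # streamlines still alive after max_steps fail
        leftover = int(alive.sum())
        failures += leftover

    total = nspv * len(seeds_idx)
    assert successes + failures == total
    return ConnectivityMap(
        counts=counts,
        total_streamlines=total,
        successes=successes,
        failures=failures,
        boundary_mask=boundary_mask,
        affine=seed.affine.copy(),
    )


def low_roi(cmap: ConnectivityMap, tau_low_percent: float = LOW_THRESHOLD_PERCENT) -> np.ndarray:
    """Boundary voxels whose count reaches the fixed low-probability cutoff.

    The cutoff is ``tau_low_percent / 100 x total_streamlines`` compared
    real-valued against the integer counts (``>=``).
    """
    if cmap.total_streamlines <= 0:
        raise ValueError("total_streamlines must be > 0")
    cutoff = tau_low_percent / 100.0 * cmap.total_streamlines
    return cmap.boundary_mask & (cmap.counts >= cutoff)


def adaptive_roi(
    cmap: ConnectivityMap,
    low_mask: np.ndarray,
    target_fraction: float,
) -> tuple[np.ndarray, float]:
    """Smallest count threshold whose ROI size is <= target_fraction x low size.

    Searches the sorted distinct count values inside the low-level ROI (the
    ROI size is non-increasing in the threshold, so the first admissible value
    gives the maximal ROI under the bound).  If even the highest count class
    is too large, the ROI collapses to empty with a warning.
    """
    low_size = int(low_mask.sum())
    if low_size == 0:
        raise ValueError("low-level ROI is empty")
    target = target_fraction * low_size
    vals = np.unique(cmap.counts[low_mask])
    for t in vals:
        roi = low_mask & (cmap.counts >= t)
        if int(roi.sum()) <= target:
            return roi, float(t)
    warnings.warn(
        "adaptive threshold target unreachable; returning empty ROI", RuntimeWarning
    )
    t = float(vals[-1]) + 1.0
    return low_mask & (cmap.counts >= t), t


def define_rrois(
    roi_set: RoiSet,
    region_labels: np.ndarray,
    region_names: dict[str, int],
) -> RoiSet:
    """Per-level, per-region ROI/rROI partition of the boundary.

    ``ROI_r = ROI & region r``; ``rROI_r`` is the region's share of the
    *global* boundary complement of the full ROI at that level (WMH-unconnected
    cortex), so per region the two partition the region's boundary voxels.
    """
    boundary = roi_set.boundary_mask
    for lvl in roi_set.levels.values():
        unconnected = boundary & ~lvl.roi
        lvl.regional_roi = {}
        lvl.regional_rroi = {}
        for name, lab in region_names.items():
            in_region = boundary & (region_labels == lab)
            lvl.regional_roi[name] = lvl.roi & in_region
            lvl.regional_rroi[name] = unconnected & in_region
    return roi_set


def build_roi_set(
    cmap: ConnectivityMap,
    region_labels: np.ndarray | None = None,
    region_names: dict[str, int] | None = None,
    tau_low_percent: float = LOW_THRESHOLD_PERCENT,
    level_fractions: dict[str, float] | None = None,
) -> RoiSet:
    """Low/medium/high nested ROIs (plus rROIs if region labels are given)."""
    fractions = level_fractions or LEVEL_FRACTIONS
    low = low_roi(cmap, tau_low_percent)
    cutoff = tau_low_percent / 100.0 * cmap.total_streamlines
    levels = {"low": LevelRois(roi=low, threshold=float(cutoff), size=int(low.sum()))}
    for name, frac in fractions.items():
        roi, thr = adaptive_roi(cmap, low, frac)
        levels[name] = LevelRois(roi=roi, threshold=thr, size=int(roi.sum()))
    roi_set = RoiSet(levels=levels, boundary_mask=cmap.boundary_mask)
    if region_labels is not None and region_names is not None:
        define_rrois(roi_set, region_labels, region_names)
    return roi_set
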