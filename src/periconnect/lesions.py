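"""WMH parcellation: periventricular/deep split and lobar parcels.

Lesion masks are classified against a Euclidean distance transform of the
ventricle mask (voxel-center to voxel-center, honoring anisotropic spacing):
voxels closer than the threshold (default 10 mm) are periventricular (pWMH),
voxels at or beyond it are deep (dWMH).  Crossing each depth class with four
lobar white-matter labels yields the eight standard WMH parcels.  Lesion
voxels without a lobar label are excluded from the parcels but retained in
the depth-class totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import Volume, check_same_grid

__all__ = [
    "WmhParcels",
    "ventricle_distance_map",
    "classify_depth",
    "split_by_lobe",
    "wmh_volume",
    "parcellate_wmh",
    "DEPTH_CLASSES",
    "PARCEL_LOBES",
]

DEPTH_CLASSES = ("pWMH", "dWMH")
PARCEL_LOBES = ("frontal", "parietal", "temporal", "occipital")


@dataclass
class WmhParcels:
    """Eight (depth x lobe) lesion parcels plus totals.

    ``parcels`` maps ``(depth, lobe)`` to a boolean mask; ``unlabeled`` holds
    lesion voxels without a lobar label (kept in the totals only).
    """

    parcels: dict[tuple[str, str], np.ndarray]
    total_pwmh: np.ndarray
    total_dwmh: np.ndarray
    unlabeled: np.ndarray
    spacing_mm: np.ndarray
    volumes_ml: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> np.ndarray:
        return self.total_pwmh | self.total_dwmh

    def compute_volumes(self) -> dict[str, float]:
        vols = {
            f"{depth}_{lobe}": wmh_volume(mask, self.spacing_mm)
            for (depth, lobe), mask in self.parcels.items()
        }
        vols["total_pWMH"] = wmh_volume(self.total_pwmh, self.spacing_mm)
        vols["total_dWMH"] = wmh_volume(self.total_dwmh, self.spacing_mm)
        vols["total_WMH"] = wmh_volume(self.total, self.spacing_mm)
        self.volumes_ml = vols
        return vols


def ventricle_distance_map(ventricles: Volume) -> Volume:
    """Per-voxel Euclidean distance (mm) to the nearest ventricle voxel."""
    mask = ventricles.data > 0
    if not mask.any():
        raise ValueError("ventricle mask is empty")
    dist = ndimage.distance_transform_edt(~mask, sampling=ventricles.spacing)
    return ventricles.like(dist)


def classify_depth(
    wmh: Volume,
    distance_map: Volume,
    threshold_mm: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a lesion mask into periventricular (< threshold) and deep (>=).

    The boundary convention follows the "within 10 mm of the ventricles"
    reading: a voxel at exactly the threshold distance is deep.
    """
    check_same_grid(wmh, distance_map, names=["wmh", "distance_map"])
    mask = wmh.data > 0
    near = distance_map.data < threshold_mm
    return mask & near, mask & ~near


def split_by_lobe(
    pwmh: np.ndarray,
    dwmh: np.ndarray,
    lobar_labels: np.ndarray,
    lobe_names: dict[str, int],
    spacing_mm,
) -> WmhParcels:
    """Cross depth masks with lobar WM labels into the eight parcels."""
    labeled = np.zeros(pwmh.shape, dtype=bool)
    parcels: dict[tuple[str, str], np.ndarray] = {}
    for depth, mask in (("pWMH", pwmh), ("dWMH", dwmh)):
        for lobe in PARCEL_LOBES:
            lab = lobe_names[lobe]
            parcels[(depth, lobe)] = mask & (lobar_labels == lab)
            labeled |= parcels[(depth, lobe)]
    unlabeled = (pwmh | dwmh) & ~labeled
    out = WmhParcels(
        parcels=parcels,
        total_pwmh=pwmh,
        total_dwmh=dwmh,
        unlabeled=unlabeled,
        spacing_mm=np.asarray(spacing_mm, dtype=float),
    )
    out.compute_volumes()
    return out


def wmh_volume(mask: np.ndarray, spacing_mm) -> float:
    """Lesion volume in mL (voxel count x voxel volume)."""
    spacing = np.asarray(spacing_mm, dtype=float)
    return float(np.count_nonzero(mask) * np.prod(spacing) / 1000.0)


def parcellate_wmh(
    wmh: Volume,
    ventricles: Volume,
    lobar_labels: Volume,
    lobe_names: dict[str, int],
    threshold_mm: float = 10.0,
) -> WmhParcels:
    """Full parcellation: distance map, depth split, lobar split, volumes."""
    check_same_grid(wmh, ventricles, lobar_labels, names=["wmh", "ventricles", "lobes"])
    dist = ventricle_distance_map(ventricles)
    pwmh, dwmh = classify_depth(wmh, dist, threshold_mm)
    return split_by_lobe(pwmh, dwmh, lobar_labels.data, lobe_names, wmh.spacing)
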