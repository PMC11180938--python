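"""Map the cortex connected to WMH with probabilistic tractography.

5000 streamlines per lesion voxel follow the local fiber directions to the
WM/GM boundary.  The termination-count map is thresholded at a fixed low
probability level (3.08e-5 percent of emitted streamlines), then adaptive
count thresholds shrink the connected ROI to 50% (medium) and 25% (high) of
the low-level surface size.  The remainder of the boundary is the
WMH-unconnected reference cortex (rROI).
"""

import numpy as np

import periconnect as pc

phantom = pc.make_phantom(pc.PhantomConfig(seed=1))
tissue = phantom.tissue
boundary = tissue.like((tissue.data == pc.TISSUE_LABELS["wm_gm_boundary"]).astype(np.uint8))
brain = tissue.like((tissue.data > 0).astype(np.uint8))
seed = tissue.like(phantom.wmh.data)

cmap = pc.track(seed, phantom.field, boundary, brain,
                pc.TrackingParams(samples_per_voxel=5000, seed=1))
print(f"emitted {cmap.total_streamlines} streamlines "
      f"({cmap.successes} reached the boundary)")

roi_set = pc.build_roi_set(cmap, phantom.region_labels(), pc.CORTICAL_REGIONS)
low = roi_set.levels["low"].size
for level in ("low", "medium", "high"):
    lvl = roi_set.levels[level]
    print(f"{level:6s} ROI: {lvl.size:5d} boundary voxels "
          f"({100 * lvl.size / low:.1f}% of low), count threshold {lvl.threshold:.1f}")

truth = phantom.truth.connected_mask
roi = roi_set.levels["low"].roi
dice = 2 * (roi & truth).sum() / (roi.sum() + truth.sum())
print(f"Dice of low-level ROI vs ground-truth connected patch: {dice:.3f}")
# The default phantom has 10 degrees of angular dispersion, so streamlines
# spread beyond the geometric patch and the low ROI over-covers it.  Rebuild
# the phantom with dispersion_deg=0 and the same comparison exceeds 0.95.
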