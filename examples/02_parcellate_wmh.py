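"""Split the WMH mask into periventricular/deep x lobar parcels.

Lesion voxels closer than 10 mm to the ventricles are periventricular
(pWMH), the rest deep (dWMH); crossing with four lobar white-matter labels
gives the eight standard parcels and their volumes in mL.
"""

import numpy as np

import periconnect as pc

phantom = pc.make_phantom(pc.PhantomConfig(seed=1))
tissue = phantom.tissue
ventricles = tissue.like((tissue.data == pc.TISSUE_LABELS["ventricle"]).astype(np.uint8))

parcels = pc.parcellate_wmh(phantom.wmh, ventricles, phantom.lobes,
                            pc.LOBAR_WM_LABELS, threshold_mm=10.0)

print("parcel volumes (mL):")
for key, vol in sorted(parcels.volumes_ml.items()):
    print(f"  {key:18s} {vol:.3f}")
# total_WMH is the covariate the cohort regressions adjust for.
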