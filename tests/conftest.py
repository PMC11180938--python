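import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import periconnect as pc

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_phantom():
    """The default 64-cube phantom (10 deg dispersion, 5% noise)."""
    return pc.make_phantom(pc.PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, dispersion-free phantom for exact-recovery checks."""
    return pc.make_phantom(pc.PhantomConfig(seed=2, dispersion_deg=0.0, noise_sd_frac=0.0))


@pytest.fixture(scope="session")
def clean_tracked(clean_phantom):
    """Connectivity map of the total WMH seed on the clean phantom."""
    ph = clean_phantom
    tissue = ph.tissue
    boundary = tissue.like((tissue.data == pc.TISSUE_LABELS["wm_gm_boundary"]).astype(np.uint8))
    brain = tissue.like((tissue.data > 0).astype(np.uint8))
    seed = tissue.like(ph.wmh.data)
    cmap = pc.track(seed, ph.field, boundary, brain,
                    pc.TrackingParams(samples_per_voxel=500, seed=11))
    return cmap


def phantom_masks(ph):
    tissue = ph.tissue
    return {
        "boundary": tissue.like(
            (tissue.data == pc.TISSUE_LABELS["wm_gm_boundary"]).astype(np.uint8)
        ),
        "brain": tissue.like((tissue.data > 0).astype(np.uint8)),
        "ventricles": tissue.like(
            (tissue.data == pc.TISSUE_LABELS["ventricle"]).astype(np.uint8)
        ),
        "cerebellum": tissue.like(
            (tissue.data == pc.TISSUE_LABELS["cerebellum_ref"]).astype(np.uint8)
        ),
        "seed": tissue.like(ph.wmh.data),
    }


def truth_roi_set(ph):
    """A single-level RoiSet whose ROI is the ground-truth connected patch."""
    boundary = ph.boundary_mask
    truth = ph.truth.connected_mask
    rs = pc.RoiSet(
        levels={"truth": pc.connectivity.LevelRois(roi=truth, threshold=0.0,
                                                   size=int(truth.sum()))},
        boundary_mask=boundary,
    )
    pc.define_rrois(rs, ph.region_labels(), pc.CORTICAL_REGIONS)
    return rs
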