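import numpy as np
import pytest

import periconnect as pc
from periconnect.connectivity import ConnectivityMap, LevelRois
from periconnect.volumes import Volume


def _slab_world(nz=20, width=7):
    """A slab with a uniform +z orientation field and a boundary top layer."""
    shape = (width, width, nz)
    affine = np.eye(4)
    brain = np.ones(shape, dtype=np.uint8)
    boundary = np.zeros(shape, dtype=np.uint8)
    boundary[:, :, nz - 2] = 1
    dirs = np.zeros((*shape, 3), dtype=np.float32)
    dirs[..., 2] = 1.0
    support = np.ones(shape, dtype=bool)
    support[:, :, nz - 1] = False
    field = pc.OrientationField(dirs, np.zeros(shape, np.float32), support)
    return shape, affine, brain, boundary, field


def test_straight_field_hits_overlying_column():
    """Zero dispersion + uniform +z field: all streamlines land in the column."""
    shape, affine, brain, boundary, field = _slab_world()
    seed = np.zeros(shape, dtype=np.uint8)
    seed[3, 3, 2] = 1
    cmap = pc.track(
        Volume(seed, affine), field, Volume(boundary, affine), Volume(brain, affine),
        pc.TrackingParams(samples_per_voxel=1000, seed=0),
    )
    assert cmap.total_streamlines == 1000
    assert cmap.successes == 1000
    assert cmap.counts[3, 3, shape[2] - 2] == 1000
    assert cmap.counts.sum() == 1000


def test_streamline_accounting_is_exact_at_default_samples():
    shape, affine, brain, boundary, field = _slab_world()
    seed = np.zeros(shape, dtype=np.uint8)
    seed[2, 2, 2] = 1
    seed[4, 4, 2] = 1
    cmap = pc.track(
        Volume(seed, affine), field, Volume(boundary, affine), Volume(brain, affine),
        pc.TrackingParams(seed=0),  # default 5000 per voxel
    )
    assert cmap.total_streamlines == 10_000
    assert cmap.successes + cmap.failures == 10_000


def test_field_pointing_away_from_boundary_yields_zero_counts():
    shape, affine, brain, boundary, field = _slab_world()
    field.directions[..., 2] = -1.0  # out through the bottom, away from boundary
    seed = np.zeros(shape, dtype=np.uint8)
    seed[3, 3, 5] = 1
    cmap = pc.track(
        Volume(seed, affine), field, Volume(boundary, affine), Volume(brain, affine),
        pc.TrackingParams(samples_per_voxel=200, seed=0),
    )
    assert cmap.successes == 0
    assert cmap.counts.sum() == 0
    assert cmap.failures == 200


def test_empty_seed_and_undefined_field_raise():
    shape, affine, brain, boundary, field = _slab_world()
    empty = Volume(np.zeros(shape, dtype=np.uint8), affine)
    with pytest.raises(ValueError):
        pc.track(empty, field, Volume(boundary, affine), Volume(brain, affine))
    seed = np.zeros(shape, dtype=np.uint8)
    seed[0, 0, shape[2] - 1] = 1  # outside field support
    with pytest.raises(ValueError):
        pc.track(Volume(seed, affine), field, Volume(boundary, affine), Volume(brain, affine))


def test_adding_seed_voxels_never_decreases_counts():
    """Per-seed-voxel RNG substreams make counts additive over seed sets."""
    shape, affine, brain, boundary, field = _slab_world()
    seed_a = np.zeros(shape, dtype=np.uint8)
    seed_a[2, 2, 2] = 1
    seed_ab = seed_a.copy()
    seed_ab[4, 4, 2] = 1
    params = pc.TrackingParams(samples_per_voxel=300, seed=5)
    ca = pc.track(Volume(seed_a, affine), field, Volume(boundary, affine),
                  Volume(brain, affine), params)
    cab = pc.track(Volume(seed_ab, affine), field, Volume(boundary, affine),
                   Volume(brain, affine), params)
    assert (cab.counts >= ca.counts).all()


def _toy_cmap(counts_spec, total, shape=(1, 1, 30)):
    counts = np.zeros(shape, dtype=np.int64)
    boundary = np.zeros(shape, dtype=bool)
    k = 0
    for value, nvox in counts_spec:
        for _ in range(nvox):
            counts[0, 0, k] = value
            boundary[0, 0, k] = True
            k += 1
    return ConnectivityMap(counts=counts, total_streamlines=total,
                           successes=int(counts.sum()), failures=total - int(counts.sum()),
                           boundary_mask=boundary, affine=np.eye(4))


def test_low_roi_cutoff_is_real_valued():
    """At 1e7 emitted streamlines the cutoff is 3.08 counts: 3 is out, 4 is in."""
    cmap = _toy_cmap([(3, 1), (4, 1), (0, 1)], total=10_000_000)
    roi = pc.low_roi(cmap)
    assert not roi[0, 0, 0] and roi[0, 0, 1] and not roi[0, 0, 2]


def test_low_roi_edge_cases():
    cmap = _toy_cmap([(0, 5)], total=1000)
    assert pc.low_roi(cmap).sum() == 0
    assert pc.low_roi(cmap, tau_low_percent=0.0).sum() == 5  # whole boundary


def test_adaptive_threshold_two_class_example():
    """10 voxels at count 5 and 10 at count 50: the 50s alone meet the 50% target."""
    cmap = _toy_cmap([(5, 10), (50, 10)], total=10_000)
    low = pc.low_roi(cmap, tau_low_percent=1e-6)
    assert low.sum() == 20
    roi, thr = pc.adaptive_roi(cmap, low, 0.5)
    assert thr == 50.0
    assert roi.sum() == 10
    assert (cmap.counts[roi] == 50).all()


def test_adaptive_threshold_target_one_returns_low_roi():
    cmap = _toy_cmap([(5, 10), (50, 10)], total=10_000)
    low = pc.low_roi(cmap, tau_low_percent=1e-6)
    roi, _ = pc.adaptive_roi(cmap, low, 1.0)
    np.testing.assert_array_equal(roi, low)


def test_adaptive_threshold_unreachable_target_warns_empty():
    cmap = _toy_cmap([(7, 10)], total=10_000)
    low = pc.low_roi(cmap, tau_low_percent=1e-6)
    with pytest.warns(RuntimeWarning):
        roi, _ = pc.adaptive_roi(cmap, low, 0.5)
    assert roi.sum() == 0


def test_adaptive_threshold_is_maximal_under_bound(clean_tracked):
    """Brute-force sweep over all count values agrees with the adaptive search."""
    cmap = clean_tracked
    low = pc.low_roi(cmap)
    low_size = int(low.sum())
    for frac in (0.5, 0.25):
        roi, thr = pc.adaptive_roi(cmap, low, frac)
        size = int(roi.sum())
        assert size <= frac * low_size
        # any strictly smaller admissible threshold must overshoot the bound
        for t in np.unique(cmap.counts[low]):
            brute = int((low & (cmap.counts >= t)).sum())
            if t < thr:
                assert brute > frac * low_size
            else:
                assert brute <= low_size


def test_levels_are_nested(clean_tracked):
    rs = pc.build_roi_set(clean_tracked)
    low, med, high = (rs.levels[k].roi for k in ("low", "medium", "high"))
    assert (high <= med).all() and (med <= low).all()
    assert rs.levels["medium"].size <= 0.5 * rs.levels["low"].size
    assert rs.levels["high"].size <= 0.25 * rs.levels["low"].size


def test_rroi_partitions_each_region(clean_phantom, clean_tracked):
    ph = clean_phantom
    rs = pc.build_roi_set(clean_tracked, ph.region_labels(), pc.CORTICAL_REGIONS)
    boundary = rs.boundary_mask
    reg = ph.region_labels()
    for lvl in rs.levels.values():
        for name, lab in pc.CORTICAL_REGIONS.items():
            in_region = boundary & (reg == lab)
            roi_r = lvl.regional_roi[name]
            rroi_r = lvl.regional_rroi[name]
            assert not (roi_r & rroi_r).any()
            np.testing.assert_array_equal(roi_r | rroi_r, in_region)


def test_rroi_extremes():
    boundary = np.zeros((4, 4, 4), dtype=bool)
    boundary[1:3, 1:3, 1] = True
    reg = np.where(boundary, 1, 0)
    # empty ROI -> rROI is the whole region
    rs = pc.RoiSet(levels={"low": LevelRois(roi=np.zeros_like(boundary), threshold=0, size=0)},
                   boundary_mask=boundary)
    pc.define_rrois(rs, reg, {"frontal": 1})
    np.testing.assert_array_equal(rs.levels["low"].regional_rroi["frontal"], boundary)
    # full ROI -> rROI empty
    rs2 = pc.RoiSet(levels={"low": LevelRois(roi=boundary.copy(), threshold=0,
                                             size=int(boundary.sum()))},
                    boundary_mask=boundary)
    pc.define_rrois(rs2, reg, {"frontal": 1})
    assert rs2.levels["low"].regional_rroi["frontal"].sum() == 0
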