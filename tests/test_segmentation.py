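"""Isolated-pore labeling, sphericity and the size/shape selection rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from porequal import (
    BinaryMask,
    GrayVolume,
    PhantomSpec,
    binarize,
    filter_pores,
    find_isolated_pores,
    generate_phantom,
    pore_shape,
    sphericity,
)
from porequal.segmentation import PoreShape
from porequal.volume_io import PoreLabelVolume

from oracles import prolate_spheroid_area_volume, rasterize_ball


# ----------------------------------------------------------------- binarize

def test_binarize_threshold_above_constant_volume_is_empty():
    vol = GrayVolume(np.full((8, 8, 8), 5.0), 10.0)
    assert not binarize(vol, 6.0).values.any()


def test_binarize_recovers_bright_phase_exactly():
    vals = np.full((16, 16, 16), 100.0)
    vals[4:12, 4:12, 4:12] = 200.0
    mask = binarize(GrayVolume(vals, 10.0), 150.0)
    assert np.array_equal(mask.values, vals == 200.0)


def test_binarize_counts_match_blurred_sphere_midlevel_oracle():
    """Thresholding the blurred phantom at mid-gray reproduces, per pore, the
    voxel count of the analytic blurred sphere above mid-level (the mid-level
    surface sits ~2*sigma^2/r inside the true radius, so counts are compared
    with the half-level sphere, not the unblurred ball)."""
    from porequal._analytic import ball_gauss
    from scipy.optimize import brentq

    spec = PhantomSpec(grid_shape=(140, 140, 140), n_closed_pores=6,
                       pore_radius_range=(8, 10), blur_sigma=2.0,
                       noise_sigma=0.0, seed=9)
    vol, gt = generate_phantom(spec)
    mask = binarize(vol, 0.5 * (spec.gray_scaffold + spec.gray_pore))
    labels = find_isolated_pores(mask)
    assert len(labels.labels) == spec.n_closed_pores
    lab = labels.values
    counts = {int(l): int((lab == l).sum()) for l in labels.labels}
    # map measured components to ground-truth pores via the center voxel
    for c, r in zip(gt.centers, gt.radii):
        l = int(lab[tuple(np.round(c).astype(int))])
        assert l > 0
        d50 = brentq(lambda d: ball_gauss(d, r, 2.0) - 0.5, r - 4, r + 2)
        oracle_count = 4.0 / 3.0 * np.pi * d50**3
        assert counts[l] == pytest.approx(oracle_count, rel=0.05)


# ------------------------------------------------------ find_isolated_pores

def _mask(arr):
    return BinaryMask(arr, 10.0)


def test_single_interior_component_is_isolated():
    m = np.zeros((20, 20, 20), bool)
    m[8:12, 8:12, 8:12] = True
    labels = find_isolated_pores(_mask(m))
    assert list(labels.labels) == [1]


def test_boundary_connected_component_is_main_pore_space():
    m = np.zeros((20, 20, 20), bool)
    m[0:10, 2:6, 2:6] = True  # reaches the z=0 face
    m[14:18, 12:16, 12:16] = True  # interior sphere-ish blob
    labels = find_isolated_pores(_mask(m))
    assert list(labels.labels) == [1]
    assert labels.values[15, 13, 13] == 1
    assert labels.values[5, 3, 3] == 0


def test_bone_contact_disqualifies_pore():
    m = np.zeros((20, 20, 20), bool)
    m[4:8, 4:8, 4:8] = True
    m[12:16, 12:16, 12:16] = True
    bone = np.zeros_like(m)
    bone[8, 5, 5] = True  # touches the first blob's 1-voxel dilation
    labels = find_isolated_pores(_mask(m), _mask(bone))
    assert len(labels.labels) == 1
    assert labels.values[13, 13, 13] == 1


def test_phantom_pores_all_recovered(small_phantom):
    spec, vol, gt = small_phantom
    mask = binarize(vol, 150.0)
    labels = find_isolated_pores(mask)
    assert len(labels.labels) == spec.n_closed_pores
    for c in gt.centers:
        assert labels.values[tuple(np.round(c).astype(int))] > 0


def test_find_isolated_pores_is_idempotent(small_phantom):
    spec, vol, _ = small_phantom
    mask = binarize(vol, 150.0)
    lab1 = find_isolated_pores(mask)
    lab2 = find_isolated_pores(BinaryMask(lab1.values > 0, 10.0))
    assert np.array_equal(lab1.values > 0, lab2.values > 0)
    assert len(lab1.labels) == len(lab2.labels)


def test_empty_mask_gives_empty_labels():
    labels = find_isolated_pores(_mask(np.zeros((8, 8, 8), bool)))
    assert labels.labels.size == 0


# ----------------------------------------------------------------- shape

def _labelled(mask):
    return PoreLabelVolume(mask.astype(np.int32), voxel_size=1000.0)  # 1 um voxels


def test_sphericity_of_digitized_ball_near_one():
    ball = rasterize_ball(20, 48)
    shape = pore_shape(_labelled(ball), 1)
    assert shape.sphericity == pytest.approx(1.0, rel=0.03)


def test_sphericity_of_prolate_spheroid_matches_closed_form():
    r = 10.0
    g = 48
    zz, yy, xx = np.mgrid[0:g, 0:g, 0:g].astype(float) - (g - 1) / 2.0
    spheroid = (zz / (2 * r)) ** 2 + (yy / r) ** 2 + (xx / r) ** 2 <= 1.0
    shape = pore_shape(_labelled(spheroid), 1)
    area, volume = prolate_spheroid_area_volume(2 * r, r)
    expected = sphericity(area, volume)
    assert expected == pytest.approx(1.077, abs=0.005)  # sanity on the oracle
    assert shape.sphericity == pytest.approx(expected, rel=0.03)


def test_sphericity_is_scale_free():
    s_small = pore_shape(_labelled(rasterize_ball(10, 26)), 1).sphericity
    s_big = pore_shape(_labelled(rasterize_ball(20, 46)), 1).sphericity
    assert s_small == pytest.approx(s_big, rel=0.03)


def test_cube_sphericity_matches_closed_form():
    cube = np.zeros((50, 50, 50), bool)
    cube[5:45, 5:45, 5:45] = True
    shape = pore_shape(_labelled(cube), 1)
    expected = sphericity(6.0 * 40**2, 40.0**3)
    assert shape.sphericity == pytest.approx(expected, rel=0.03)


def test_missing_label_raises():
    with pytest.raises(KeyError):
        pore_shape(_labelled(rasterize_ball(5, 16)), 3)


# ----------------------------------------------------------------- filter

def _shape(label, count, s):
    return PoreShape(label=label, voxel_count=count, volume_um3=1.0,
                     surface_area_um2=1.0, sphericity=s)


def test_filter_thresholds_are_strict():
    shapes = [
        _shape(1, 1000, 1.0),   # exactly 1000 voxels -> out
        _shape(2, 1001, 1.3),   # S exactly 1.3 -> out
        _shape(3, 1001, 1.29),  # in
    ]
    assert filter_pores(shapes) == [3]


def test_filter_constructed_set():
    shapes = [_shape(1, 1500, 1.1), _shape(2, 800, 1.0), _shape(3, 2000, 1.5)]
    assert filter_pores(shapes) == [1]


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(
        st.tuples(st.integers(0, 5000), st.floats(0.9, 2.0)),
        min_size=0, max_size=20,
    )
)
def test_filter_is_a_subset_and_idempotent(pairs):
    shapes = [_shape(i + 1, c, s) for i, (c, s) in enumerate(pairs)]
    kept = filter_pores(shapes)
    assert set(kept) <= {s.label for s in shapes}
    kept_shapes = [s for s in shapes if s.label in kept]
    assert filter_pores(kept_shapes) == kept
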