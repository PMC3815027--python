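"""Spatial metrics: pair classes, associations, axis frame, positions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_object
from spermfish3d.metrics import (
    ADJACENT,
    COLOCALIZED,
    DISTANT,
    ELONGATED,
    ROUND,
    AxisUndefinedError,
    ap_position,
    border_distance,
    classify_masks,
    classify_morphology,
    classify_pair,
    count_associations,
    count_clusters,
    fit_axis_frame,
    ml_position,
)
from spermfish3d.synthetic import NucleusSpec, _nucleus_mask

SPACING = (0.244, 0.093, 0.093)
PX = 0.093


def obj(voxels, label=1, shape=(8, 16, 16)):
    return make_object(voxels, shape=shape, spacing=SPACING, label=label)


# ---------------------------------------------------------------------------
# Pair classification


def test_two_shared_voxels_colocalized():
    a = obj([[2, 2, 2], [2, 2, 3], [2, 2, 4]])
    b = obj([[2, 2, 3], [2, 2, 4], [2, 2, 5]], label=2)
    assert classify_pair(a, b) == COLOCALIZED


def test_one_shared_voxel_is_adjacent_not_colocalized():
    a = obj([[2, 2, 2], [2, 2, 3]])
    b = obj([[2, 2, 3], [2, 2, 4]], label=2)
    # one shared voxel is below the 2-voxel colocalization minimum, and the
    # shared voxel makes the edge gap zero -> adjacent
    assert classify_pair(a, b) == ADJACENT


def test_touching_voxels_adjacent():
    a = obj([[2, 2, 2], [2, 2, 3]])
    b = obj([[2, 2, 4], [2, 2, 5]], label=2)
    # neighboring centers: distance = 1 px, gap = 0 < px
    assert classify_pair(a, b) == ADJACENT


def test_one_pixel_gap_adjacent():
    a = obj([[2, 2, 2]])
    b = obj([[2, 2, 4]], label=2)
    # centers 2 px apart -> gap = 1 px, not < 1 px... boundary: gap == px
    # is distant (strict inequality)
    assert classify_pair(a, b) == DISTANT


def test_far_objects_distant():
    a = obj([[1, 1, 1]])
    b = obj([[6, 12, 12]], label=2)
    assert classify_pair(a, b) == DISTANT


def test_classify_pair_symmetry_examples():
    pairs = [
        ([[2, 2, 2], [2, 2, 3]], [[2, 2, 3], [2, 2, 4]]),
        ([[1, 1, 1]], [[5, 10, 10]]),
        ([[2, 2, 2], [2, 3, 2]], [[2, 4, 2], [2, 5, 2]]),
    ]
    for va, vb in pairs:
        a, b = obj(va), obj(vb, label=2)
        assert classify_pair(a, b) == classify_pair(b, a)


@given(st.data())
def test_classify_pair_symmetry_property(data):
    shape = (6, 10, 10)
    def draw_voxels(name):
        n = data.draw(st.integers(2, 6), label=f"n_{name}")
        vox = data.draw(
            st.lists(
                st.tuples(st.integers(0, 5), st.integers(0, 9), st.integers(0, 9)),
                min_size=n, max_size=n, unique=True,
            ),
            label=name,
        )
        return vox
    a = make_object(draw_voxels("a"), shape=shape, spacing=SPACING, label=1)
    b = make_object(draw_voxels("b"), shape=shape, spacing=SPACING, label=2)
    assert classify_pair(a, b) == classify_pair(b, a)


def test_classify_masks_agrees_with_classify_pair():
    shape = (8, 16, 16)
    rng = np.random.default_rng(3)
    for _ in range(10):
        ma = np.zeros(shape, dtype=bool)
        mb = np.zeros(shape, dtype=bool)
        za, ya, xa = rng.integers(0, 5), rng.integers(0, 12), rng.integers(0, 12)
        zb, yb, xb = rng.integers(0, 5), rng.integers(0, 12), rng.integers(0, 12)
        ma[za:za + 3, ya:ya + 3, xa:xa + 3] = True
        mb[zb:zb + 3, yb:yb + 3, xb:xb + 3] = True
        a = make_object(np.argwhere(ma), shape=shape, spacing=SPACING, label=1)
        b = make_object(np.argwhere(mb), shape=shape, spacing=SPACING, label=2)
        assert classify_masks(ma, mb, SPACING) == classify_pair(a, b)


def test_classify_masks_empty_raises():
    shape = (4, 4, 4)
    with pytest.raises(ValueError):
        classify_masks(np.zeros(shape, bool), np.ones(shape, bool), SPACING)


# ---------------------------------------------------------------------------
# Associations


def test_count_clusters():
    assert count_clusters([]) == 0
    assert count_clusters([obj([[1, 1, 1]]), obj([[3, 3, 3]], label=2)]) == 2


def test_associations_each_object_used_once():
    # one A near two Bs: only one association can be formed
    a1 = obj([[2, 2, 4], [2, 2, 5]])
    b1 = obj([[2, 2, 3]], label=1)
    b2 = obj([[2, 2, 6]], label=2)
    assert count_associations([a1], [b1, b2]) == 1


def test_associations_two_disjoint_pairs():
    a1 = obj([[2, 2, 2]], label=1)
    a2 = obj([[5, 12, 12]], label=2)
    b1 = obj([[2, 2, 3]], label=1)
    b2 = obj([[5, 12, 13]], label=2)
    assert count_associations([a1, a2], [b1, b2]) == 2


def test_associations_all_distant():
    a = obj([[1, 1, 1]])
    b = obj([[6, 14, 14]], label=1)
    assert count_associations([a], [b]) == 0


def test_associations_empty_sets():
    assert count_associations([], []) == 0
    assert count_associations([obj([[1, 1, 1]])], []) == 0


# ---------------------------------------------------------------------------
# Axis frame and normalized positions


def _nucleus_object(axis=(0.0, 0.0, 1.0), semi_axes=(6.0, 3.5, 1.5),
                    grid=(24, 168, 168)):
    sp = np.asarray(SPACING)
    center = (np.asarray(grid) - 1) * sp / 2
    spec = NucleusSpec(semi_axes=semi_axes, axis=axis, center=tuple(center))
    mask = _nucleus_mask(spec, grid, SPACING)
    o = make_object(np.argwhere(mask), shape=grid, spacing=SPACING)
    return spec, o, mask


def test_axis_direction_within_3_degrees():
    theta = 0.4
    axis = (0.0, math.sin(theta), math.cos(theta))
    spec, nucleus, _ = _nucleus_object(axis=axis)
    frame = fit_axis_frame(nucleus, anterior_hint=axis)
    cosang = abs(float(frame.ap_direction @ np.asarray(axis)))
    assert math.degrees(math.acos(min(1.0, cosang))) < 3.0


def test_axis_hint_fixes_sign():
    spec, nucleus, _ = _nucleus_object()
    f_pos = fit_axis_frame(nucleus, anterior_hint=(0, 0, 1))
    f_neg = fit_axis_frame(nucleus, anterior_hint=(0, 0, -1))
    assert float(f_pos.ap_direction @ f_neg.ap_direction) == pytest.approx(-1, abs=1e-9)


def test_sphere_has_no_axis():
    grid = (40, 60, 60)
    sp = np.asarray(SPACING)
    center = (np.asarray(grid) - 1) * sp / 2
    zz, yy, xx = np.indices(grid)
    d2 = (((zz * sp[0] - center[0])) ** 2 + ((yy * sp[1] - center[1])) ** 2
          + ((xx * sp[2] - center[2])) ** 2)
    mask = d2 <= 2.0 ** 2
    sphere = make_object(np.argwhere(mask), shape=grid, spacing=SPACING)
    with pytest.raises(AxisUndefinedError):
        fit_axis_frame(sphere)


def test_ap_position_poles_and_center():
    spec, nucleus, _ = _nucleus_object()
    frame = fit_axis_frame(nucleus, anterior_hint=spec.anterior_direction)
    center = np.asarray(spec.center)
    anterior = spec.normalized_to_physical(97.0, 0.0, 0.0)
    posterior = spec.normalized_to_physical(3.0, 0.0, 0.0)
    assert ap_position(center, frame) == pytest.approx(50.0, abs=1.5)
    assert ap_position(anterior, frame) == pytest.approx(97.0, abs=1.5)
    assert ap_position(posterior, frame) == pytest.approx(3.0, abs=1.5)


def test_ml_position_axis_and_border():
    spec, nucleus, mask = _nucleus_object()
    frame = fit_axis_frame(nucleus, anterior_hint=spec.anterior_direction)
    on_axis = spec.normalized_to_physical(50.0, 0.0, 0.0)
    near_border = spec.normalized_to_physical(50.0, 90.0, 0.0)
    midway = spec.normalized_to_physical(50.0, 45.0, 0.0)
    assert ml_position(on_axis, frame, mask, SPACING) == pytest.approx(0.0, abs=2.0)
    assert ml_position(near_border, frame, mask, SPACING) == pytest.approx(90.0, abs=3.0)
    assert ml_position(midway, frame, mask, SPACING) == pytest.approx(45.0, abs=3.0)


def test_ml_position_rotation_invariance():
    values = []
    for theta in (0.0, 0.7, 1.9):
        axis = (0.0, math.sin(theta), math.cos(theta))
        spec, nucleus, mask = _nucleus_object(axis=axis)
        frame = fit_axis_frame(nucleus, anterior_hint=spec.anterior_direction)
        p = spec.normalized_to_physical(60.0, 55.0, 0.0)
        values.append(ml_position(p, frame, mask, SPACING))
    assert max(values) - min(values) < 3.0


def test_ml_position_outside_mask_raises():
    spec, nucleus, mask = _nucleus_object()
    frame = fit_axis_frame(nucleus, anterior_hint=spec.anterior_direction)
    with pytest.raises(ValueError, match="outside"):
        ml_position((0.0, 0.0, 0.0), frame, mask, SPACING)


# ---------------------------------------------------------------------------
# Morphology and border distance


def test_morphology_cube_round():
    vox = [(z, y, x) for z in range(3) for y in range(3) for x in range(3)]
    cube = make_object(vox, shape=(8, 8, 8), spacing=(1, 1, 1))
    assert classify_morphology(cube) == ROUND


def test_morphology_line_elongated():
    line = make_object([[1, 1, x] for x in range(6)], shape=(8, 8, 8),
                       spacing=(1, 1, 1))
    assert classify_morphology(line) == ELONGATED


def test_morphology_exact_threshold_is_round():
    # points with analytically exact covariance eigenvalue ratio:
    # (+-a, 0) and (0, +-b) in a plane give sqrt(l1/l2) = a/b exactly
    a, b = 3, 2
    vox = [[1, 4 + a, 4], [1, 4 - a, 4], [1, 4, 4 + b], [1, 4, 4 - b]]
    o = make_object(vox, shape=(3, 9, 9), spacing=(1, 1, 1))
    assert classify_morphology(o, ratio_threshold=a / b) == ROUND
    assert classify_morphology(o, ratio_threshold=a / b - 1e-9) == ELONGATED


def test_border_distance_matches_brute_force():
    shape = (9, 9, 9)
    mask = np.zeros(shape, dtype=bool)
    mask[2:7, 2:7, 2:7] = True
    sp = np.array([1.0, 1.0, 1.0])
    c = np.array([4.0, 4.0, 4.0])
    # brute force: nearest border voxel (border = mask voxel with a 6-neighbor
    # outside the mask)
    best = np.inf
    for p in np.argwhere(mask):
        is_border = False
        for d in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            q = p + d
            if np.any(q < 0) or np.any(q >= shape) or not mask[tuple(q)]:
                is_border = True
                break
        if is_border:
            best = min(best, float(np.linalg.norm(p * sp - c)))
    assert border_distance(c, mask, sp) == pytest.approx(best)


def test_border_distance_outside_raises():
    mask = np.zeros((5, 5, 5), dtype=bool)
    mask[2, 2, 2] = True
    with pytest.raises(ValueError):
        border_distance((0.0, 0.0, 0.0), mask, (1, 1, 1))
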