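"""Grid sampling and DMV/UMV selection criteria."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from blinkflow.motion import (
    FlowField,
    MotionVectorSet,
    Vec2,
    downward_motion_vector,
    make_sample_grid,
    sample_vectors,
    total_motion_vector,
    upward_motion_vector,
)

# ---------------------------------------------------------------------------
# Independent brute-force oracles for the selection criteria
# ---------------------------------------------------------------------------


def dmv_brute(vectors):
    sx = sy = 0.0
    for x, y in vectors:
        mag = math.hypot(x, y)
        if mag < 2.0:
            continue
        if y <= 0:
            continue
        if y < 0.5 * mag:
            continue
        sx += x
        sy += y
    return sx, sy


def umv_brute(vectors):
    sx = sy = 0.0
    for x, y in vectors:
        if math.hypot(x, y) < 2.0:
            continue
        if y >= 0:
            continue
        sx += x
        sy += y
    return sx, sy


class TestSampleGrid:
    def test_default_processing_region_has_544_points(self):
        assert len(make_sample_grid(170, 320, 10)) == 544

    def test_single_cell(self):
        assert len(make_sample_grid(10, 10, 10)) == 1

    def test_floor_semantics_matches_cell_enumeration(self):
        grid = make_sample_grid(25, 25, 10)
        # Brute-force: count complete d x d cells.
        n = sum(1 for i in range(25 // 10) for j in range(25 // 10))
        assert len(grid) == n == 4

    def test_points_at_cell_centers_inside_frame(self):
        grid = make_sample_grid(170, 320, 10)
        xs, ys = grid.points[:, 0], grid.points[:, 1]
        assert xs.min() == 5.0 and ys.min() == 5.0
        assert xs.max() <= 169 and ys.max() <= 319
        # Adjacent points differ by d on each axis.
        assert np.isclose(np.diff(sorted(set(xs))), 10).all()

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError):
            make_sample_grid(170, 320, 0)
        with pytest.raises(ValueError):
            make_sample_grid(10, 10, 11)


class TestSampleVectors:
    def test_uniform_flow_sampled_everywhere(self):
        flow = FlowField(dx=np.full((40, 30), 1.0), dy=np.full((40, 30), 2.0))
        mvs = sample_vectors(flow, make_sample_grid(30, 40, 10))
        assert np.allclose(mvs.vectors, [1.0, 2.0])

    def test_zero_flow(self):
        flow = FlowField(dx=np.zeros((40, 30)), dy=np.zeros((40, 30)))
        mvs = sample_vectors(flow, make_sample_grid(30, 40, 10))
        assert np.allclose(mvs.vectors, 0.0)

    def test_half_plane_flow_hits_only_bottom_points(self):
        dy = np.zeros((320, 170))
        dy[160:, :] = 5.0
        mvs = sample_vectors(FlowField(dx=np.zeros_like(dy), dy=dy), make_sample_grid(170, 320, 10))
        assert len(mvs) == 544
        down = mvs.vectors[:, 1] == 5.0
        assert down.sum() == 544 // 2  # exactly the bottom-half markers

    def test_out_of_bounds_point_rejected(self):
        flow = FlowField(dx=np.zeros((20, 20)), dy=np.zeros((20, 20)))
        grid = make_sample_grid(30, 30, 10)
        with pytest.raises(ValueError):
            sample_vectors(flow, grid)


class TestMotionVectors:
    def test_total_empty_is_zero(self):
        assert tuple(total_motion_vector(MotionVectorSet.from_vecs([]))) == (0.0, 0.0)

    def test_total_sums_componentwise(self):
        mvs = MotionVectorSet.from_vecs([(1, 2), (3, -1)])
        assert tuple(total_motion_vector(mvs)) == (4.0, 1.0)

    def test_total_of_544_unit_down_vectors(self):
        mvs = MotionVectorSet.from_vecs([(0, 1)] * 544)
        assert tuple(total_motion_vector(mvs)) == (0.0, 544.0)

    def test_downward_selection_worked_example(self):
        # (0,1.5) fails magnitude; (0,-5) points up; (5,1) has y < half its
        # own magnitude; (1,5) and (0,3) survive.
        mvs = MotionVectorSet.from_vecs([(0, 1.5), (0, -5), (5, 1), (1, 5), (0, 3)])
        assert tuple(downward_motion_vector(mvs))[:2] == (1.0, 8.0)

    def test_downward_all_up_is_zero(self):
        mvs = MotionVectorSet.from_vecs([(0, -3), (1, -4)])
        assert tuple(downward_motion_vector(mvs)) == (0.0, 0.0)

    def test_downward_pure_survivor(self):
        v = downward_motion_vector(MotionVectorSet.from_vecs([(0, 10)]))
        assert tuple(v) == (0.0, 10.0) and v.magnitude == pytest.approx(10.0)

    def test_boundary_magnitude_two_is_kept(self):
        assert tuple(downward_motion_vector(MotionVectorSet.from_vecs([(0, 2.0)]))) == (0.0, 2.0)
        assert tuple(upward_motion_vector(MotionVectorSet.from_vecs([(0, -2.0)]))) == (0.0, -2.0)

    def test_upward_selection_worked_example(self):
        mvs = MotionVectorSet.from_vecs([(0, -5), (0, 1.5), (3, -4)])
        v = upward_motion_vector(mvs)
        assert tuple(v) == (3.0, -9.0)
        assert v.magnitude == pytest.approx(math.sqrt(90))

    def test_upward_all_down_is_zero(self):
        assert tuple(upward_motion_vector(MotionVectorSet.from_vecs([(0, 3), (1, 5)]))) == (0.0, 0.0)

    def test_total_criterion_variant_references_unfiltered_sum(self):
        # With the "total" reading, criterion (iii) compares y to half the
        # magnitude of the unfiltered vector sum.
        vecs = [(0.0, 3.0), (4.0, 3.0)]
        total_mag = math.hypot(4.0, 6.0)
        expect = [v for v in vecs if v[1] >= 0.5 * total_mag]
        got = downward_motion_vector(MotionVectorSet.from_vecs(vecs), criterion="total")
        assert tuple(got) == (sum(v[0] for v in expect), sum(v[1] for v in expect))


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.floats(-20, 20, allow_nan=False, width=32),
            st.floats(-20, 20, allow_nan=False, width=32),
        ),
        max_size=60,
    )
)
def test_selection_matches_bruteforce_and_sets_disjoint(vecs):
    """DMV/UMV equal an independent criteria loop; survivor sets are disjoint."""
    mvs = MotionVectorSet.from_vecs(vecs)
    assert tuple(downward_motion_vector(mvs)) == pytest.approx(dmv_brute(vecs), abs=1e-9)
    assert tuple(upward_motion_vector(mvs)) == pytest.approx(umv_brute(vecs), abs=1e-9)
    for x, y in vecs:
        down = math.hypot(x, y) >= 2 and y > 0 and y >= 0.5 * math.hypot(x, y)
        up = math.hypot(x, y) >= 2 and y < 0
        assert not (down and up)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.floats(-10, 10, allow_nan=False), st.floats(-10, 10, allow_nan=False)),
        min_size=1,
        max_size=30,
    ),
    st.floats(1.5, 5.0, allow_nan=False),
)
def test_scaling_survivors_scales_sums(vecs, c):
    """Once every vector's magnitude reaches 2, scaling by c scales the sums by c."""
    big = [(c * x, c * y) for x, y in vecs if math.hypot(x, y) >= 2.0 / min(c, 1)]
    big = [(x, y) for x, y in big if math.hypot(x, y) >= 2.0]
    scaled_again = [(2 * x, 2 * y) for x, y in big]
    d1 = downward_motion_vector(MotionVectorSet.from_vecs(big))
    d2 = downward_motion_vector(MotionVectorSet.from_vecs(scaled_again))
    assert d2.x == pytest.approx(2 * d1.x, abs=1e-9)
    assert d2.y == pytest.approx(2 * d1.y, abs=1e-9)


def test_vec2_magnitude_consistency():
    v = Vec2(3.0, 4.0)
    assert v.magnitude == pytest.approx(5.0, abs=1e-9)
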