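import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from msystems.geometry import (
    Pose,
    TileShape,
    brownian_step,
    overlap,
    point_in_polyhedron,
    reflect_into_box,
    shape_distance,
    to_world,
)


def unit_square():
    return TileShape.rectangle(1.0, 1.0)


class TestToWorld:
    @pytest.mark.parametrize(
        "pose, p, expected",
        [
            (Pose.identity(), (1, 2, 3), (1, 2, 3)),
            (Pose((1, 0, 0)), (0, 0, 0), (1, 0, 0)),
            (
                Pose.from_rotation(Rotation.from_euler("z", np.pi / 2)),
                (1, 0, 0),
                (0, 1, 0),
            ),
        ],
    )
    def test_examples(self, pose, p, expected):
        assert np.allclose(to_world(pose, p), expected, atol=1e-9)

    def test_rejects_non_unit_quaternion(self):
        with pytest.raises(ValueError, match="norm"):
            Pose((0, 0, 0), (1.0, 1.0, 0.0, 0.0))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-10, 10), min_size=10, max_size=10))
    def test_rigid_transform_preserves_distances(self, vals):
        a = np.array(vals[:3])
        b = np.array(vals[3:6])
        rot = Rotation.from_euler("xyz", vals[6:9])
        pose = Pose.from_rotation(rot, (vals[9], 0.0, 1.0))
        d0 = np.linalg.norm(a - b)
        d1 = np.linalg.norm(to_world(pose, a) - to_world(pose, b))
        assert abs(d0 - d1) < 1e-9


class TestOverlap:
    def test_coincident_squares_overlap(self):
        s = unit_square()
        assert overlap(s, Pose.identity(), s, Pose.identity(), 0.01)

    def test_distant_squares_do_not(self):
        s = unit_square()
        assert not overlap(s, Pose.identity(), s, Pose((10, 0, 0)), 0.01)

    def test_parallel_planes_within_clearance(self):
        # analytic oracle: parallel unit squares 0.005 apart -> distance
        # is exactly the plane separation
        s = unit_square()
        d = shape_distance(s, Pose.identity(), s, Pose((0, 0, 0.005)))
        assert abs(d - 0.005) < 1e-9
        assert overlap(s, Pose.identity(), s, Pose((0, 0, 0.005)), 0.01)
        assert not overlap(s, Pose.identity(), s, Pose((0, 0, 0.05)), 0.01)

    def test_symmetric(self):
        s = unit_square()
        r = TileShape.rod(1.0)
        pa, pb = Pose.identity(), Pose((0.3, 0.4, 0.2))
        assert shape_distance(s, pa, r, pb) == pytest.approx(
            shape_distance(r, pb, s, pa), abs=1e-12
        )

    def test_rod_crossing_polygon_touches(self):
        s = unit_square()
        rod = TileShape("rod1D", np.array([[0.0, 0.0, -1.0], [0.0, 0.0, 1.0]]))
        assert shape_distance(s, Pose.identity(), rod, Pose.identity()) == 0.0

    def test_negative_clearance_rejected(self):
        s = unit_square()
        with pytest.raises(ValueError):
            overlap(s, Pose.identity(), s, Pose.identity(), -1.0)


class TestBrownian:
    def test_zero_step_is_identity(self, rng):
        p = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(brownian_step(p, 0.0, rng), p)

    def test_norm_equals_step(self, rng):
        for _ in range(100):
            q = brownian_step(np.zeros(3), 1.0, rng)
            assert abs(np.linalg.norm(q) - 1.0) < 1e-9

    def test_direction_uniform_on_sphere(self, rng):
        # Monte-Carlo check of the uniform-sphere sampler
        pts = np.array([brownian_step(np.zeros(3), 1.0, rng) for _ in range(10000)])
        assert np.all(np.abs(pts.mean(axis=0)) < 0.04)

    def test_reflection_keeps_point_in_box(self, rng):
        lo, hi = np.zeros(3), np.ones(3)
        p = np.array([0.5, 0.5, 0.5])
        for _ in range(200):
            p = brownian_step(p, 0.9, rng, bounds=(lo, hi))
            assert np.all(p >= lo) and np.all(p <= hi)

    def test_reflect_into_box_folds(self):
        q = reflect_into_box(np.array([1.25, -0.25, 0.5]), np.zeros(3), np.ones(3))
        assert np.allclose(q, [0.75, 0.25, 0.5])


class TestPointInPolyhedron:
    def test_unit_cube(self, rng):
        c = [
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]],
            [[0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]],
            [[0, 0, 0], [1, 0, 0], [1, 0, 1], [0, 0, 1]],
            [[0, 1, 0], [1, 1, 0], [1, 1, 1], [0, 1, 1]],
            [[0, 0, 0], [0, 1, 0], [0, 1, 1], [0, 0, 1]],
            [[1, 0, 0], [1, 1, 0], [1, 1, 1], [1, 0, 1]],
        ]
        faces = [np.array(f, dtype=float) for f in c]
        assert point_in_polyhedron((0.5, 0.5, 0.5), faces, rng)
        assert not point_in_polyhedron((1.5, 0.5, 0.5), faces, rng)
        assert not point_in_polyhedron((0.5, 0.5, -2.0), faces, rng)


class TestShapes:
    def test_regular_polygon_edge_length(self):
        oct_ = TileShape.regular_polygon(8, 1.0)
        v = oct_.vertices
        edges = np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)
        assert np.allclose(edges, 1.0)

    def test_polygon_requires_coplanarity(self):
        with pytest.raises(ValueError, match="coplanar"):
            TileShape(
                "polygon2D",
                np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0.5], [0, 1, 0]], dtype=float),
            )

    def test_rod_requires_positive_length(self):
        with pytest.raises(ValueError, match="length"):
            TileShape("rod1D", np.zeros((2, 3)))
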