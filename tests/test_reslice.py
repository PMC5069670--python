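"""Plane fitting, alignment angles, volume rotation, flat/curved reslices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import slotkit as sk
from slotkit.core import DataError, ValidationError, Volume3D
from slotkit.reslice import rotation_matrix

EZ = np.array([0.0, 0.0, 1.0])


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


class TestPlaneFromLandmarks:
    def test_unit_axes_triangle(self):
        lm = sk.Landmarks((0, 0, 0), (1, 0, 0), (0, 1, 0))
        plane = sk.plane_from_landmarks(lm)
        assert plane.normal == pytest.approx((0, 0, 1))
        assert plane.point == (0, 0, 0)

    def test_collinear_landmarks_rejected(self):
        with pytest.raises(ValidationError, match="collinear"):
            sk.Landmarks((0, 0, 0), (1, 0, 0), (2, 0, 0))

    def test_normal_orthogonal_to_edges(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            pts = rng.normal(size=(3, 3)) * 10
            if np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0])) < 1e-3:
                continue
            plane = sk.plane_from_landmarks(
                sk.Landmarks(tuple(pts[0]), tuple(pts[1]), tuple(pts[2]))
            )
            n = np.asarray(plane.normal)
            assert abs(n @ (pts[1] - pts[0])) < 1e-9 * np.linalg.norm(pts[1] - pts[0])
            assert abs(n @ (pts[2] - pts[0])) < 1e-9 * np.linalg.norm(pts[2] - pts[0])
            assert n[2] >= 0   # canonical orientation


class TestAlignmentAngles:
    def test_already_aligned_normal(self):
        a = sk.alignment_angles(sk.PlaneSpec((0, 0, 0), (0, 0, 1)))
        assert a.alpha_x == 0.0 and a.alpha_y == 0.0

    def test_printed_relation_example(self):
        n = _unit((0.3, 0.4, np.sqrt(1 - 0.09 - 0.16)))
        a = sk.alignment_angles(sk.PlaneSpec((0, 0, 0), tuple(n)))
        assert abs(np.sin(a.alpha_x)) == pytest.approx(0.4, abs=1e-12)
        assert abs(np.sin(a.alpha_y)) == pytest.approx(0.3 / np.cos(a.alpha_x), abs=1e-12)
        assert rotation_matrix(a) @ n == pytest.approx(EZ, abs=1e-12)

    def test_gimbal_normal_rejected(self):
        with pytest.raises(ValidationError, match="gimbal"):
            sk.alignment_angles(sk.PlaneSpec((0, 0, 0), (0, 1, 0)))

    @given(st.integers(min_value=0, max_value=9999))
    @settings(max_examples=200, derandomize=True)
    def test_rotation_pair_maps_normal_to_stack_axis(self, i):
        rng = np.random.default_rng(i)
        n = _unit(rng.normal(size=3))
        if np.sqrt(1 - min(n[1] ** 2, 1.0)) < 1e-6:
            return   # gimbal neighbourhood, excluded by contract
        a = sk.alignment_angles(sk.PlaneSpec((0, 0, 0), tuple(n)))
        n_canon = n if n[2] >= 0 else -n
        assert np.linalg.norm(rotation_matrix(a) @ n_canon - EZ) < 1e-9
        assert abs(abs(np.sin(a.alpha_y)) - abs(n[0] / np.cos(a.alpha_x))) < 1e-9


class TestRotateVolume:
    def test_zero_angles_identity(self, blob_volume):
        out = sk.rotate_volume(blob_volume, sk.AlignmentAngles(0.0, 0.0))
        assert np.array_equal(out.data, blob_volume.data)

    def test_round_trip_interior(self):
        rng = np.random.default_rng(3)
        from scipy import ndimage

        data = ndimage.gaussian_filter(rng.random((48, 48, 48)), 2).astype(np.float32)
        v = Volume3D(data, (1, 1, 1), "reconstructed")
        a = sk.AlignmentAngles(0.3, -0.2)
        back = sk.rotate_volume(sk.rotate_volume(v, a), a, inverse=True)
        # compare on the interior, away from zero-padded borders
        off = tuple((b - s) // 2 for b, s in zip(back.shape, v.shape))
        core = back.data[
            off[0] + 8 : off[0] + 40, off[1] + 8 : off[1] + 40, off[2] + 8 : off[2] + 40
        ]
        ref = data[8:40, 8:40, 8:40]
        err = np.sqrt(np.mean((core - ref) ** 2)) / (ref.max() - ref.min())
        assert err < 0.02

    def test_planted_plane_collapses_to_thin_slab(self):
        n = 64
        true_n = _unit((0.25, 0.35, 0.9))
        c = (n - 1) / 2
        zz, yy, xx = np.meshgrid(*[np.arange(n) - c] * 3, indexing="ij")
        d = true_n[0] * xx + true_n[1] * yy + true_n[2] * zz
        v = Volume3D(np.exp(-(d**2) / 2).astype(np.float32), (1, 1, 1), "reconstructed")
        a = sk.alignment_angles(sk.PlaneSpec((c, c, c), tuple(true_n)))
        rot = sk.rotate_volume(v, a)
        bright = np.argwhere(rot.data > 0.8 * rot.data.max())
        assert bright[:, 0].max() - bright[:, 0].min() <= 2


class TestExtractReslice:
    def test_integer_index_is_exact_slice(self, blob_volume):
        assert np.array_equal(sk.extract_reslice(blob_volume, 1), blob_volume.data[1])

    def test_fractional_index_interpolates(self):
        data = np.arange(4, dtype=float)[:, None, None] * np.ones((1, 3, 3))
        v = Volume3D(data, (1, 1, 1), "reconstructed")
        sl = sk.extract_reslice(v, 1.5)
        assert np.allclose(sl, 1.5)

    def test_out_of_range_rejected(self, blob_volume):
        with pytest.raises(ValidationError):
            sk.extract_reslice(blob_volume, blob_volume.shape[0])


class TestCurvedReslice:
    def test_straight_path_equals_flat_strip(self):
        rng = np.random.default_rng(8)
        data = rng.random((10, 20, 20))
        v = Volume3D(data, (1, 1, 1), "reconstructed")
        path = sk.PolylinePath(vertices=((3.0, 2.0), (3.0, 14.0)))
        out = sk.curved_reslice(v, path)
        assert out.shape == (10, 12)
        assert np.allclose(out, data[:, 2:14, 3])

    def test_l_shaped_path_width(self):
        v = Volume3D(np.zeros((4, 32, 32)), (1, 1, 1), "reconstructed")
        path = sk.PolylinePath(vertices=((2.0, 2.0), (12.5, 2.0), (12.5, 9.0)))
        out = sk.curved_reslice(v, path)
        assert out.shape[1] == int(np.ceil(10.5 + 7.0))

    def test_matches_pointwise_trilinear_oracle(self):
        rng = np.random.default_rng(9)
        data = rng.random((6, 24, 24))
        v = Volume3D(data, (1, 1, 1), "reconstructed")
        verts = ((2.2, 3.1), (15.7, 8.4), (9.3, 19.2))
        path = sk.PolylinePath(vertices=verts)
        out = sk.curved_reslice(v, path)

        # independent per-point trilinear evaluator
        from slotkit.reslice import _arc_length_samples

        pts = _arc_length_samples(np.asarray(verts))
        for s in range(0, pts.shape[0], 5):
            x, y = pts[s]
            for z in range(6):
                x0, y0 = int(np.floor(x)), int(np.floor(y))
                fx, fy = x - x0, y - y0
                val = (
                    data[z, y0, x0] * (1 - fy) * (1 - fx)
                    + data[z, y0, x0 + 1] * (1 - fy) * fx
                    + data[z, y0 + 1, x0] * fy * (1 - fx)
                    + data[z, y0 + 1, x0 + 1] * fy * fx
                )
                assert out[z, s] == pytest.approx(val, abs=1e-6)

    def test_path_outside_volume_names_vertex(self):
        v = Volume3D(np.zeros((4, 8, 8)), (1, 1, 1), "reconstructed")
        with pytest.raises(DataError, match="vertex 1"):
            sk.curved_reslice(v, sk.PolylinePath(vertices=((1.0, 1.0), (20.0, 1.0))))


def test_landmark_noise_pipeline_recovers_normal():
    """Noisy landmarks (sigma = 0.5 voxel) on a planted plane: normal < 2 deg off."""
    rng = np.random.default_rng(12)
    true_n = _unit((0.2, 0.3, 0.93))
    c = 32.0
    e1 = _unit(np.cross(true_n, EZ))
    e2 = np.cross(true_n, e1)
    pts = [
        c + a * e1 + b * e2 + rng.normal(0, 0.5, 3)
        for a, b in [(-20, -14), (22, -8), (3, 20)]
    ]
    plane = sk.plane_from_landmarks(
        sk.Landmarks(tuple(pts[0]), tuple(pts[1]), tuple(pts[2]))
    )
    dev = np.degrees(np.arccos(np.clip(abs(np.dot(plane.normal, true_n)), 0, 1)))
    assert dev < 2.0
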