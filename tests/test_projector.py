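"""Forward projection: Beer-Lambert, sinusoid traces, fan geometry."""

from types import SimpleNamespace

import numpy as np
import pytest

import slotkit as sk
from slotkit.core import FanGeometry, ValidationError, Volume3D


def _pair(fluorescence: Volume3D, absorption: Volume3D | None = None):
    if absorption is None:
        absorption = Volume3D(
            np.zeros_like(fluorescence.data), fluorescence.spacing, "absorption"
        )
    return SimpleNamespace(absorption=absorption, fluorescence=fluorescence)


def _point_volume(n=96, r=30.0, phi0_deg=40.0, rows=2):
    vol = np.zeros((n, rows, n), dtype=np.float32)
    c = (n - 1) / 2
    phi0 = np.deg2rad(phi0_deg)
    vol[int(round(c + r * np.sin(phi0))), :, int(round(c + r * np.cos(phi0)))] = 1.0
    return Volume3D(vol, (1, 1, 1), "fluorescence")


class TestParallelProjection:
    def test_empty_phantom_gives_i0_and_zero(self):
        v = Volume3D(np.zeros((16, 4, 16), np.float32), (1, 1, 1), "fluorescence")
        geom = sk.default_geometry(v, 8, i0=3.0)
        trans, fluo = sk.forward_project(_pair(v), geom)
        assert np.allclose(trans.data, 3.0)
        assert np.allclose(fluo.data, 0.0)

    def test_uniform_slab_beer_lambert(self):
        # mu = 0.01/um over a 100 um path -> central transmission = i0 * e^-1
        sp = 2.0
        vol = np.zeros((64, 2, 64), dtype=np.float32)
        vol[7:57, :, 20:44] = 0.01
        absorption = Volume3D(vol, (sp, sp, sp), "absorption")
        fluo_vol = Volume3D(np.zeros_like(vol), (sp, sp, sp), "fluorescence")
        geom = sk.default_geometry(absorption, 1, i0=2.0)
        trans, _ = sk.forward_project(_pair(fluo_vol, absorption), geom)
        assert trans.data[0, 0, 32] == pytest.approx(2.0 * np.exp(-1.0), rel=1e-5)

    def test_point_traces_a_sinusoid(self):
        n, r, phi0_deg = 96, 30.0, 40.0
        v = _point_volume(n, r, phi0_deg)
        geom = sk.default_geometry(v, 96)
        sino = sk.project_volume(v, geom)
        phis = np.deg2rad(geom.angles_deg)
        expected = (n - 1) / 2 + r * np.cos(phis - np.deg2rad(phi0_deg))
        w = sino[:, 0, :]
        centroid = (w * np.arange(n)).sum(axis=1) / w.sum(axis=1)
        assert np.abs(centroid - expected).max() < 1.0

    def test_fluorescence_linearity(self, blob_volume):
        geom = sk.default_geometry(blob_volume, 24)
        s1 = sk.project_volume(blob_volume, geom)
        s2 = sk.project_volume(blob_volume.with_data(2.5 * blob_volume.data), geom)
        assert np.allclose(s2, 2.5 * s1, atol=1e-4 * s1.max())

    def test_mass_conserved_across_angles(self, blob_volume):
        geom = sk.default_geometry(blob_volume, 90)
        s = sk.project_volume(blob_volume, geom)
        row_sums = s.sum(axis=2)[:, 0]
        true = blob_volume.data[:, 0, :].sum() * blob_volume.spacing[0]
        assert (row_sums.max() - row_sums.min()) / row_sums.mean() < 0.005
        assert row_sums.mean() == pytest.approx(true, rel=0.005)

    def test_transmission_bounded_and_log_invertible(self, lobe_phantom):
        geom = sk.default_geometry(lobe_phantom.absorption, 12, i0=1.5)
        trans, _ = sk.forward_project(lobe_phantom, geom)
        assert trans.data.max() <= 1.5 + 1e-6
        assert trans.data.min() > 0
        li = sk.transmission_to_line_integral(trans)
        back = sk.project_volume(lobe_phantom.absorption, geom)
        assert np.allclose(li.data, back, atol=1e-5 * back.max())

    def test_matches_skimage_radon(self):
        """Independent cross-check against skimage's Radon transform.

        skimage's ``theta`` turns the opposite way, so its projection at
        360 - phi corresponds to this projector's at phi.  An odd grid size
        keeps both rotation centres on the same pixel.
        """
        from scipy import ndimage
        from skimage.transform import radon

        rng = np.random.default_rng(17)
        n = 65
        img = ndimage.gaussian_filter(rng.random((n, n)), 2)
        c = (n - 1) / 2
        zz, xx = np.meshgrid(np.arange(n) - c, np.arange(n) - c, indexing="ij")
        img *= (zz**2 + xx**2) <= (n / 2 - 4) ** 2
        v = Volume3D(img[:, None, :].astype(np.float32), (1, 1, 1), "fluorescence")
        geom = sk.default_geometry(v, 48)
        mine = sk.project_volume(v, geom)[:, 0, :]
        theta = (360.0 - geom.angles_deg) % 360.0
        ski = radon(img, theta=theta).T
        assert np.abs(mine - ski).max() < 0.02 * mine.max()

    def test_detector_mismatch_rejected(self, blob_volume):
        geom = sk.AcquisitionGeometry(n_projections=4, detector_x=16, detector_y=3)
        with pytest.raises(sk.DataError):
            sk.project_volume(blob_volume, geom)


class TestFanProjection:
    def test_zero_shear_equals_parallel(self, blob_volume):
        geom_p = sk.default_geometry(blob_volume, 16)
        fan = FanGeometry(shear_rate=0.0, center_x=31.5)
        geom_f = sk.default_geometry(blob_volume, 16, fan=fan)
        tp, fp = sk.forward_project(_pair(blob_volume), geom_p)
        tf, ff = sk.fan_project(_pair(blob_volume), geom_f)
        assert np.array_equal(fp.data, ff.data)
        assert np.array_equal(tp.data, tf.data)

    def test_fan_column_matches_parallel_at_shifted_angle(self, blob_volume):
        """Column x of the fan sinogram is the parallel view at phi + beta(x)."""
        v = blob_volume
        n = v.shape[2]
        rate, cx = 6.0 / ((n - 1) / 2), (n - 1) / 2
        geom_f = sk.default_geometry(v, 120, fan=FanGeometry(rate, cx))
        _, ff = sk.fan_project(_pair(v), geom_f)
        # dense parallel reference to interpolate in angle
        geom_p = sk.default_geometry(v, 720)
        par = sk.project_volume(v, geom_p)
        dphi = 360.0 / 720
        err = []
        for x in range(10, n - 10, 4):
            beta = rate * (x - cx)
            shifted = np.interp(
                np.mod(geom_f.angles_deg + beta, 360.0) / dphi,
                np.arange(720), par[:, 0, x], period=720,
            )
            err.append(np.abs(ff.data[:, 0, x] - shifted).max())
        assert max(err) < 0.02 * par.max()

    def test_center_column_agrees_with_parallel(self, blob_volume):
        n = blob_volume.shape[2]
        cx = (n - 1) / 2
        fan = FanGeometry(shear_rate=0.1, center_x=cx)
        geom_f = sk.default_geometry(blob_volume, 16, fan=fan)
        geom_p = sk.default_geometry(blob_volume, 16)
        _, ff = sk.fan_project(_pair(blob_volume), geom_f)
        _, fp = sk.forward_project(_pair(blob_volume), geom_p)
        # zero tilt at the centre column (x = cx falls between samples; check both)
        mid = n // 2
        scale = fp.data.max()
        assert np.abs(ff.data[:, :, mid] - fp.data[:, :, mid]).max() < 0.02 * scale

    def test_excessive_tilt_rejected(self, blob_volume):
        fan = FanGeometry(shear_rate=2.0, center_x=0.0)   # 126 deg at far edge
        geom = sk.default_geometry(blob_volume, 4, fan=fan)
        with pytest.raises(ValidationError):
            sk.fan_project(_pair(blob_volume), geom)

    def test_fan_requires_fan_geometry(self, blob_volume):
        geom = sk.default_geometry(blob_volume, 4)
        with pytest.raises(ValidationError):
            sk.fan_project(_pair(blob_volume), geom)
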