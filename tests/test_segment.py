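"""ROI screening: diffusion, gradients, watershed, density classification."""

import numpy as np
import pytest

import slotkit as sk
from slotkit.core import ValidationError, Volume3D
from slotkit.segment import DiffusionParams


def _vol(data, spacing=(1, 1, 1)):
    return Volume3D(np.asarray(data, float), spacing, "reconstructed")


class TestAnisotropicDiffusion:
    def test_zero_iterations_is_identity(self):
        rng = np.random.default_rng(0)
        v = _vol(rng.random((8, 8, 8)))
        out = sk.anisotropic_diffusion(v, DiffusionParams(conductance=1.0, iterations=0))
        assert np.array_equal(out.data, v.data)

    def test_uniform_volume_unchanged(self):
        v = _vol(np.full((10, 10, 10), 2.5))
        out = sk.anisotropic_diffusion(v, DiffusionParams(conductance=0.1, iterations=25))
        assert np.allclose(out.data, 2.5, atol=1e-12)

    def test_global_mean_preserved(self):
        rng = np.random.default_rng(1)
        v = _vol(rng.random((12, 12, 12)))
        out = sk.anisotropic_diffusion(v, DiffusionParams(conductance=0.3, iterations=30))
        assert out.data.mean() == pytest.approx(v.data.mean(), rel=1e-6)

    def test_edge_preserved_while_noise_suppressed(self):
        """Step edge survives diffusion but not Gaussian blur at matched denoising."""
        from scipy import ndimage

        rng = np.random.default_rng(2)
        step = np.zeros((20, 20, 48))
        step[..., 24:] = 1.0
        noisy = step + rng.normal(0, 0.1, step.shape)
        out = sk.anisotropic_diffusion(
            _vol(noisy), DiffusionParams(conductance=0.4, iterations=10)
        )

        def edge_contrast(a):
            prof = a.mean(axis=(0, 1))
            return prof[24:27].mean() - prof[21:24].mean()

        def flat_var(a):
            return a[..., 4:20].var()

        base_contrast = edge_contrast(step)
        drop = 1.0 - flat_var(out.data) / flat_var(noisy)
        assert drop > 0.5
        assert edge_contrast(out.data) > 0.9 * base_contrast

        # Gaussian at matched (or stronger) noise reduction blurs the edge
        for sigma in np.arange(0.5, 6.0, 0.25):
            g = ndimage.gaussian_filter(noisy, sigma)
            if 1.0 - flat_var(g) / flat_var(noisy) >= drop:
                assert edge_contrast(g) < 0.9 * base_contrast
                break
        else:
            pytest.fail("no Gaussian sigma matched the diffusion's noise reduction")

    @pytest.mark.parametrize("bad_dt", [0.0, 0.3])
    def test_unstable_time_step_rejected(self, bad_dt):
        with pytest.raises(ValidationError):
            DiffusionParams(conductance=1.0, time_step=bad_dt)


class TestGradientMagnitude:
    def test_constant_volume_gives_zero(self):
        out = sk.gradient_magnitude(_vol(np.full((6, 6, 6), 4.0)))
        assert np.allclose(out.data, 0.0)

    def test_ramp_closed_form(self):
        x = np.arange(16, dtype=float)
        data = np.broadcast_to(3.0 * x, (16, 16, 16))
        out = sk.gradient_magnitude(_vol(data, spacing=(1, 1, 2.0)))
        assert np.allclose(out.data[:, :, 1:-1], 1.5)   # 3 per 2 um

    def test_matches_per_voxel_loop_oracle(self):
        rng = np.random.default_rng(3)
        data = rng.random((6, 7, 8))
        sp = (1.0, 2.0, 0.5)
        out = sk.gradient_magnitude(_vol(data, spacing=sp))
        for z in range(1, 5):
            for y in range(1, 6):
                for x in range(1, 7):
                    gz = (data[z + 1, y, x] - data[z - 1, y, x]) / (2 * sp[0])
                    gy = (data[z, y + 1, x] - data[z, y - 1, x]) / (2 * sp[1])
                    gx = (data[z, y, x + 1] - data[z, y, x - 1]) / (2 * sp[2])
                    assert out.data[z, y, x] == pytest.approx(
                        np.sqrt(gz**2 + gy**2 + gx**2), abs=1e-9
                    )


class TestWatershed:
    def test_two_basins_split_on_ridge(self):
        """Marker flooding of a double-well landscape: brute-force check."""
        n = 16
        x = np.linspace(-1, 1, n)
        _, _, xx = np.meshgrid(x, x, x, indexing="ij")
        grad = 1.0 - np.abs(xx)          # ridge at x = 0, wells at both edges
        markers = np.zeros((n, n, n), int)
        markers[8, 8, 2] = 1
        markers[8, 8, 13] = 2
        lv = sk.watershed_regions(_vol(grad), markers=markers)
        assert set(np.unique(lv.labels)) == {1, 2}
        assert np.all(lv.labels[..., : n // 2] == 1)
        assert np.all(lv.labels[..., n // 2 :] == 2)

    def test_single_marker_fills_domain(self):
        grad = np.random.default_rng(4).random((8, 8, 8))
        markers = np.zeros((8, 8, 8), int)
        markers[4, 4, 4] = 1
        lv = sk.watershed_regions(_vol(grad), markers=markers)
        assert np.all(lv.labels == 1)

    def test_uniform_gradient_gives_voronoi(self):
        grad = np.zeros((9, 9, 9))
        markers = np.zeros((9, 9, 9), int)
        markers[4, 4, 1] = 1
        markers[4, 4, 7] = 2
        lv = sk.watershed_regions(_vol(grad), markers=markers)
        assert np.all(lv.labels[..., :4] == 1)
        assert np.all(lv.labels[..., 5:] == 2)

    def test_labels_partition_and_bounded_by_markers(self):
        grad = np.random.default_rng(5).random((10, 10, 10))
        markers = np.zeros((10, 10, 10), int)
        markers[2, 2, 2] = 1
        markers[7, 7, 7] = 2
        markers[2, 7, 5] = 3
        lv = sk.watershed_regions(_vol(grad), markers=markers)
        assert np.all(lv.labels > 0)
        assert len(np.unique(lv.labels)) <= 3

    def test_needs_markers_or_level(self):
        with pytest.raises(ValidationError):
            sk.watershed_regions(_vol(np.zeros((4, 4, 4))))


class TestClassifyRegions:
    def test_threshold_above_max_gives_no_fibrotic(self):
        labels = sk.watershed_regions(
            _vol(np.zeros((6, 6, 6))), markers=np.ones((6, 6, 6), int)
        )
        intensity = _vol(np.random.default_rng(6).random((6, 6, 6)))
        out, report = sk.classify_regions(labels, intensity, density_threshold=5.0)
        assert (report["class"] == "fibrotic").sum() == 0

    def test_bimodal_blob_classified_at_midpoint(self):
        rng = np.random.default_rng(7)
        intensity = np.full((16, 16, 16), 1.0) + rng.normal(0, 0.05, (16, 16, 16))
        intensity[4:10, 4:10, 4:10] = 2.0 + rng.normal(0, 0.05, (6, 6, 6))
        labels = np.ones((16, 16, 16), int)
        labels[4:10, 4:10, 4:10] = 2
        lv = sk.LabelVolume(labels=labels)
        out, report = sk.classify_regions(lv, _vol(intensity), density_threshold=1.5)
        assert out.class_map[2] == "fibrotic"
        assert out.class_map[1] == "parenchyma"
        assert np.array_equal(out.mask_of("fibrotic"), labels == 2)


class TestScreeningPipeline:
    def test_phantom_fibrosis_recovered(self, lobe_phantom):
        _, report, fib = sk.screen_rois(lobe_phantom.absorption)
        truth = lobe_phantom.truth_labels.data == 4
        dice = 2 * np.logical_and(fib, truth).sum() / (fib.sum() + truth.sum())
        assert dice > 0.7

    def test_median_dice_over_seeded_phantoms(self):
        dices = []
        for seed in range(5):
            p = sk.PhantomParams(
                shape=(64, 64, 64), voxel_size=30.0, fibrosis_fraction=0.1, seed=seed
            )
            pair = sk.make_lobe_phantom(p)
            _, _, fib = sk.screen_rois(pair.absorption)
            truth = pair.truth_labels.data == 4
            dices.append(2 * np.logical_and(fib, truth).sum() / (fib.sum() + truth.sum()))
        assert np.median(dices) > 0.7
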