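"""Tests of centrosome detection, segmentation, and measurement."""

import numpy as np
import pytest

from pcmflux import Emitter, SimConfig, render_frame, simulate_centrosome_field
from pcmflux.quant import (
    Detection,
    correct_uneven_illumination,
    detect_centrosomes,
    fold_enrichment,
    max_project,
    measure_beads,
    measure_objects,
    otsu_threshold,
)


def otsu_bruteforce(image, n_bins=256):
    """Independent exhaustive scan over all candidate bin-edge thresholds."""
    image = np.asarray(image, dtype=float).ravel()
    counts, edges = np.histogram(image, bins=n_bins, range=(image.min(), image.max()))
    n = counts.sum()
    centers = np.arange(n_bins) + 0.5
    best_t, best_v = None, -np.inf
    for k in range(1, n_bins):
        w0 = counts[:k].sum()
        w1 = n - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        v = (w0 / n) * (w1 / n) * (mu0 - mu1) ** 2
        if v > best_v:  # strict: ties keep the lower threshold
            best_v, best_t = v, edges[k]
    return best_t


class TestIlluminationCorrection:
    def test_constant_image_maps_to_zero(self):
        img = np.full((64, 64), 37.0)
        out = correct_uneven_illumination(img, 10.0)
        assert np.all(np.abs(out[8:-8, 8:-8]) < 1e-6 * 37.0)

    def test_planar_gradient_suppressed(self):
        yy, xx = np.mgrid[0:128, 0:128]
        amplitude = 50.0
        img = 100.0 + amplitude * xx / 127.0
        out = correct_uneven_illumination(img, 16.0)
        interior = out[32:-32, 32:-32]
        assert interior.max() - interior.min() <= 0.1 * amplitude

    def test_spot_intensity_preserved_on_gradient(self):
        cfg = SimConfig(image_shape=(128, 128), background_level=0.0)
        spot = render_frame([Emitter((64.0, 64.0), 1.0)], cfg)
        yy, xx = np.mgrid[0:128, 0:128]
        img = spot + 20.0 + 10.0 * xx / 127.0
        out = correct_uneven_illumination(img, 40.0)
        window = out[48:81, 48:81]
        assert window.sum() == pytest.approx(cfg.photon_scale, rel=0.05)

    def test_warns_when_scale_too_small(self):
        with pytest.warns(UserWarning):
            correct_uneven_illumination(np.ones((32, 32)), 5.0, object_diameter_px=9.0)


class TestMaxProject:
    def test_single_slice_identity(self, rng):
        stack = rng.random((1, 16, 16))
        np.testing.assert_array_equal(max_project(stack), stack[0])

    def test_offset_slice_wins(self, rng):
        a = rng.random((16, 16))
        np.testing.assert_array_equal(max_project(np.stack([a, a + 1])), a + 1)

    def test_matches_elementwise_oracle(self, rng):
        stack = rng.random((5, 20, 20))
        expected = np.array(
            [[stack[:, i, j].max() for j in range(20)] for i in range(20)]
        )
        np.testing.assert_array_equal(max_project(stack), expected)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            max_project(np.empty((0, 8, 8)))


class TestDetectCentrosomes:
    def test_even_diameter_rejected(self):
        with pytest.raises(ValueError):
            detect_centrosomes(np.zeros((32, 32)), 8)

    def test_blank_image_empty(self):
        assert detect_centrosomes(np.zeros((64, 64)), 9) == []

    def test_subpixel_localization_noiseless(self):
        cfg = SimConfig(image_shape=(64, 64), background_level=0.0)
        img = render_frame([Emitter((30.4, 33.7), 1.0)], cfg)
        dets = detect_centrosomes(img, 9, min_mass=10)
        assert len(dets) == 1
        assert abs(dets[0].y - 30.4) < 0.1
        assert abs(dets[0].x - 33.7) < 0.1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recall_precision_on_synthetic_field(self, seed):
        cfg = SimConfig(image_shape=(128, 128), n_frames=1)
        stack, truth = simulate_centrosome_field(cfg, 10, seed=seed, min_separation_px=12)
        img = correct_uneven_illumination(stack[0], 30.0)
        dets = detect_centrosomes(img, 9, min_mass=50)
        matched, errs = 0, []
        for row in truth.itertuples():
            d = [np.hypot(d.y - row.y_px, d.x - row.x_px) for d in dets]
            if d and min(d) <= 2.0:
                matched += 1
                errs.append(min(d))
        recall = matched / len(truth)
        precision = matched / max(len(dets), 1)
        assert recall >= 0.95 and precision >= 0.95
        assert np.sqrt(np.mean(np.square(errs))) <= 0.5

    def test_translation_equivariance(self):
        cfg = SimConfig(image_shape=(96, 96), background_level=0.0)
        img = render_frame(
            [Emitter((40.2, 45.8), 1.0), Emitter((60.0, 30.0), 0.8)], cfg
        )
        dy, dx = 5, 3
        shifted = np.roll(img, (dy, dx), axis=(0, 1))
        d0 = sorted(detect_centrosomes(img, 9, min_mass=10), key=lambda d: d.y)
        d1 = sorted(detect_centrosomes(shifted, 9, min_mass=10), key=lambda d: d.y)
        assert len(d0) == len(d1) == 2
        for a, b in zip(d0, d1):
            assert b.y - a.y == pytest.approx(dy, abs=1e-9)
            assert b.x - a.x == pytest.approx(dx, abs=1e-9)


class TestOtsu:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_scan(self, seed):
        rng = np.random.default_rng(seed)
        img = np.concatenate(
            [rng.normal(30, 8, 600), rng.normal(120, 25, 400)]
        ).reshape(40, 25)
        assert otsu_threshold(img) == otsu_bruteforce(img)

    def test_two_value_image(self):
        img = np.array([[0.0] * 8, [100.0] * 8] * 4)
        thr = otsu_threshold(img)
        assert 0.0 < thr < 100.0
        assert np.array_equal(img > thr, img == 100.0)

    def test_bimodal_mixture_misclassification(self):
        rng = np.random.default_rng(5)
        lo = rng.normal(10, 5, 5000)
        hi = rng.normal(200, 5, 5000)
        img = np.concatenate([lo, hi]).reshape(100, 100)
        thr = otsu_threshold(img)
        mis = (lo > thr).sum() + (hi <= thr).sum()
        assert mis / 10000 < 0.01

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full((8, 8), 3.0))

    def test_agrees_with_skimage_within_one_bin(self):
        """Independent library cross-check: conventions differ (bin edge vs
        bin center), so agreement is asserted to within one bin width."""
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(9)
        img = np.concatenate(
            [rng.normal(20, 6, 2000), rng.normal(150, 20, 1000)]
        ).reshape(50, 60)
        bin_width = (img.max() - img.min()) / 256
        assert abs(otsu_threshold(img) - threshold_otsu(img, nbins=256)) <= bin_width


class TestMeasureObjects:
    @staticmethod
    def _disc_image(center, radius, value, shape=(64, 64)):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        img = np.zeros(shape)
        img[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2] = value
        return img

    def test_uniform_disc_exact(self):
        img = self._disc_image((32, 32), 6, 10.0)
        n_px = int((img > 0).sum())
        det = Detection(frame=0, y=32.0, x=32.0, mass=1.0)
        measure_objects(img, 5.0, [det])
        assert det.area_px == n_px
        assert det.sum_intensity == pytest.approx(10.0 * n_px)

    def test_merged_discs_flagged(self):
        img = self._disc_image((32, 28), 6, 10.0) + self._disc_image((32, 36), 6, 10.0)
        d1 = Detection(frame=0, y=32.0, x=28.0, mass=1.0)
        d2 = Detection(frame=0, y=32.0, x=36.0, mass=1.0)
        measure_objects(img, 5.0, [d1, d2])
        assert d1.area_px == d2.area_px
        assert "merged" in d1.flags and "merged" in d2.flags

    def test_subthreshold_detection_flagged(self):
        img = self._disc_image((32, 32), 4, 10.0)
        det = Detection(frame=0, y=10.0, x=10.0, mass=1.0)
        measure_objects(img, 5.0, [det])
        assert det.area_px == 0
        assert "subthreshold" in det.flags

    def test_sum_matches_simulator_truth(self):
        cfg = SimConfig(image_shape=(128, 128), n_frames=1, background_level=0.0)
        stack, truth = simulate_centrosome_field(
            cfg, 6, seed=4, min_separation_px=20, noise=False
        )
        img = stack[0]
        # a low threshold keeps essentially the whole PSF mass in the
        # segmented component (an Otsu cut would trim the Gaussian skirt)
        dets = [
            Detection(frame=0, y=r.y_px, x=r.x_px, mass=1.0) for r in truth.itertuples()
        ]
        measure_objects(img, 0.2, dets)
        for det, row in zip(dets, truth.itertuples()):
            assert det.sum_intensity == pytest.approx(row.sum_intensity, rel=0.05)

    def test_area_invariant_under_monotone_rescale(self):
        img = self._disc_image((32, 32), 5, 10.0) + 1.0
        det = Detection(frame=0, y=32.0, x=32.0, mass=1.0)
        measure_objects(img, 5.0, [det])
        area_orig = det.area_px
        det2 = Detection(frame=0, y=32.0, x=32.0, mass=1.0)
        measure_objects(3.0 * img + 7.0, 3.0 * 5.0 + 7.0, [det2])
        assert det2.area_px == area_orig


class TestFoldEnrichment:
    def test_uniform_image_gives_one(self):
        img = np.full((32, 32), 5.0)
        obj = np.zeros((32, 32), bool)
        obj[10:14, 10:14] = True
        cyto = np.zeros((32, 32), bool)
        cyto[20:30, 20:30] = True
        assert fold_enrichment(img, obj, cyto).fold_enrichment == pytest.approx(1.0)

    def test_known_ratio(self):
        img = np.full((32, 32), 100.0)
        obj = np.zeros((32, 32), bool)
        obj[5:9, 5:9] = True
        img[obj] = 500.0
        cyto = np.zeros((32, 32), bool)
        cyto[20:30, 20:30] = True
        assert fold_enrichment(img, obj, cyto).fold_enrichment == pytest.approx(5.0)

    def test_overlap_rejected(self):
        img = np.ones((16, 16))
        m = np.zeros((16, 16), bool)
        m[4:8, 4:8] = True
        with pytest.raises(ValueError):
            fold_enrichment(img, m, m)

    def test_simulator_brightness_ratio_recovered(self):
        cfg = SimConfig(image_shape=(96, 96), background_level=20.0, rng_seed=11)
        img = render_frame([Emitter((48.0, 48.0), 1.0)], cfg, noise=True)
        corrected = img - 20.0
        yy, xx = np.mgrid[0:96, 0:96]
        obj = (yy - 48) ** 2 + (xx - 48) ** 2 <= 2**2
        cyto = (yy - 20) ** 2 + (xx - 20) ** 2 <= 10**2
        corrected[cyto] += 10.0  # synthetic cytoplasm level
        rec = fold_enrichment(corrected, obj, cyto)
        peak_mean = corrected[obj].mean()
        assert rec.fold_enrichment == pytest.approx(peak_mean / 10.0, rel=0.1)


class TestMeasureBeads:
    def test_empty_image_empty_list(self):
        assert measure_beads(np.zeros((64, 64)), 200.0) == []

    def test_rendered_bead_mean_recovered(self):
        # a 2.7 um bead at 200 nm pixels: Gaussian blob of sigma ~ d/(2 sqrt 2)
        cfg = SimConfig(
            image_shape=(96, 96),
            pixel_size_nm=200.0,
            psf_sigma_nm=2700.0 / (2.0 * np.sqrt(2.0)),
            background_level=0.0,
        )
        img = render_frame([Emitter((48.0, 48.0), 1.0)], cfg)
        beads = measure_beads(img, 200.0, estimated_diameter_um=2.7, quality_threshold=0.5)
        assert len(beads) == 1
        b = beads[0]
        yy, xx = np.mgrid[0:96, 0:96]
        r = 2.7 * 1000.0 / 200.0 / 2.0
        truth_mean = img[(yy - 48.0) ** 2 + (xx - 48.0) ** 2 <= r**2].mean()
        assert b.mean_intensity == pytest.approx(truth_mean, rel=0.02)

    def test_diameter_too_small_rejected(self):
        with pytest.raises(ValueError):
            measure_beads(np.zeros((32, 32)), 1000.0, estimated_diameter_um=0.002)
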