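"""Tests of bleach correction, tracking, recovery fitting, and kymographs."""

import numpy as np
import pytest

from pcmflux import (
    Emitter,
    ScaffoldMode,
    SimConfig,
    render_frame,
    simulate_centrosome_field,
    simulate_frap_movie,
)
from pcmflux.frap import (
    bleach_correct,
    fit_one_phase_association,
    make_kymograph,
    partner_redistribution,
    recovery_curve,
    track_object,
)


def _one_phase(t, y0, plateau, k):
    return y0 + (plateau - y0) * (1.0 - np.exp(-k * t))


def _frap_config(**kw):
    base = dict(
        image_shape=(64, 64),
        n_frames=60,
        frame_interval_s=2.0,
        background_level=0.0,
        read_noise_sd=0.0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestBleachCorrect:
    def test_recovers_simulated_decay_rate(self):
        lam = 0.01
        # Poisson-only noise: with a zero background, clipped Gaussian read
        # noise would add a non-bleaching pedestal to the field mean
        cfg = SimConfig(
            image_shape=(96, 96),
            n_frames=40,
            frame_interval_s=2.0,
            bleach_rate_per_s=lam,
            background_level=0.0,
            read_noise_sd=0.0,
        )
        stack, _ = simulate_centrosome_field(
            cfg, 16, seed=1, min_separation_px=12, brightness_range=(2.0, 3.0)
        )
        corrected, fitted = bleach_correct(
            stack, np.zeros(cfg.image_shape, bool), cfg.frame_interval_s
        )
        assert fitted == pytest.approx(lam, rel=0.05)
        means = corrected.mean(axis=(1, 2))
        rms_flatness = np.sqrt(np.mean((means / means.mean() - 1.0) ** 2))
        assert rms_flatness < 0.02

    def test_no_decay_is_near_identity(self):
        cfg = SimConfig(
            image_shape=(96, 96),
            n_frames=40,
            frame_interval_s=2.0,
            background_level=0.0,
            read_noise_sd=0.0,
        )
        stack, _ = simulate_centrosome_field(cfg, 8, seed=2, min_separation_px=12)
        corrected, fitted = bleach_correct(
            stack, np.zeros(cfg.image_shape, bool), cfg.frame_interval_s
        )
        assert np.all(np.abs(corrected - stack) <= 0.005 * stack.max())

    def test_growth_clipped_with_warning(self):
        t = np.arange(12)
        stack = (100.0 + 5.0 * t)[:, None, None] * np.ones((12, 8, 8))
        with pytest.warns(UserWarning):
            _, lam = bleach_correct(stack, np.zeros((8, 8), bool))
        assert lam == 0.0

    def test_all_excluded_mask_rejected(self):
        with pytest.raises(ValueError):
            bleach_correct(np.ones((12, 8, 8)), np.ones((8, 8), bool))


class TestTrackObject:
    def test_stationary_object_low_jitter(self):
        cfg = SimConfig(image_shape=(64, 64), n_frames=20, background_level=10.0, rng_seed=4)
        rng = np.random.default_rng(4)
        stack = np.stack(
            [render_frame([Emitter((30.0, 30.0), 1.0)], cfg, noise=True, rng=rng) for _ in range(20)]
        )
        pos, flags = track_object(stack, (30.0, 30.0), search_radius_px=6)
        rms = np.sqrt(np.mean((pos - [30.0, 30.0]) ** 2))
        assert rms <= 0.5 and not flags

    def test_linear_drift_recovered(self):
        cfg = SimConfig(image_shape=(64, 64), n_frames=30, background_level=5.0, rng_seed=5)
        rng = np.random.default_rng(5)
        v = 0.3
        stack = np.stack(
            [
                render_frame([Emitter((20.0 + v * f, 30.0), 1.0)], cfg, noise=True, rng=rng)
                for f in range(30)
            ]
        )
        pos, _ = track_object(stack, (20.0, 30.0), search_radius_px=6)
        slope = np.polyfit(np.arange(30), pos[:, 0], 1)[0]
        assert slope == pytest.approx(v, rel=0.1)

    def test_empty_movie_rejected(self):
        with pytest.raises(ValueError):
            track_object(np.empty((0, 8, 8)), (4, 4), 3)


class TestRecoveryCurve:
    def _movie(self, **kw):
        return simulate_frap_movie(
            _frap_config(),
            ScaffoldMode(mode="liquid", exchange_rate_per_s=0.05, **kw),
            (32, 32, 18),
            bleach_frame=5,
            noise=False,
        )

    def test_normalization_identities(self):
        mv = self._movie()
        track = np.tile([32.0, 32.0], (60, 1))
        curve = recovery_curve(mv.stack, track, 5, 18, 2.0)
        assert curve.normalized_intensity[:5].mean() == pytest.approx(1.0)
        assert curve.normalized_intensity[5] == 0.0
        assert curve.times_s[5] == 0.0

    def test_immobile_fraction_sets_plateau(self):
        mv = self._movie(immobile_fraction=0.4)
        track = np.tile([32.0, 32.0], (60, 1))
        curve = recovery_curve(mv.stack, track, 5, 18, 2.0)
        fit = fit_one_phase_association(curve)
        assert fit.plateau == pytest.approx(0.6, rel=0.1)

    def test_no_bleach_rejected(self):
        stack = np.ones((20, 32, 32))
        track = np.tile([16.0, 16.0], (20, 1))
        with pytest.raises(ValueError):
            recovery_curve(stack, track, 5, 6, 1.0)

    def test_normalization_idempotent(self):
        """A stack whose ROI trace is already normalized returns unchanged."""
        t = np.arange(30, dtype=float)
        vals = np.concatenate([np.ones(5), 1.0 - np.exp(-0.2 * (t[5:] - 5))])
        stack = vals[:, None, None] * np.ones((30, 5, 5))
        track = np.tile([2.0, 2.0], (30, 1))
        curve = recovery_curve(stack, track, 5, 0.5, 1.0)
        np.testing.assert_allclose(curve.normalized_intensity, vals, atol=1e-12)


class TestOnePhaseFit:
    def test_exact_inversion(self):
        t = np.linspace(0, 120, 40)
        y = _one_phase(t, 0.0, 0.8, 0.05)
        fit = fit_one_phase_association((t, y))
        assert fit.Y0 == pytest.approx(0.0, abs=1e-6)
        assert fit.plateau == pytest.approx(0.8, rel=1e-6)
        assert fit.K == pytest.approx(0.05, rel=1e-6)
        assert fit.t_half == pytest.approx(np.log(2) / fit.K)
        assert fit.mobile_fraction == pytest.approx(0.8, rel=1e-6)

    def test_noisy_K_median_error(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 120, 40)
        errs = []
        for _ in range(50):
            y = _one_phase(t, 0.05, 0.8, 0.05) + rng.normal(0, 0.05 * 0.8, t.size)
            fit = fit_one_phase_association((t, y))
            errs.append(abs(fit.K - 0.05) / 0.05)
        assert np.median(errs) <= 0.10

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_one_phase_association((np.arange(4.0), np.arange(4.0)))


class TestKymograph:
    def test_constant_movie_columns_identical(self):
        stack = np.tile(np.arange(64.0).reshape(8, 8)[None], (5, 1, 1))
        k = make_kymograph(stack, ((1.0, 1.0), (6.0, 6.0)), 1)
        assert np.all(k.data == k.data[:, :1])

    def test_moving_spot_slope(self):
        cfg = SimConfig(image_shape=(32, 128), background_level=0.0)
        v = 2.0
        stack = np.stack(
            [render_frame([Emitter((16.0, 10.0 + v * f), 1.0)], cfg) for f in range(40)]
        )
        k = make_kymograph(stack, ((16.0, 5.0), (16.0, 120.0)), 3)
        ridge = k.data.argmax(axis=0)
        slope = np.polyfit(np.arange(40), ridge.astype(float), 1)[0]
        assert slope == pytest.approx(v, rel=0.05)

    def test_matches_resampling_oracle(self, rng):
        """Brute-force bilinear sampling reproduces the kymograph exactly."""
        stack = rng.random((4, 24, 24))
        (y0, x0), (y1, x1) = (3.2, 4.1), (18.9, 20.3)
        width = 3
        k = make_kymograph(stack, ((y0, x0), (y1, x1)), width)
        length = np.hypot(y1 - y0, x1 - x0)
        n = int(np.floor(length)) + 1
        s = np.linspace(0, length, n)
        uy, ux = (y1 - y0) / length, (x1 - x0) / length
        py, px = -ux, uy
        expected = np.empty((n, 4))
        for fi in range(4):
            img = stack[fi]

            def bilinear(yy, xx):
                yy = min(max(yy, 0.0), 22.999999)
                xx = min(max(xx, 0.0), 22.999999)
                i, j = int(yy), int(xx)
                fy, fx = yy - i, xx - j
                return (
                    img[i, j] * (1 - fy) * (1 - fx)
                    + img[i + 1, j] * fy * (1 - fx)
                    + img[i, j + 1] * (1 - fy) * fx
                    + img[i + 1, j + 1] * fy * fx
                )

            for si in range(n):
                vals = [
                    bilinear(y0 + s[si] * uy + o * py, x0 + s[si] * ux + o * px)
                    for o in (-1, 0, 1)
                ]
                expected[si, fi] = np.mean(vals)
        np.testing.assert_allclose(k.data, expected, atol=1e-10)

    def test_degenerate_line_rejected(self):
        with pytest.raises(ValueError):
            make_kymograph(np.ones((3, 8, 8)), ((2.0, 2.0), (2.0, 2.0)), 1)


class TestPartnerRedistribution:
    def _paired(self, mode, seed=0, noise=False):
        scaffold = (
            ScaffoldMode(mode="liquid", exchange_rate_per_s=0.05)
            if mode == "liquid"
            else ScaffoldMode(
                mode="solid", exchange_rate_per_s=0.05, internal_mixing=False
            )
        )
        cfg = SimConfig(
            image_shape=(64, 128),
            n_frames=60,
            frame_interval_s=2.0,
            background_level=0.0,
            read_noise_sd=0.0,
            rng_seed=seed,
        )
        return simulate_frap_movie(
            cfg, scaffold, (32, 30, 16), bleach_frame=5, paired=True, seed=seed, noise=noise
        )

    def test_liquid_mode_partner_loss_positive(self):
        mv = self._paired("liquid")
        b = np.tile(mv.truth["centers"][0], (60, 1))
        p = np.tile(mv.truth["centers"][1], (60, 1))
        series, loss = partner_redistribution(mv.stack, b, p, 14, 5)
        assert series[:5].mean() == pytest.approx(1.0)
        assert loss > 0

    def test_solid_mode_partner_flat(self):
        mv = self._paired("solid")
        b = np.tile(mv.truth["centers"][0], (60, 1))
        p = np.tile(mv.truth["centers"][1], (60, 1))
        _, loss = partner_redistribution(mv.stack, b, p, 14, 5)
        assert abs(loss) < 0.01

    def test_overlapping_rois_rejected(self):
        stack = np.ones((20, 32, 32))
        a = np.tile([16.0, 10.0], (20, 1))
        b = np.tile([16.0, 14.0], (20, 1))
        with pytest.raises(ValueError):
            partner_redistribution(stack, a, b, 6, 5)


class TestBleachRecoveryConsistency:
    def test_fitted_K_invariant_to_global_bleaching(self):
        """Bleach-correcting a movie with lambda > 0 gives the same K as the
        lambda = 0 movie at matched seed."""
        fits = {}
        for lam in (0.0, 0.004):
            cfg = _frap_config(bleach_rate_per_s=lam, n_frames=80)
            mv = simulate_frap_movie(
                cfg,
                ScaffoldMode(mode="liquid", exchange_rate_per_s=0.05),
                (32, 32, 18),
                bleach_frame=5,
                seed=11,
                noise=False,
                cyto_level=5.0,
            )
            stack = mv.stack
            if lam > 0:
                yy, xx = np.mgrid[0:64, 0:64]
                mask = (yy - 32) ** 2 + (xx - 32) ** 2 <= 22**2
                stack, fitted = bleach_correct(stack, mask, cfg.frame_interval_s)
                assert fitted == pytest.approx(lam, rel=0.05)
            track = np.tile([32.0, 32.0], (80, 1))
            curve = recovery_curve(stack, track, 5, 18, cfg.frame_interval_s)
            fits[lam] = fit_one_phase_association(curve).K
        assert fits[0.004] == pytest.approx(fits[0.0], rel=0.05)
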