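"""Velocity decoding, background correction, anti-aliasing, segmentation,
flow integration and SNR/CNR."""

import numpy as np
import pytest

from sweepflow.flow import (
    RAYLEIGH_SD_FACTOR,
    EmptyLumenError,
    correct_background_phase,
    decode_velocity,
    mean_flow,
    segment_lumen,
    snr_cnr,
    unwrap_aliasing,
)
from sweepflow.phantom import evaluate_background_phase


def _encode(v, venc=150.0, mag=1.0):
    """Synthesise the four encoding images for a velocity field (3, nx, ny)."""
    out = [np.full(v.shape[1:], mag, dtype=complex)]
    for axis in (2, 0, 1):  # TP, X, Y
        out.append(mag * np.exp(1j * np.pi * v[axis] / venc))
    return np.stack(out)


class TestDecodeVelocity:
    def test_identical_images_decode_to_zero(self, rng):
        x = rng.standard_normal((5, 5)) + 1j * rng.standard_normal((5, 5))
        enc = np.stack([x, x, x, x])
        np.testing.assert_allclose(decode_velocity(enc, 150.0), 0.0, atol=1e-12)

    def test_quarter_turn_decodes_to_half_venc(self):
        enc = np.stack([np.ones((2, 2), complex)] * 4)
        enc[1] *= np.exp(1j * np.pi / 2)
        v = decode_velocity(enc, 150.0)
        np.testing.assert_allclose(v[2], 75.0)

    def test_round_trip_within_venc(self, rng):
        v = rng.uniform(-140, 140, (3, 6, 6))
        got = decode_velocity(_encode(v), 150.0)
        np.testing.assert_allclose(got, v, atol=1e-10)

    def test_beyond_venc_wraps_to_negative(self):
        v = np.zeros((3, 2, 2))
        v[2] = 200.0
        got = decode_velocity(_encode(v), 150.0)
        np.testing.assert_allclose(got[2], -100.0, atol=1e-9)


class TestBackgroundCorrection:
    def _grid(self, n=32, vox=1.2):
        x = (np.arange(n) - n // 2) * vox
        return x, x

    def test_zero_background_changes_little(self, rng):
        x, y = self._grid()
        v = rng.normal(0.0, 0.02, (32, 32))
        mask = np.ones((32, 32), bool)
        corrected, _ = correct_background_phase(v, mask, x, y)
        assert np.abs(corrected - v).max() < 0.1

    def test_recovers_injected_second_order_coefficients(self):
        """Noiseless polynomial field: fit matches injected coefficients to 1%."""
        x, y = self._grid()
        coeffs = (2.0, 0.05, -0.03, 8e-4, -5e-4, 6e-4)  # cm/s over mm
        field = evaluate_background_phase(coeffs, x, y)  # same poly basis
        mask = np.ones(field.shape, bool)
        mask[10:20, 12:22] = False  # "vessel" hole
        corrected, fit = correct_background_phase(field, mask, x, y)
        np.testing.assert_allclose(fit.coeffs, coeffs, rtol=0.01)
        assert np.abs(corrected).max() < 1e-8
        assert fit.residual_mean_cm_s < 0.5

    def test_lumen_bias_small_after_correction(self, rng):
        """Correction subtracts the fit everywhere, leaving the vessel offset
        below 1 cm/s when the background is truly second order."""
        x, y = self._grid()
        coeffs = (1.0, 0.04, -0.02, 5e-4, 2e-4, -3e-4)
        bg = evaluate_background_phase(coeffs, x, y)
        truth = np.zeros_like(bg)
        truth[14:18, 14:18] = 80.0
        mask = truth == 0
        corrected, _ = correct_background_phase(truth + bg, mask, x, y)
        assert np.abs(corrected[~mask] - 80.0).max() < 1.0

    def test_rank_deficient_fit_raises(self):
        x, y = self._grid()
        v = np.zeros((32, 32))
        mask = np.zeros((32, 32), bool)
        mask[5, :] = True  # a single line: quadratic in x unidentifiable
        mask[6, :] = True
        with pytest.raises(np.linalg.LinAlgError):
            correct_background_phase(v, mask, x, y)

    def test_small_static_mask_rejected(self):
        x, y = self._grid()
        mask = np.zeros((32, 32), bool)
        mask[0, :10] = True
        with pytest.raises(ValueError):
            correct_background_phase(np.zeros((32, 32)), mask, x, y)


class TestUnwrapAliasing:
    def test_smooth_field_within_venc_unchanged(self, rng):
        xx, yy = np.meshgrid(np.linspace(-1, 1, 24), np.linspace(-1, 1, 24), indexing="ij")
        v = 100.0 * np.exp(-(xx**2 + yy**2))
        res = unwrap_aliasing(v, 150.0)
        np.testing.assert_array_equal(res.velocity, v)
        assert res.n_unresolved == 0

    def test_wrapped_parabolic_core_restored(self):
        """Tube at 200 cm/s, VENC 150: wrapped core recovered to 200 +/- 3."""
        n = 32
        xx, yy = np.meshgrid(np.arange(n) - n // 2, np.arange(n) - n // 2, indexing="ij")
        r2 = (xx**2 + yy**2) / 8.0**2
        truth = np.where(r2 <= 1.0, 200.0 * (1 - r2), 0.0)
        venc = 150.0
        wrapped = (truth + venc) % (2 * venc) - venc  # decoded representation
        res = unwrap_aliasing(wrapped, venc)
        assert res.velocity[n // 2, n // 2] == pytest.approx(200.0, abs=3.0)
        np.testing.assert_allclose(res.velocity, truth, atol=3.0)

    def test_adversarial_checkerboard_reports_unresolved(self):
        n = 16
        v = 149.0 * (-1.0) ** (np.add.outer(np.arange(n), np.arange(n)))
        res = unwrap_aliasing(v, 150.0)
        assert res.n_unresolved > 0


class TestSegmentLumen:
    def _plane(self, rng, centers=((16, 16),), radius=4.0, lumen=0.25, tissue=0.03):
        n = 32
        xx, yy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        mag = np.full((n, n), tissue)
        mag[np.hypot(xx - 16, yy - 16) > 14] = 0.0  # air ring
        truth = np.zeros((n, n), bool)
        for cx, cy in centers:
            m = np.hypot(xx - cx, yy - cy) <= radius
            mag[m] = lumen
            truth |= m
        mag += rng.normal(0, 1e-3, mag.shape)
        return np.repeat(mag[None], 3, axis=0), truth

    def test_oracle_mode_returns_labels(self, rng):
        mag, truth = self._plane(rng)
        got = segment_lumen(mag, (16, 16), labels_mask=truth)
        np.testing.assert_array_equal(got, truth)

    def test_threshold_dice_above_09_on_clean_tube(self, rng):
        mag, truth = self._plane(rng)
        got = segment_lumen(mag, (16, 16))
        dice = 2 * (got & truth).sum() / (got.sum() + truth.sum())
        assert dice > 0.9

    def test_two_vessel_plane_keeps_seeded_component_only(self, rng):
        mag, truth = self._plane(rng, centers=((10, 10), (22, 22)), radius=3.0)
        got = segment_lumen(mag, (10, 10))
        assert got[10, 10]
        assert not got[22, 22]

    def test_empty_oracle_mask_raises(self, rng):
        mag, _ = self._plane(rng)
        with pytest.raises(EmptyLumenError):
            segment_lumen(mag, (16, 16), labels_mask=np.zeros((32, 32), bool))


class TestMeanFlow:
    def test_uniform_velocity_times_area(self):
        """100 cm/s over 100 mm^2 is 100 mL/s (1 cm/s * 1 mm^2 = 0.01 mL/s)."""
        v = np.full((4, 10, 10), 100.0)
        mask = np.ones((10, 10), bool)  # 100 pixels at 1 mm^2
        m = mean_flow(v, mask, 1.0)
        assert m.mean_flow_ml_s == pytest.approx(100.0)

    def test_zero_velocity_zero_flow(self):
        m = mean_flow(np.zeros((2, 5, 5)), np.ones((5, 5), bool), 1.44)
        assert m.mean_flow_ml_s == 0.0

    def test_mean_equals_time_average_of_phases(self, rng):
        v = rng.normal(50, 10, (6, 8, 8))
        mask = rng.random((8, 8)) > 0.4
        m = mean_flow(v, mask, 1.44)
        assert m.mean_flow_ml_s == pytest.approx(m.per_phase_flow_ml_s.mean())

    def test_parabolic_tube_matches_analytic(self, small_tube_phantom):
        """Voxelised Poiseuille flow vs pi R^2 v_c / 2 within 5%."""
        ph = small_tube_phantom
        iz = ph.grid_shape[2] // 2
        mask = ph.lumen_mask("tube")[:, :, iz]
        v = np.moveaxis(ph.velocity[2, :, :, iz, :], -1, 0)
        m = mean_flow(v, mask, ph.voxel_size_mm**2)
        analytic = np.pi * 4.0**2 * 100.0 / 2.0 / 100.0  # 25.13 mL/s
        assert m.mean_flow_ml_s == pytest.approx(analytic, rel=0.05)


class TestSnrCnr:
    def _masks(self, n=40):
        lumen = np.zeros((n, n), bool); lumen[5:10, 5:10] = True
        lung = np.zeros((n, n), bool); lung[20:30, 5:15] = True
        air = np.zeros((n, n), bool); air[:, 32:] = True
        return lumen, lung, air

    def test_noiseless_volume_flags_infinite(self):
        lumen, lung, air = self._masks()
        mag = np.zeros((40, 40))
        mag[lumen] = 1.0
        mag[lung] = 0.2
        res = snr_cnr(mag, lumen, lung, air)
        assert res.infinite
        assert res.air_sd_raw == 0.0

    def test_rayleigh_correction_recovers_component_sd(self, rng):
        """|complex noise| SD in air, divided by sqrt(2 - pi/2), estimates the
        per-component sigma within 5% at >= 10^4 voxels."""
        sigma = 0.05
        n = 128  # 16384 voxels
        noise = rng.normal(0, sigma, (n, n)) + 1j * rng.normal(0, sigma, (n, n))
        mag = np.abs(noise)
        lumen = np.zeros((n, n), bool); lumen[0, 0] = True
        lung = np.zeros((n, n), bool); lung[0, 1] = True
        air = np.ones((n, n), bool); air[0, :2] = False
        res = snr_cnr(mag + 0.0, lumen, lung, air)
        assert res.noise_sd_corrected == pytest.approx(sigma, rel=0.05)

    def test_cnr_zero_when_lung_equals_lumen(self, rng):
        lumen, lung, air = self._masks()
        mag = rng.normal(0.02, 0.001, (40, 40)) ** 2 ** 0.5
        mag = np.abs(mag)
        mag[lumen] = 0.5
        mag[lung] = 0.5
        res = snr_cnr(mag, lumen, lung, air)
        assert res.cnr == pytest.approx(0.0, abs=1e-12)
        assert res.snr >= res.cnr

    def test_overlapping_masks_rejected(self):
        lumen, lung, air = self._masks()
        bad_lung = lung | lumen
        with pytest.raises(ValueError, match="disjoint"):
            snr_cnr(np.ones((40, 40)), lumen, bad_lung, air)

    def test_rayleigh_factor_value(self):
        assert RAYLEIGH_SD_FACTOR == pytest.approx(0.6551, abs=1e-4)


class TestFlowInvariances:
    """Physics invariances of the measurement chain on the 2D comparator."""

    def test_venc_invariance_when_unaliased(self):
        """Decoding the same tube at VENC 150 and 400 gives the same flow."""
        from sweepflow.experiments import measure_plane_2d, tube_phantom

        ph = tube_phantom(rr_jitter_frac=0.0, n_phases=8)
        flows = {}
        for venc in (150.0, 400.0):
            m, _ = measure_plane_2d(ph, 0.0, "tube", n_phases=4, venc=venc)
            flows[venc] = m.mean_flow_ml_s
        assert flows[150.0] == pytest.approx(flows[400.0], rel=0.01)

    def test_plane_position_invariance_along_straight_tube(self):
        """Mean flow is the same (within 3%) at any cross-sectional plane."""
        from sweepflow.experiments import measure_plane_2d, tube_phantom

        ph = tube_phantom(rr_jitter_frac=0.0, n_phases=8)
        flows = []
        for z in (-9.6, 0.0, 9.6):
            m, _ = measure_plane_2d(ph, z, "tube", n_phases=4)
            flows.append(m.mean_flow_ml_s)
        assert max(flows) <= min(flows) * 1.03
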