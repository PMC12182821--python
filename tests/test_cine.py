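"""Windowing, cardiac gating, the temporal-TV prox, and CS reconstruction."""

import numpy as np
import pytest

from sweepflow.acquire import AcquisitionConfig, simulate_sweep
from sweepflow.cine import (
    CSConfig,
    EmptyCardiacBinError,
    GatedSpiralOperator,
    assign_cardiac_phase,
    make_windows,
    reconstruct_cine,
    tv1d_cyclic_prox,
    tv1d_cyclic_value,
)
from sweepflow.phantom import PhantomConfig, TriggerTrain, sample_triggers
from sweepflow.trajectory import build_schedule


class TestWindowArithmetic:
    def test_protocol_scale_hop_and_arms_per_encoding(self):
        """996-arm windows sharing 332 arms: hop 664 TRs, 249 arms/encoding."""
        cs = CSConfig(arms_per_window=996, overlap_arms=332)
        assert cs.hop == 664
        sched = build_schedule(996 + 2 * 664, 7.5, 0.0, 0.005)
        windows = make_windows(sched, cs)
        assert len(windows) == 3
        assert windows[0].arms_per_encoding == 249
        assert windows[1].start - windows[0].start == 664

    def test_exactly_one_window(self):
        cs = CSConfig(arms_per_window=996, overlap_arms=332)
        sched = build_schedule(996, 7.5, 0.0, 0.005)
        assert len(make_windows(sched, cs)) == 1

    def test_trailing_trs_dropped(self):
        cs = CSConfig(arms_per_window=100, overlap_arms=20)
        sched = build_schedule(100 + 80 + 79, 7.5, 0.0, 0.005)
        assert len(make_windows(sched, cs)) == 2

    def test_center_z_advances_by_hop_times_shift(self):
        cs = CSConfig(arms_per_window=100, overlap_arms=40)
        sched = build_schedule(400, 7.5, 0.0, 0.02)
        w = make_windows(sched, cs)
        assert w[1].center_z_mm - w[0].center_z_mm == pytest.approx(60 * 0.02)

    def test_schedule_shorter_than_window_rejected(self):
        cs = CSConfig(arms_per_window=996, overlap_arms=332)
        with pytest.raises(ValueError):
            make_windows(build_schedule(500, 7.5, 0.0, 0.005), cs)


class TestCardiacPhase:
    def test_r_peak_maps_to_zero(self):
        t = TriggerTrain(np.array([0.0, 800.0, 1600.0]))
        assert assign_cardiac_phase(800.0, t) == 0.0

    def test_interval_midpoint_maps_to_half(self):
        t = TriggerTrain(np.array([0.0, 800.0, 1600.0]))
        assert assign_cardiac_phase(400.0, t) == pytest.approx(0.5)

    def test_matches_bruteforce_interval_search_on_jittered_train(self):
        """Vectorised searchsorted vs an explicit per-time linear scan."""
        cfg = PhantomConfig(rr_jitter_frac=0.08)
        trig = sample_triggers(cfg, 60_000.0, 2)
        rng = np.random.default_rng(0)
        times = rng.uniform(0.0, trig.r_peak_times_ms[-1], 500)
        got = assign_cardiac_phase(times, trig)
        peaks = trig.r_peak_times_ms
        for t, g in zip(times, got):
            i = 0
            while peaks[i + 1] <= t:
                i += 1
            expected = (t - peaks[i]) / (peaks[i + 1] - peaks[i])
            assert abs(g - expected) < 1e-12

    def test_time_outside_span_rejected(self):
        t = TriggerTrain(np.array([0.0, 800.0]))
        with pytest.raises(ValueError):
            assign_cardiac_phase(900.0, t)
        with pytest.raises(ValueError):
            assign_cardiac_phase(-1.0, t)


class TestTemporalTVProx:
    def test_zero_weight_is_identity(self, rng):
        v = rng.standard_normal((6, 4, 4)) + 1j * rng.standard_normal((6, 4, 4))
        np.testing.assert_array_equal(tv1d_cyclic_prox(v, 0.0), v)

    def test_two_phase_closed_form(self, rng):
        """n=2 cyclic TV is 2|x1-x2|: prox shrinks the difference toward 0."""
        a, b = 3.0 + 1j, -1.0 + 0.5j
        theta = 0.3
        v = np.array([a, b]).reshape(2, 1, 1)
        got = tv1d_cyclic_prox(v, theta, n_inner=200).ravel()
        # independent oracle: direct numerical minimisation of the prox objective
        from scipy.optimize import minimize

        def obj(z):
            x = z[:2] + 1j * z[2:]
            return 0.5 * np.sum(np.abs(x - np.array([a, b])) ** 2) + theta * 2 * abs(
                x[0] - x[1]
            )

        res = minimize(obj, np.array([a.real, b.real, a.imag, b.imag]), tol=1e-12)
        oracle = res.x[:2] + 1j * res.x[2:]
        np.testing.assert_allclose(got, oracle, atol=1e-5)

    def test_temporal_mean_preserved_and_variation_shrinks(self, rng):
        """The dual update sums to zero along the cyclic axis, so the prox
        preserves each pixel's temporal mean exactly; the total variation
        itself decreases monotonically with the weight."""
        v = rng.standard_normal((8, 3, 3)) + 1j * rng.standard_normal((8, 3, 3))
        prev_tv = tv1d_cyclic_value(v)
        for theta in (0.1, 0.5, 2.0):
            got = tv1d_cyclic_prox(v, theta, n_inner=200)
            np.testing.assert_allclose(
                got.mean(axis=0), v.mean(axis=0), atol=1e-10
            )
            tv = tv1d_cyclic_value(got)
            assert tv < prev_tv
            prev_tv = tv

    def test_prox_decreases_objective(self, rng):
        v = rng.standard_normal((8, 5, 5)) + 1j * rng.standard_normal((8, 5, 5))
        theta = 0.5
        x = tv1d_cyclic_prox(v, theta, n_inner=100)

        def F(z):
            return 0.5 * np.linalg.norm(z - v) ** 2 + theta * tv1d_cyclic_value(z)

        assert F(x) <= F(v) + 1e-10


def _single_slice_kspace(phantom, n_arms, seed=0, n_turns=0.5, encodings=(0,)):
    n_tr = 4 * n_arms
    cfg = AcquisitionConfig(
        fov_mm=phantom.grid_shape[0] * phantom.voxel_size_mm,
        in_plane_resolution_mm=phantom.voxel_size_mm,
        shift_per_tr_mm=0.0,
        duration_s=n_tr * 7.5e-3,
        noise_sd=0.0,
        z_start_mm=0.0,
        n_spiral_turns=n_turns,
        seed=seed,
    )
    triggers = sample_triggers(
        phantom.config, n_tr * 7.5 + 3 * phantom.config.cardiac_period_ms, seed + 1
    )
    return simulate_sweep(phantom, triggers, cfg, encodings=encodings)


@pytest.fixture(scope="module")
def tube_kspace(small_tube_phantom):
    # 96 arms/encoding at a 24-grid: 2x the azimuthal Nyquist (24 arms at
    # 0.5 turns) even after 4-way binning -> fully sampled per bin
    return _single_slice_kspace(small_tube_phantom, 96)


class TestReconstructCine:
    def test_unregularized_dense_recon_matches_phantom(self, small_tube_phantom, tube_kspace):
        """lambda=0, fully sampled: the solver reaches the true image, up to
        the k-space corners the circular spiral coverage never samples (the
        reference is low-passed to the sampled |k| <= k_max disc)."""
        cs = CSConfig(
            arms_per_window=len(tube_kspace.schedule), overlap_arms=0,
            n_cardiac_phases=4, ttv_weight=0.0, n_iterations=30,
        )
        window = make_windows(tube_kspace.schedule, cs)[0]
        result = reconstruct_cine(tube_kspace, window, cs, encodings=(0,))
        img = result.images[0, 0]
        from sweepflow.acquire import slice_profile_weights, _encoded_volume

        ph = small_tube_phantom
        w = slice_profile_weights(ph.axis_coords(2), 0.0, tube_kspace.config.slice_thickness_mm)
        expected = np.tensordot(
            _encoded_volume(ph, 0, 0, tube_kspace.config), w, axes=([2], [0])
        )
        # the solution is data-consistent ...
        op = GatedSpiralOperator(tube_kspace, window, 0, 4)
        resid = np.concatenate(
            [op.ops[b].forward(result.images[0, b]) - op.data[b] for b in range(4)]
        )
        assert np.linalg.norm(resid) / np.linalg.norm(np.concatenate(op.data)) < 0.01
        # ... and matches the truth up to content in the unsampled k-space
        # corners (|k| > k_max), which a circular spiral cannot constrain
        nrmse = np.linalg.norm(np.abs(img) - np.abs(expected)) / np.linalg.norm(
            np.abs(expected)
        )
        assert nrmse < 0.1

    def test_static_object_gives_equal_phases_under_any_weight(self, tube_kspace):
        """Steady tube: the TTV cost is zero at the truth, all bins agree."""
        cs = CSConfig(
            arms_per_window=len(tube_kspace.schedule), overlap_arms=0,
            n_cardiac_phases=4, ttv_weight=0.08, n_iterations=30,
        )
        window = make_windows(tube_kspace.schedule, cs)[0]
        img = reconstruct_cine(tube_kspace, window, cs, encodings=(0,)).images[0]
        ref = np.abs(img[0])
        for b in range(1, img.shape[0]):
            assert np.abs(np.abs(img[b]) - ref).max() <= 0.01 * ref.max()

    def test_objective_non_increasing(self, tube_kspace):
        cs = CSConfig(
            arms_per_window=len(tube_kspace.schedule), overlap_arms=0,
            n_cardiac_phases=4, ttv_weight=0.08, n_iterations=20,
        )
        window = make_windows(tube_kspace.schedule, cs)[0]
        obj = reconstruct_cine(tube_kspace, window, cs, encodings=(0,)).objective[0]
        assert np.all(np.diff(obj) <= 1e-9 * obj[0])

    def test_reconstruction_is_pure(self, tube_kspace):
        """Same window reconstructed twice gives identical images."""
        cs = CSConfig(
            arms_per_window=len(tube_kspace.schedule), overlap_arms=0,
            n_cardiac_phases=4, ttv_weight=0.08, n_iterations=5,
        )
        window = make_windows(tube_kspace.schedule, cs)[0]
        a = reconstruct_cine(tube_kspace, window, cs, encodings=(0,))
        b = reconstruct_cine(tube_kspace, window, cs, encodings=(0,))
        np.testing.assert_array_equal(a.images, b.images)

    def test_flow_phase_reproduced_when_densely_sampled(self):
        """Noiseless dense sampling: CINE phase difference reproduces the
        velocity-encoding phase within 0.05 rad.

        Uses a smooth (band-limited) flow blob: a hard-edged lumen carries
        k-space-corner content the circular trajectory never samples, which
        would contaminate the comparison with inverse-crime truncation
        ringing rather than reconstruction error.
        """
        from sweepflow.phantom import FlowPhantom

        n, nz, n_phases = 24, 12, 4
        x = np.arange(n) - n // 2
        xx, yy = np.meshgrid(x, x, indexing="ij")
        blob2d = np.exp(-(xx**2 + yy**2) / (2 * 2.0**2))
        blob = np.repeat(blob2d[..., None], nz, axis=2)
        ph = FlowPhantom(
            magnitude=np.repeat(blob[..., None], n_phases, axis=3),
            velocity=np.zeros((3, n, n, nz, n_phases)),
            labels=np.ones((n, n, nz), dtype=np.int16),
            voxel_size_mm=1.0,
            phases=np.arange(n_phases) / n_phases,
            config=PhantomConfig(grid_shape=(n, n, nz), voxel_size_mm=1.0,
                                 rr_jitter_frac=0.0),
        )
        # smooth through-plane velocity, peak 100 cm/s, same blob shape
        ph.velocity[2] = 100.0 * blob[..., None] * np.ones(4)
        ks = _single_slice_kspace(ph, 96, encodings=(0, 1))
        cs = CSConfig(
            arms_per_window=len(ks.schedule), overlap_arms=0,
            n_cardiac_phases=4, ttv_weight=0.08, n_iterations=30,
        )
        window = make_windows(ks.schedule, cs)[0]
        imgs = reconstruct_cine(ks, window, cs, encodings=(0, 1)).images
        iz = ph.grid_shape[2] // 2
        mask = blob[:, :, iz] > 0.2
        dphi = np.angle(imgs[1, 0] * np.conj(imgs[0, 0]))
        expected = np.pi * ph.velocity[2, :, :, iz, 0] / ks.config.venc_cm_s
        bg = ph.background_phase_map()
        assert np.abs(dphi[mask] - expected[mask] - bg[mask]).max() < 0.05

    def test_empty_cardiac_bin_raises_with_location(self, small_tube_phantom):
        ks = _single_slice_kspace(small_tube_phantom, 16)
        cs = CSConfig(
            arms_per_window=len(ks.schedule), overlap_arms=0,
            n_cardiac_phases=50, ttv_weight=0.08, n_iterations=2,
        )
        window = make_windows(ks.schedule, cs)[0]
        with pytest.raises(EmptyCardiacBinError, match="bin"):
            reconstruct_cine(ks, window, cs, encodings=(0,))
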