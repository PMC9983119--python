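"""Phantom geometry, truth maps and forward simulators."""

import numpy as np
import pytest

import ctiphantom as cp
from ctiphantom.phantom import (DEFAULT_B_VALUES, GeometryError, ConfigError,
                                bench_concentration_true, compartment_signal)


def fine_grid_disk_area_px(center, diameter, fov, grid_size, oversample=16):
    """Independent oracle: disk area in coarse-pixel units by rasterizing
    pixel centres on an ``oversample``-times finer grid."""
    n = grid_size * oversample
    px = fov / n
    coords = (np.arange(n) + 0.5) * px - fov / 2.0
    x, y = np.meshgrid(coords, coords, indexing="xy")
    inside = (x - center[0]) ** 2 + (y - center[1]) ** 2 < (diameter / 2) ** 2
    return inside.sum() / oversample**2


class TestRasterize:
    def test_chamber_areas_match_analytic_and_fine_grid(self, default_layout):
        _, _, masks = cp.rasterize_layout(default_layout)
        px_area = default_layout.pixel_size ** 2
        analytic_px = np.pi * 4.5**2 / px_area          # ~289.5 px
        for c in default_layout.chambers:
            n = masks[c.chamber_id].sum()
            assert abs(n - analytic_px) / analytic_px < 0.05
            fine = fine_grid_disk_area_px(c.center_xy, c.diameter,
                                          default_layout.fov,
                                          default_layout.grid_size)
            assert abs(n - fine) / fine < 0.05

    def test_zero_chambers_gives_body_only(self):
        layout = cp.PhantomLayout(chambers=())
        label, body, masks = cp.rasterize_layout(layout)
        assert masks == {}
        assert body.any()
        assert set(np.unique(label)) == {-1, 0}

    def test_chamber_at_body_edge_rejected(self):
        c = cp.ChamberSpec("bad", (20.0, 0.0), 9.0, 0.5, 2.0, 0.5, 2.0)
        with pytest.raises(GeometryError):
            cp.PhantomLayout(chambers=(c,))

    def test_overlapping_chambers_rejected(self):
        a = cp.ChamberSpec("a", (0.0, 0.0), 9.0, 0.5, 2.0, 0.5, 2.0)
        b = cp.ChamberSpec("b", (5.0, 0.0), 9.0, 0.5, 2.0, 0.5, 2.0)
        with pytest.raises(GeometryError):
            cp.PhantomLayout(chambers=(a, b))

    def test_masks_disjoint_and_inside_body(self, default_layout):
        _, body, masks = cp.rasterize_layout(default_layout)
        total = np.zeros_like(body, dtype=int)
        for m in masks.values():
            total += m
            assert not (m & ~body).any()
        assert total.max() == 1


class TestTruthMaps:
    def test_designed_alpha_values(self, default_truth, designed_alpha):
        for cid, a in designed_alpha.items():
            m = default_truth.chamber_masks[cid]
            assert np.allclose(default_truth.alpha[m], a)

    def test_sigma_h_near_two_everywhere(self, default_truth):
        m = default_truth.signal_mask
        assert np.all(np.abs(default_truth.sigma_h[m] - 2.0) <= 0.02 + 1e-12)

    def test_background_invalid(self, default_truth):
        assert np.all(np.isnan(default_truth.alpha[~default_truth.signal_mask]))


class TestSimulateDwi:
    def test_electrolyte_log_signal_linear_in_b(self, noiseless_dwi, default_truth):
        m = default_truth.chamber_masks["electrolyte"]
        i, j = np.argwhere(m)[0]
        s = noiseless_dwi.signal[:, i, j]
        slope = np.polyfit(noiseless_dwi.b_values, np.log(s), 1)[0]
        assert slope == pytest.approx(-2.82e-3, rel=1e-6)

    def test_b0_equals_s0(self, noiseless_dwi, default_truth):
        assert np.allclose(noiseless_dwi.signal[0][default_truth.signal_mask], 1.0)

    def test_biexponential_point_value(self):
        # 0.4 e^-2.39 + 0.6 e^-0.69, frozen from direct evaluation
        s = compartment_signal(1000.0, 0.4, 2.39, 0.69)
        assert s == pytest.approx(0.337595, abs=5e-6)

    def test_same_seed_bit_identical_different_seed_not(self, default_truth):
        acq1 = cp.AcquisitionConfig(rng_seed=5)
        acq2 = cp.AcquisitionConfig(rng_seed=6)
        a = cp.simulate_dwi(default_truth, acq1)
        b = cp.simulate_dwi(default_truth, acq1)
        c = cp.simulate_dwi(default_truth, acq2)
        assert np.array_equal(a.signal, b.signal)
        assert not np.array_equal(a.signal, c.signal)

    def test_rician_b0_bias_below_one_percent(self, default_truth):
        acq = cp.AcquisitionConfig(snr=20, rng_seed=3)
        dwi = cp.simulate_dwi(default_truth, acq)
        mean_b0 = dwi.signal[0][default_truth.signal_mask].mean()
        assert abs(mean_b0 - 1.0) < 0.01

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            cp.AcquisitionConfig(snr=-1)
        with pytest.raises(ConfigError):
            cp.AcquisitionConfig(b_values=(0, 500, 100))
        with pytest.raises(ConfigError):
            cp.AcquisitionConfig(b_values=(100, 500))


class TestSimulatePhase:
    def test_zero_conductivity_zero_phase(self, default_layout):
        truth = cp.make_truth_maps(default_layout)
        truth.sigma_h = np.where(truth.body_mask, 0.0, np.nan)
        acq = cp.AcquisitionConfig(noise_model="none")
        ph = cp.simulate_transceive_phase(truth, acq, noiseless=True)
        assert np.allclose(ph.phase, 0.0)

    @pytest.mark.parametrize("sigma_map", ["uniform", "two_valued"])
    def test_discrete_laplacian_round_trip(self, default_layout, sigma_map):
        """The 5-point Laplacian of the solved phase must reproduce the
        Poisson right-hand side away from interfaces (round-trip oracle)."""
        from ctiphantom.phantom import MU0
        truth = cp.make_truth_maps(default_layout)
        if sigma_map == "uniform":
            sigma = np.where(truth.body_mask, 2.0, 0.0)
        else:
            x, y = default_layout.pixel_centers()
            sigma = np.where(truth.body_mask, np.where(x < 0, 1.0, 2.0), 0.0)
        truth.sigma_h = np.where(truth.body_mask, sigma, np.nan)
        acq = cp.AcquisitionConfig(noise_model="none")
        ph = cp.simulate_transceive_phase(truth, acq, noiseless=True)
        h = default_layout.pixel_size * 1e-3
        lap = (np.roll(ph.phase, 1, 0) + np.roll(ph.phase, -1, 0)
               + np.roll(ph.phase, 1, 1) + np.roll(ph.phase, -1, 1)
               - 4 * ph.phase) / h**2
        interior = truth.body_mask.copy()
        for ax, sh in ((0, 1), (0, -1), (1, 1), (1, -1)):
            interior &= np.roll(truth.body_mask, sh, ax)
        if sigma_map == "two_valued":
            x, _ = default_layout.pixel_centers()
            interior &= np.abs(x) > 2 * default_layout.pixel_size
        omega = 2 * np.pi * 400e6
        expected = 2 * MU0 * omega * sigma
        assert np.allclose(lap[interior], expected[interior],
                           rtol=1e-6, atol=1e-6 * expected.max())

    def test_empty_body_raises(self, default_layout):
        truth = cp.make_truth_maps(default_layout)
        truth.body_mask = np.zeros_like(truth.body_mask)
        with pytest.raises(GeometryError):
            cp.simulate_transceive_phase(truth, cp.AcquisitionConfig())


class TestSimulateMems:
    def test_single_echo_phase_identity(self, default_truth):
        acq = cp.AcquisitionConfig(n_echoes=1, noise_model="none")
        ph = cp.simulate_transceive_phase(default_truth, acq, noiseless=True)
        mems = cp.simulate_mems(default_truth, ph, acq)
        m = default_truth.signal_mask
        assert np.allclose(np.angle(mems.echoes[0])[m], ph.phase[m])

    def test_echo_decay_ratio(self, default_truth):
        acq = cp.AcquisitionConfig(noise_model="none")
        ph = cp.simulate_transceive_phase(default_truth, acq, noiseless=True)
        mems = cp.simulate_mems(default_truth, ph, acq)
        m = default_truth.signal_mask
        ratio = np.abs(mems.echoes[5])[m] / np.abs(mems.echoes[0])[m]
        # T2 = 40 ms, TE1 = 15, TE6 = 90: e^(-75/40), frozen closed form
        assert np.allclose(ratio, 0.153355, atol=1e-6)

    def test_combined_phase_round_trip(self, default_truth):
        acq = cp.AcquisitionConfig(noise_model="none")
        ph = cp.simulate_transceive_phase(default_truth, acq, noiseless=True)
        mems = cp.simulate_mems(default_truth, ph, acq)
        rec = cp.combine_echo_phase(mems)
        m = default_truth.signal_mask
        assert np.allclose(rec.phase[m], ph.phase[m], atol=1e-12)


class TestBenchSamples:
    def test_concentration_dilution_arithmetic(self):
        assert bench_concentration_true(1.0) == pytest.approx(0.1 / 1.2)
        assert bench_concentration_true(0.586) == pytest.approx(0.1 / 0.786)
        assert round(bench_concentration_true(0.586), 3) == 0.127
        assert bench_concentration_true(0.0) == pytest.approx(0.5)

    def test_samples_and_standards(self, default_layout):
        samples, standards = cp.simulate_bench_samples(default_layout)
        assert [s.sample_id for s in samples] == \
            [c.chamber_id for c in default_layout.chambers]
        assert len(standards) == 6
        molarities = [m for m, _ in standards]
        assert molarities[0] == 0.0 and molarities[-1] == 0.5

    def test_zero_slope_rejected(self, default_layout):
        with pytest.raises(ConfigError):
            cp.simulate_bench_samples(default_layout, calib_slope=0.0)


class TestRoundTrips:
    @pytest.mark.parametrize("alpha", [0.05, 0.2, 0.5, 0.8, 0.95])
    def test_noiseless_dwi_fit_recovers_parameters(self, alpha):
        b = np.array(DEFAULT_B_VALUES, float)
        s = compartment_signal(b, alpha, 2.4, 0.7)
        a, de, di, s0, rss, flag = cp.fit_voxel(s, b)
        assert a == pytest.approx(alpha, abs=1e-3)
        assert de == pytest.approx(2.4, abs=1e-3)
        assert di == pytest.approx(0.7, abs=1e-3)

    def test_noiseless_phase_recon_recovers_uniform_sigma(self, default_layout):
        truth = cp.make_truth_maps(default_layout)
        truth.sigma_h = np.where(truth.body_mask, 2.0, np.nan)
        acq = cp.AcquisitionConfig(noise_model="none")
        ph = cp.simulate_transceive_phase(truth, acq, noiseless=True)
        cm = cp.laplacian_sigma(ph, kernel_radius=2,
                                pixel_size=default_layout.pixel_size)
        mean = np.nanmean(cm.sigma[cm.mask])
        assert abs(mean - 2.0) / 2.0 < 0.02
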