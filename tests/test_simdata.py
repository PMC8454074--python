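"""Forward transport model and synthetic image generator."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bbbarray import ConfigurationError, simdata
from bbbarray.simdata import (
    Condition,
    OrganoidGeometry,
    SimulationConfig,
    TransportParams,
    forward_core_intensity,
    render_brightfield_array,
    render_confocal_stack,
)

SHUTTLE = TransportParams(baseline=10.0, alpha=1.0, k_rate=0.05)


class TestForwardModel:
    def test_shuttle_starts_at_baseline(self):
        assert forward_core_intensity(0.0, 100.0, SHUTTLE, "shuttle") == pytest.approx(10.0)

    def test_shuttle_plateau(self):
        # limit of the association model: baseline + alpha * dose
        assert forward_core_intensity(1e9, 100.0, SHUTTLE, "shuttle") == pytest.approx(110.0)

    def test_shuttle_closed_form_value(self):
        # independent evaluation: 10 + 100 * (1 - e^-1) at k*t = 1
        expected = 10.0 + 100.0 * (1.0 - math.exp(-1.0))
        got = forward_core_intensity(20.0, 100.0, SHUTTLE, "shuttle")
        assert got == pytest.approx(expected)
        assert got == pytest.approx(73.21205588285577)

    def test_excluded_constant_in_time_and_dose(self):
        params = TransportParams(baseline=10.0, rim_amplitude=30.0)
        times = np.array([0.0, 15.0, 360.0])
        out = forward_core_intensity(times, 100.0, params, "excluded")
        assert np.allclose(out, 10.0)

    def test_paracellular_adds_leak(self):
        params = TransportParams(baseline=10.0, leak_amplitude=60.0)
        assert forward_core_intensity(240.0, 0.0, params, "paracellular") == pytest.approx(70.0)

    @pytest.mark.parametrize("t,dose", [(-1.0, 10.0), (10.0, -1.0)])
    def test_negative_inputs_rejected(self, t, dose):
        with pytest.raises(ValueError):
            forward_core_intensity(t, dose, SHUTTLE, "shuttle")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        t1=st.floats(0, 500),
        dt=st.floats(0, 500),
        d1=st.floats(0, 300),
        dd=st.floats(0, 300),
    )
    def test_nondecreasing_in_time_and_dose(self, t1, dt, d1, dd):
        lo = forward_core_intensity(t1, d1, SHUTTLE, "shuttle")
        hi_t = forward_core_intensity(t1 + dt, d1, SHUTTLE, "shuttle")
        hi_d = forward_core_intensity(t1, d1 + dd, SHUTTLE, "shuttle")
        assert hi_t >= lo - 1e-9
        assert hi_d >= lo - 1e-9

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            TransportParams(baseline=-1.0)
        with pytest.raises(ConfigurationError):
            TransportParams(alpha=1.0, k_rate=0.0)
        with pytest.raises(ConfigurationError):
            OrganoidGeometry(flattening=0.0)


class TestBrightfieldArray:
    def test_full_occupancy_counts(self):
        cfg = SimulationConfig(n_rows=4, n_cols=4, occupancy=1.0)
        _, truth = render_brightfield_array(cfg, seed=1)
        assert len(truth) == 16

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_rows=2, n_cols=2)
        img1, t1 = render_brightfield_array(cfg, seed=5)
        img2, t2 = render_brightfield_array(cfg, seed=5)
        assert np.array_equal(img1, img2)
        assert t1.equals(t2)

    def test_rendered_disk_diameter_matches_truth(self):
        # measure the rendered binary mask directly (independent of the
        # arraymorph segmentation recipe)
        cfg = SimulationConfig(
            n_rows=1, n_cols=1, occupancy=1.0, diameter_mean_um=235.0, diameter_sd_um=1e-9
        )
        img, truth = render_brightfield_array(cfg, seed=2, noise=False)
        bg = np.median(img)
        mask = img < 0.75 * bg  # disks are rendered at half background depth
        diam = 2.0 * np.sqrt(mask.sum() / np.pi) * cfg.pixel_size_um
        assert diam == pytest.approx(truth.true_diameter_um.iloc[0], abs=2.0 * cfg.pixel_size_um)

    def test_pitch_smaller_than_organoid_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(well_pitch_um=200.0)


class TestConfocalStack:
    def test_seed_determinism(self, shuttle_params, shuttle_condition):
        cfg = SimulationConfig()
        geo = cfg.geometry(235.0)
        s1, _ = render_confocal_stack(geo, shuttle_params, shuttle_condition, cfg, seed=42)
        s2, _ = render_confocal_stack(geo, shuttle_params, shuttle_condition, cfg, seed=42)
        assert np.array_equal(s1.data, s2.data)

    def test_non_treated_core_near_background(self, noise_free_config):
        """Without any injected signal the core window stays at the
        autofluorescence baseline (within 2 noise SD when noise is on)."""
        cfg = replace(noise_free_config, poisson_gain=1.0, read_noise_sd=1.5)
        params = simdata.default_transport_params("non_treated")
        cond = Condition("non_treated", "excluded")
        stack, truth = render_confocal_stack(cfg.geometry(235.0), params, cond, cfg, seed=3)
        from bbbarray.corequant import measure_stack

        m = measure_stack(stack)
        noise_sd = np.sqrt(cfg.poisson_gain * truth["true_core_mean"] + cfg.read_noise_sd**2)
        # MIP of noisy slices is upward-biased by design; stay within 2 SD
        assert abs(m.core_mean - truth["true_core_mean"]) < 2.0 * noise_sd

    def test_time_monotonicity_of_noise_free_core(self, noise_free_config, shuttle_params):
        geo = noise_free_config.geometry(235.0)
        levels = {}
        for t in (15.0, 360.0):
            cond = Condition("human_shuttle", "shuttle", dose_nM=100.0, time_min=t)
            _, truth = render_confocal_stack(geo, shuttle_params, cond, noise_free_config, seed=9)
            levels[t] = truth["true_core_mean"]
        assert levels[360.0] > levels[15.0]

    def test_condition_fidelity_dextran_core_is_baseline(self, noise_free_config):
        params = simdata.default_transport_params("dextran")
        cond = Condition("dextran_70kDa", "excluded")
        _, truth = render_confocal_stack(
            noise_free_config.geometry(235.0), params, cond, noise_free_config, seed=4
        )
        assert truth["true_core_mean"] == pytest.approx(params.baseline)

    def test_truth_matches_noise_free_voxel_mean(self, noise_free_shuttle_stack, noise_free_config):
        """Truth contract: the recorded core level equals the noise-free
        voxel mean of the analytic interior (eroded by the blur scale) to
        within rendering discretization (2%)."""
        stack, truth = noise_free_shuttle_stack
        cfg = noise_free_config
        R = 235.0 / 2.0
        c = R * cfg.flattening
        tau = cfg.shell_thickness_um / R
        erode = 3.0 * cfg.blur_sigma_um
        nz, ny, nx = cfg.stack_shape
        z = (np.arange(nz) + 0.5) * cfg.z_step_um
        y = (np.arange(ny) - (ny - 1) / 2.0) * cfg.voxel_xy_um
        x = (np.arange(nx) - (nx - 1) / 2.0) * cfg.voxel_xy_um
        zc = cfg.bottom_margin_um + c
        Ri, ci = R * (1 - tau) - erode, c * (1 - tau) - erode
        m2 = ((y[:, None] ** 2 + x[None, :] ** 2) / Ri**2)[None] + (((z - zc) / ci) ** 2)[
            :, None, None
        ]
        interior = m2 <= 1.0
        vox_mean = float(stack.channel("tracer")[interior].mean())
        assert vox_mean == pytest.approx(truth["true_core_mean"], rel=0.02)

    def test_no_bec_removes_endothelial_channel(self, noise_free_config):
        params = simdata.default_transport_params("no_bec")
        cond = Condition("no_bec", "paracellular", no_bec=True)
        stack, _ = render_confocal_stack(
            noise_free_config.geometry(235.0), params, cond, noise_free_config, seed=6
        )
        assert stack.channel("endothelial").max() == 0.0
        assert stack.channel("nuclei").max() > 0.0

    def test_insufficient_depth_rejected(self, shuttle_params, shuttle_condition):
        cfg = SimulationConfig(stack_shape=(20, 224, 224))  # 20 µm < 29.5 µm needed
        with pytest.raises(ConfigurationError):
            render_confocal_stack(
                cfg.geometry(235.0), shuttle_params, shuttle_condition, cfg, seed=1
            )


class TestMeasurementLevelSimulator:
    def test_values_follow_forward_model(self):
        params = TransportParams(baseline=10.0, alpha=1.0, k_rate=0.05)
        df = simdata.simulate_core_measurements(
            params, "shuttle", [15, 360], 100.0, 2000, noise_cv=0.1, rng=np.random.default_rng(0)
        )
        for t, grp in df.groupby("time_min"):
            expected = forward_core_intensity(t, 100.0, params, "shuttle")
            assert grp.core_mean.mean() == pytest.approx(expected, rel=0.02)
            assert grp.core_mean.std() / expected == pytest.approx(0.1, rel=0.15)
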