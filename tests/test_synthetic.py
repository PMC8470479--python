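"""Generators: determinism, conservation of injected truth, analytic references."""

import numpy as np
import pytest

from gliakit.synthetic import (
    CellSimConfig,
    ChannelSimConfig,
    FieldSimConfig,
    TraceSimConfig,
    expected_derivative_peak_times,
    match_event_times,
    simulate_arbor,
    simulate_cell_mask,
    simulate_if_field,
    simulate_trace_set,
    transient_kernel,
)


class TestTraceSimulator:
    def test_no_event_config_gives_constant_traces(self):
        cfg = TraceSimConfig(
            n_rois=5, event_rate_per_100s=0, noise_sd=0, responder_fraction=0, seed=0
        )
        traces, truth = simulate_trace_set(cfg)
        np.testing.assert_allclose(
            traces.F, np.broadcast_to(truth.f0[:, None], traces.F.shape)
        )

    def test_same_seed_is_bit_identical(self):
        a, _ = simulate_trace_set(TraceSimConfig(n_rois=50, seed=1))
        b, _ = simulate_trace_set(TraceSimConfig(n_rois=50, seed=1))
        assert np.array_equal(a.F, b.F)

    def test_different_seed_differs(self):
        a, _ = simulate_trace_set(TraceSimConfig(n_rois=5, seed=1))
        b, _ = simulate_trace_set(TraceSimConfig(n_rois=5, seed=2))
        assert not np.array_equal(a.F, b.F)

    def test_poisson_event_count_mean(self):
        cfg = TraceSimConfig(
            n_rois=200, duration_s=300.0, event_rate_per_100s=2.0,
            stimulus_time_s=None, seed=3,
        )
        _, truth = simulate_trace_set(cfg)
        counts = truth.event_count()
        se = np.sqrt(6.0 / 200)  # Poisson mean 6 per ROI
        assert abs(counts.mean() - 6.0) <= 3 * se

    def test_loading_efficiency_is_multiplicative(self):
        # scaling the baseline changes F but not the injected ΔF/F₀ truth
        a, ta = simulate_trace_set(TraceSimConfig(n_rois=10, seed=4, baseline_mean=50))
        b, tb = simulate_trace_set(TraceSimConfig(n_rois=10, seed=4, baseline_mean=500))
        for x, y in zip(ta.event_amps, tb.event_amps):
            np.testing.assert_array_equal(x, y)
        np.testing.assert_allclose(b.F / tb.f0[:, None], a.F / ta.f0[:, None], rtol=1e-12)

    def test_responder_count_is_exact(self):
        _, truth = simulate_trace_set(
            TraceSimConfig(n_rois=50, responder_fraction=0.8, seed=5)
        )
        assert truth.responder.sum() == 40

    def test_event_times_inside_recording(self):
        _, truth = simulate_trace_set(TraceSimConfig(n_rois=30, seed=6))
        for t in truth.event_times:
            assert np.all((t >= 0) & (t <= 350.0))

    @pytest.mark.parametrize(
        "bad",
        [
            {"duration_s": -1.0},
            {"n_rois": 0},
            {"responder_fraction": 1.5},
            {"stimulus_time_s": 400.0},
            {"noise_sd": -0.1},
        ],
    )
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            simulate_trace_set(TraceSimConfig(**bad))

    def test_kernel_peak_normalized(self):
        t = np.linspace(0, 100, 10001)
        k = transient_kernel(t, 1.5, 8.0)
        assert k.max() == pytest.approx(1.0, abs=1e-6)
        assert transient_kernel(np.array([-1.0]), 1.5, 8.0)[0] == 0.0

    def test_expected_derivative_peak_lags_onset_by_samples(self):
        lags = expected_derivative_peak_times(np.array([100.0, 100.5]), 1.5, 8.0) - [100.0, 100.5]
        assert np.all(lags >= 0.5) and np.all(lags <= 3.0)


class TestEventMatching:
    def test_exact_match(self):
        m, d, t = match_event_times([10.0, 20.0], [10.5, 19.0], tol_s=2.0)
        assert (m, d, t) == (2, 2, 2)

    def test_one_to_one(self):
        # two detections near one true event: only one can match
        m, d, t = match_event_times([10.0, 10.5], [10.2], tol_s=2.0)
        assert (m, d, t) == (1, 2, 1)

    def test_outside_tolerance(self):
        m, _, _ = match_event_times([10.0], [14.0], tol_s=2.0)
        assert m == 0


class TestCellSimulator:
    def test_amoeboid_reference_is_a_disk(self):
        cfg = CellSimConfig(morphology_class="amoeboid", soma_radius_um=10, n_processes=0)
        _, ref = simulate_cell_mask(cfg)
        assert ref.solidity == pytest.approx(1.0, abs=1e-6)
        assert ref.area_um2 == pytest.approx(np.pi * 100, rel=0.01)
        assert ref.elliptical_form_factor == pytest.approx(1.0, abs=0.01)

    def test_ramified_mask_area_matches_geometry(self):
        cfg = CellSimConfig(n_processes=6, seed=7)
        cell, ref = simulate_cell_mask(cfg)
        pixel_area = cell.mask.sum() * cfg.pixel_size_um**2
        assert pixel_area == pytest.approx(ref.area_um2, rel=0.10)

    def test_same_seed_identical_mask(self):
        a, _ = simulate_cell_mask(CellSimConfig(seed=3))
        b, _ = simulate_cell_mask(CellSimConfig(seed=3))
        assert np.array_equal(a.mask, b.mask)

    def test_mask_is_single_component_off_border(self):
        cell, _ = simulate_cell_mask(CellSimConfig(seed=11))
        assert cell.n_components() == 1
        border = np.concatenate(
            [cell.mask[0], cell.mask[-1], cell.mask[:, 0], cell.mask[:, -1]]
        )
        assert not border.any()

    def test_amoeboid_with_processes_rejected(self):
        with pytest.raises(ValueError, match="n_processes"):
            CellSimConfig(morphology_class="amoeboid", n_processes=3).validate()


class TestArborSimulator:
    def test_reference_profile_doubles_at_branch_radius(self):
        _, ref = simulate_arbor(4, 20.0, 40.0, step_um=1.0, seed=0)
        assert np.all(ref.intersections[ref.radii_um <= 20.0] == 4)
        assert np.all(ref.intersections[ref.radii_um > 20.0] == 8)
        assert ref.max_intersection_number == 8

    def test_branch_beyond_max_rejected(self):
        with pytest.raises(ValueError):
            simulate_arbor(1, 40.0, 40.0)

    def test_sum_identity(self):
        _, ref = simulate_arbor(3, 15.0, 35.0, step_um=2.0, seed=1)
        assert ref.sum_of_intersections == int(ref.intersections.sum())

    def test_zero_primaries_gives_empty_profile(self):
        cell, ref = simulate_arbor(0, 20.0, 40.0)
        assert not cell.mask.any()
        assert ref.sum_of_intersections == 0

    def test_same_seed_identical(self):
        a, _ = simulate_arbor(5, 18.0, 38.0, seed=2)
        b, _ = simulate_arbor(5, 18.0, 38.0, seed=2)
        assert np.array_equal(a.mask, b.mask)


class TestFieldSimulator:
    def test_zero_stain_fraction(self):
        cfg = FieldSimConfig(
            channels={"m": ChannelSimConfig(stain_fraction=0.0)}, seed=0
        )
        _, truth = simulate_if_field(cfg)
        assert truth.stained_pixels["m"] == 0
        assert np.isnan(truth.stained_mean_intensity["m"])

    def test_noiseless_intensity_exact(self):
        cfg = FieldSimConfig(
            channels={"m": ChannelSimConfig(intensity_sd=0.0, background_mean=0.0)},
            seed=1,
        )
        field, truth = simulate_if_field(cfg)
        assert truth.stained_mean_intensity["m"] == 100.0
        stained = field["m"] > 0
        assert field["m"][stained].mean() == 100.0

    def test_stained_area_tracks_fraction(self):
        cfg = FieldSimConfig(
            channels={"m": ChannelSimConfig(n_cells=20, stain_fraction=0.5)}, seed=2
        )
        _, truth = simulate_if_field(cfg)
        assert truth.stained_pixels["m"] == pytest.approx(
            0.5 * truth.cell_area_pixels["m"], rel=0.10
        )

    def test_determinism(self):
        cfg = FieldSimConfig(seed=5)
        a, _ = simulate_if_field(cfg)
        b, _ = simulate_if_field(cfg)
        assert np.array_equal(a["marker_A"], b["marker_A"])

    def test_invalid_channel_config_rejected(self):
        with pytest.raises(ValueError):
            ChannelSimConfig(background_mean=200.0, intensity_mean=100.0).validate()
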