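"""Trace analysis: normalization, peak calling, responders, evoked metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gliakit.protocols import final_bath_concentration
from gliakit.synthetic import TraceSimConfig, simulate_trace_set, transient_kernel
from gliakit.traces import (
    NormalizedTraceSet,
    classify_evoked_responders,
    detect_spontaneous_peaks,
    evoked_response_metrics,
    local_maxima_1d,
    metrics_frame,
    normalize_dff,
    responder_proportion,
    roi_spontaneous_metrics,
)


# ---------------------------------------------------------------------------
# normalization

class TestNormalize:
    def test_constant_trace_gives_zero_dff_and_derivative(self, make_traceset):
        ts = make_traceset(np.full((3, 50), 7.0))
        norm = normalize_dff(ts)
        assert np.all(norm.dff == 0)
        assert np.all(norm.ddff == 0)
        assert np.allclose(norm.f0, 7.0)

    def test_step_trace_arithmetic(self, make_traceset):
        ts = make_traceset([[1.0, 1.0, 1.0, 2.0]])
        norm = normalize_dff(ts, baseline_window=(0, 3))
        assert np.allclose(norm.dff, [[0.0, 0.0, 0.0, 1.0]])

    def test_scale_invariance(self, make_traceset):
        rng = np.random.default_rng(0)
        F = 50 + rng.random((4, 80)) * 10
        a = normalize_dff(make_traceset(F))
        b = normalize_dff(make_traceset(2.0 * F))
        np.testing.assert_allclose(a.dff, b.dff, rtol=1e-12)

    def test_baseline_mean_of_dff_is_zero(self, make_traceset):
        rng = np.random.default_rng(1)
        F = 100 + rng.random((5, 60))
        norm = normalize_dff(make_traceset(F))
        assert np.allclose(norm.dff.mean(axis=1), 0.0, atol=1e-12)

    def test_nonpositive_baseline_roi_excluded(self, make_traceset, caplog):
        F = np.ones((2, 40))
        F[1] = 0.0
        with caplog.at_level("WARNING"):
            norm = normalize_dff(make_traceset(F))
        assert list(norm.roi_ids) == [0]
        assert list(norm.excluded_roi_ids) == [1]
        assert "non-positive baseline" in caplog.text

    def test_too_short_baseline_rejected(self, make_traceset):
        ts = make_traceset(np.ones((1, 40)))
        with pytest.raises(ValueError, match="fewer than 2"):
            normalize_dff(ts, baseline_window=(0, 1))


# ---------------------------------------------------------------------------
# local maxima and peak detection

def brute_force_maxima(y):
    """Definitional enumeration: strictly above both sides, plateau -> first."""
    out = []
    for i in range(1, len(y) - 1):
        left = next((y[j] for j in range(i - 1, -1, -1) if y[j] != y[i]), None)
        right = next((y[j] for j in range(i + 1, len(y)) if y[j] != y[i]), None)
        if left is None or right is None:
            continue
        if left < y[i] and right < y[i] and y[i - 1] != y[i]:
            out.append(i)
    return out


class TestLocalMaxima:
    @pytest.mark.parametrize(
        "y,expected",
        [
            ([0, 1, 0], [1]),
            ([0, 1, 1, 0], [1]),            # plateau takes its first sample
            ([1, 0, 1], []),                # endpoints are never maxima
            ([0, 1, 1, 2, 0], [3]),
            ([0, 0, 0], []),
            ([3, 2, 1], []),
        ],
    )
    def test_hand_cases(self, y, expected):
        assert list(local_maxima_1d(np.array(y, float))) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.integers(-3, 3), min_size=3, max_size=20))
    def test_matches_brute_force(self, ys):
        y = np.array(ys, dtype=float)
        assert list(local_maxima_1d(y)) == brute_force_maxima(y)


class TestPeakDetection:
    def test_flat_traces_yield_no_events(self, make_norm):
        det = detect_spontaneous_peaks(make_norm(np.zeros((3, 30))))
        assert len(det) == 0

    def test_percentile_retains_exact_top_fraction(self, make_norm):
        # 100 spike candidates with distinct derivative heights across 10 ROIs
        heights = (1 + np.arange(100)) / 100.0
        dff = np.zeros((10, 61))
        for i, h in enumerate(heights):
            roi, slot = divmod(i, 10)
            t = 3 + 6 * slot
            dff[roi, t] = h  # isolated triangle: rise h then fall h
        norm = make_norm(dff)
        det = detect_spontaneous_peaks(norm, percentile=95.0)
        assert det.n_candidates == 100
        retained = sorted(e.derivative_height for e in det)
        assert len(retained) == 5
        assert np.allclose(retained, heights[-5:])

    def test_oracle_equivalence_on_short_traces(self, make_norm):
        # exhaustive brute force over random <=20-sample recordings
        rng = np.random.default_rng(42)
        for _ in range(100):
            n_roi = rng.integers(1, 4)
            n_t = rng.integers(5, 21)
            dff = rng.normal(0, 1, (n_roi, n_t)).round(2)
            norm = make_norm(dff)
            det = detect_spontaneous_peaks(norm, percentile=80.0)
            ddff = np.diff(dff, axis=1)
            pooled = []
            per_roi = []
            for r in range(n_roi):
                idx = brute_force_maxima(ddff[r])
                per_roi.append(idx)
                pooled.extend(ddff[r][i] for i in idx)
            if not pooled:
                assert len(det) == 0
                continue
            thr = np.percentile(pooled, 80.0)
            assert det.threshold == pytest.approx(thr)
            expected = {
                (r, i) for r, idx in enumerate(per_roi) for i in idx if ddff[r][i] > thr
            }
            got = {(int(e.roi_id), int(e.time_s) - 1) for e in det}
            assert got == expected

    def test_amplitude_reads_dff_peak_of_noiseless_transient(self, make_norm):
        t = np.arange(80, dtype=float)
        dff = 0.7 * transient_kernel(t - 20.0, 2.0, 8.0)
        dff += 0.05 * transient_kernel(t - 55.0, 2.0, 8.0)  # small second event
        det = detect_spontaneous_peaks(make_norm(dff[None, :]), percentile=50.0)
        assert len(det) >= 1
        best = max(det, key=lambda e: e.derivative_height)
        assert best.amplitude == pytest.approx(dff.max(), rel=1e-6)
        assert 20.0 <= best.time_s <= 25.0


# ---------------------------------------------------------------------------
# per-ROI metrics

class TestSpontaneousMetrics:
    def test_zero_event_roi(self, make_norm):
        norm = make_norm(np.zeros((1, 30)))
        det = detect_spontaneous_peaks(norm)
        (m,) = roi_spontaneous_metrics(det, norm)
        assert not m.has_spontaneous_response
        assert m.peak_frequency == 0
        assert np.isnan(m.peak_height)

    def test_peak_height_is_median_amplitude(self, make_norm):
        from gliakit.traces import PeakEvent

        norm = make_norm(np.zeros((1, 30)))
        events = [
            PeakEvent(0, 5.0, 1.0, a, "spontaneous") for a in (0.2, 0.6, 0.4)
        ]
        (m,) = roi_spontaneous_metrics(events, norm)
        assert m.peak_height == pytest.approx(0.4)
        assert m.peak_frequency == 3

    def test_counting_consistency_and_mfes_bound(self):
        traces, _ = simulate_trace_set(TraceSimConfig(n_rois=30, seed=5))
        norm = normalize_dff(traces)
        det = detect_spontaneous_peaks(norm)
        metrics = roi_spontaneous_metrics(det, norm)
        assert sum(m.peak_frequency for m in metrics) == len(det)
        for m in metrics:
            for e in det.for_roi(m.roi_id):
                assert m.mfes >= e.derivative_height - 1e-12


# ---------------------------------------------------------------------------
# evoked responders

class TestResponderClassification:
    def test_flat_evoked_window_gives_zero_responders(self, make_norm):
        rng = np.random.default_rng(3)
        dff = rng.normal(0, 0.02, (10, 120))  # activity but no evoked response
        norm = make_norm(dff, baseline_end=100, evoked_end=120)
        cls = classify_evoked_responders(norm)
        assert cls.proportion().k == 0

    def test_dominating_peak_is_responder_under_both_rules(self, make_norm):
        dff = np.zeros((1, 120))
        dff[0, 40] = 0.1                      # small spontaneous transient
        dff[0, 105:110] = 1.0                 # huge evoked response
        norm = make_norm(dff, baseline_end=100, evoked_end=120)
        for rule in ("spontaneous_percentile", "max_fraction"):
            cls = classify_evoked_responders(norm, rule=rule)
            assert list(cls.responder_ids) == [0]

    def test_kcl_protocol_labels_neurons(self):
        traces, truth = simulate_trace_set(TraceSimConfig(n_rois=50, seed=2))
        norm = normalize_dff(traces)
        cls = classify_evoked_responders(norm)
        assert set(cls.classes.unique()) <= {"neuron", "non_neuron"}
        # strong evoked amplitude: classification should track the truth well
        agreement = np.mean(
            (cls.classes.to_numpy() == "neuron") == truth.responder
        )
        assert agreement >= 0.9

    def test_unknown_rule_rejected(self, make_norm):
        norm = make_norm(np.zeros((1, 120)), baseline_end=100, evoked_end=120)
        with pytest.raises(ValueError, match="unknown rule"):
            classify_evoked_responders(norm, rule="nope")

    def test_missing_evoked_window_raises(self, make_norm):
        norm = make_norm(np.zeros((1, 50)))
        with pytest.raises(ValueError, match="evoked window"):
            classify_evoked_responders(norm)


class TestEvokedMetrics:
    def test_rectangular_pulse_flux_duration(self, make_norm):
        dff = np.zeros((1, 120))
        dff[0, 104:108] = 1.0  # 4-sample pulse at 1 Hz
        norm = make_norm(dff, baseline_end=100, evoked_end=120)
        cls = classify_evoked_responders(norm)
        (m,) = evoked_response_metrics(norm, cls)
        assert m.evoked_peak_height == pytest.approx(1.0)
        assert m.flux_duration_s == pytest.approx(4.0)

    def test_noiseless_kernel_peak_height(self, make_norm):
        t = np.arange(120, dtype=float)
        dff = 1.0 * transient_kernel(t - 100.0, 1.5, 8.0)
        norm = make_norm(dff[None, :], baseline_end=100, evoked_end=120)
        cls = classify_evoked_responders(norm)
        (m,) = evoked_response_metrics(norm, cls)
        # discrete sampling of the peak-normalized kernel
        assert m.evoked_peak_height == pytest.approx(dff.max(), abs=1e-9)

    def test_flux_duration_grows_with_decay_constant(self, make_norm):
        durations = []
        for tau_d in (6.0, 12.0):
            t = np.arange(160, dtype=float)
            dff = transient_kernel(t - 100.0, 1.5, tau_d)
            norm = make_norm(dff[None, :], baseline_end=100, evoked_end=160)
            cls = classify_evoked_responders(norm)
            (m,) = evoked_response_metrics(norm, cls)
            durations.append(m.flux_duration_s)
        assert durations[1] > durations[0]


# ---------------------------------------------------------------------------
# proportions and dilution arithmetic

class TestProportionAndDilution:
    def test_trivial_proportions(self):
        assert responder_proportion([False] * 10).value == 0.0
        p = responder_proportion([True] * 72 + [False] * 28)
        assert (p.k, p.n, p.value) == (72, 100, 0.72)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            responder_proportion([])

    def test_proportion_converges_to_configured_fraction(self):
        traces, truth = simulate_trace_set(
            TraceSimConfig(n_rois=1000, responder_fraction=0.6, seed=11)
        )
        assert abs(truth.responder.mean() - 0.6) <= 0.03

    @pytest.mark.parametrize(
        "stock,added,bath,expected",
        [(500.0, 20.0, 180.0, 50.0), (200.0, 20.0, 180.0, 20.0), (7.0, 5.0, 0.0, 7.0)],
    )
    def test_final_bath_concentration(self, stock, added, bath, expected):
        assert final_bath_concentration(stock, added, bath) == pytest.approx(expected)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            final_bath_concentration(500.0, 0.0, 180.0)
        with pytest.raises(ValueError):
            final_bath_concentration(500.0, 20.0, -1.0)


# ---------------------------------------------------------------------------
# scale invariance of the whole metric set

def test_all_metrics_invariant_under_loading_efficiency():
    """F -> c·F must leave every reported metric unchanged (the point of ΔF/F₀)."""
    from gliakit.pipeline import analyze_trace_set
    from gliakit.traces import TraceSet

    traces, _ = simulate_trace_set(TraceSimConfig(n_rois=20, seed=9))
    base = analyze_trace_set(traces)
    for c in (0.1, 3.0, 10.0):
        scaled = TraceSet(traces.roi_ids, traces.times_s, c * traces.F, traces.protocol)
        other = analyze_trace_set(scaled)
        for col in ("peak_frequency", "is_responder", "roi_class", "has_spontaneous_response"):
            assert (base[col] == other[col]).all(), col
        for col in ("mfes", "peak_height", "evoked_peak_height", "flux_duration_s"):
            np.testing.assert_allclose(
                base[col].to_numpy(), other[col].to_numpy(), rtol=1e-9, err_msg=col
            )
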