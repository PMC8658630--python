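"""Streaming FSM detector: hand-traced oracles, invariants, ground truth."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mmiflow import (BinnedTrace, DetectorConfig, DetectorState,
                     StreamingDetector, auto_threshold, bin_photons,
                     detect_stream, generate_photon_stream,
                     pattern_span_correction)
from conftest import make_params

BW = 100e-6


def trace_of(counts, bin_width=BW, start_time=0.0):
    return BinnedTrace(np.asarray(counts, dtype=np.int64), bin_width,
                       start_time)


def rect_cluster_counts():
    """0, then seven 1-bin peaks of height 10 separated by single zeros."""
    counts = [0]
    for _ in range(7):
        counts += [10, 0]
    return counts + [0] * 14


@pytest.fixture
def simple_config():
    return DetectorConfig(bin_width=BW, start_threshold=5.0,
                          end_threshold=5.0, wait_time=1e-3)


def test_all_zero_trace_no_events(simple_config):
    events = detect_stream(trace_of([0] * 500), simple_config)
    assert events == []
    det = StreamingDetector(simple_config)
    det.push([0] * 500)
    assert det.state.phase.value == "baseline"


def test_rectangular_cluster_hand_trace(simple_config):
    """Hand-traced FSM on the canonical 7-peak rectangular cluster."""
    events = detect_stream(trace_of(rect_cluster_counts()), simple_config)
    assert len(events) == 1
    ev = events[0]
    assert ev.index == 1
    assert ev.n_peaks == 7
    assert all(p.width == pytest.approx(BW) for p in ev.peaks)
    assert all(p.height == 10 for p in ev.peaks)
    # first above-threshold bin is bin 1, last is bin 13
    assert ev.detection_time_tag == pytest.approx(1 * BW)
    assert ev.cluster_width == pytest.approx(13 * BW)
    assert not ev.truncated


def test_two_separated_clusters(simple_config):
    counts = rect_cluster_counts() + [0] * 20 + rect_cluster_counts()
    events = detect_stream(trace_of(counts), simple_config)
    assert len(events) == 2
    assert [e.index for e in events] == [1, 2]
    assert all(e.n_peaks == 7 for e in events)


def test_wait_time_merges_nearby_runs(simple_config):
    # two runs separated by 5 quiet bins (0.5 ms < 1 ms wait): one cluster
    counts = [0, 10, 10] + [0] * 5 + [10, 10] + [0] * 15
    events = detect_stream(trace_of(counts), simple_config)
    assert len(events) == 1
    assert events[0].n_peaks == 2
    # 10 quiet bins (1 ms = wait): two clusters
    counts = [0, 10, 10] + [0] * 10 + [10, 10] + [0] * 15
    events = detect_stream(trace_of(counts), simple_config)
    assert len(events) == 2


def test_end_of_trace_flush(simple_config):
    counts = [0] * 5 + [10, 10, 10]
    events = detect_stream(trace_of(counts), simple_config)
    assert len(events) == 1
    assert events[0].n_peaks == 1
    assert events[0].cluster_width == pytest.approx(3 * BW)


def test_diff_threshold_gates_cluster_start():
    # slow ramp never jumps by >= 4 between consecutive bins
    ramp = list(range(0, 20, 2)) + [20] * 5 + [0] * 15
    cfg = DetectorConfig(bin_width=BW, start_threshold=5.0, end_threshold=5.0,
                         diff_threshold=4.0, wait_time=1e-3)
    assert detect_stream(trace_of(ramp), cfg) == []
    jump = [0, 0, 20, 20] + [0] * 15
    assert len(detect_stream(trace_of(jump), cfg)) == 1


def test_truncation_at_max_cluster_width(simple_config):
    cfg = dataclasses.replace(simple_config, max_cluster_width=2e-3)
    counts = [0] + [10] * 60 + [0] * 15
    events = detect_stream(trace_of(counts), cfg)
    assert len(events) >= 2
    assert events[0].truncated
    assert events[0].cluster_width <= 2e-3 + BW + 1e-12


def test_event_height_background_subtraction():
    cfg = DetectorConfig(bin_width=BW, background_level=2.0,
                         start_threshold=8.0, end_threshold=5.0,
                         subtract_background=True)
    counts = [2, 2, 12, 2] + [0] * 15
    ev = detect_stream(trace_of(counts), cfg)[0]
    assert ev.peaks[0].height == 10.0


@pytest.mark.parametrize("chunk", [1, 7, 1000])
def test_chunking_invariance(chunk, detector_config):
    rng = np.random.default_rng(5)
    counts = rng.poisson(1.0, size=6000)
    spikes = rng.random(6000) < 0.03
    counts = counts + spikes * rng.integers(5, 40, size=6000)
    ref = detect_stream(trace_of(counts), detector_config)
    det = StreamingDetector(detector_config)
    events = []
    for k in range(0, counts.size, chunk):
        events += det.push(counts[k:k + chunk])
    events += det.finish()
    assert len(events) == len(ref)
    for a, b in zip(events, ref):
        assert a.detection_time_tag == b.detection_time_tag
        assert a.cluster_width == b.cluster_width
        assert a.n_peaks == b.n_peaks


def test_state_is_constant_size(detector_config):
    """The FSM keeps O(1) state: no field grows with the trace length."""
    det = StreamingDetector(detector_config)
    rng = np.random.default_rng(6)
    det.push(rng.poisson(0.5, size=10_000))
    state = det.state
    assert len(dataclasses.fields(DetectorState)) == len(
        dataclasses.fields(state))
    # the only unbounded-looking field holds at most one open cluster's peaks
    assert len(state.peaks) <= detector_config.max_cluster_bins


@given(st.integers(min_value=0, max_value=10_000))
def test_threshold_monotonicity(seed):
    """Raising the start threshold never increases the event count."""
    rng = np.random.default_rng(seed)
    counts = rng.poisson(1.0, size=400) + \
        (rng.random(400) < 0.1) * rng.integers(0, 30, size=400)
    n_prev = None
    for thr in (5.0, 10.0, 15.0, 20.0):
        cfg = DetectorConfig(bin_width=BW, start_threshold=thr,
                             end_threshold=5.0, wait_time=1e-3)
        n = len(detect_stream(trace_of(counts), cfg))
        if n_prev is not None:
            assert n <= n_prev
        n_prev = n


def test_event_separation_at_least_wait_time(detector_config):
    rng = np.random.default_rng(7)
    counts = rng.poisson(1.0, size=5000) + \
        (rng.random(5000) < 0.05) * rng.integers(0, 40, size=5000)
    events = detect_stream(trace_of(counts), detector_config)
    tags = [e.detection_time_tag for e in events if not e.truncated]
    widths = [e.cluster_width for e in events if not e.truncated]
    for (t0, w0), t1 in zip(zip(tags, widths), tags[1:]):
        assert t1 - (t0 + w0) >= detector_config.wait_time - BW / 2


class TestSimulationGroundTruth:

    def test_clean_transits_all_detected(self, clean_params, clean_transits,
                                         detector_config):
        stream = generate_photon_stream(clean_transits, clean_params)
        trace = bin_photons(stream, BW)
        events = detect_stream(trace, detector_config)
        assert len(events) == len(clean_transits)
        # shot noise can occasionally split one peak at its edge
        peak_counts = np.array([e.n_peaks for e in events])
        assert np.median(peak_counts) == clean_params.n_spots
        assert np.all(peak_counts >= clean_params.n_spots)
        assert np.all(peak_counts <= clean_params.n_spots + 2)

    def test_noise_free_trace_resolves_all_spots(self, clean_params,
                                                 clean_transits,
                                                 detector_config):
        """On the deterministic expected-intensity trace every event
        shows exactly n_spots peaks."""
        from mmiflow import emission_rate
        n_bins = int(clean_params.duration / BW)
        centers = (np.arange(n_bins) + 0.5) * BW
        intensity = np.zeros(n_bins)
        for tr in clean_transits:
            intensity += np.asarray(
                emission_rate(tr, clean_params, centers))
        counts = np.rint(intensity * BW).astype(np.int64)
        trace = BinnedTrace(counts, BW)
        events = detect_stream(trace, detector_config)
        assert len(events) == len(clean_transits)
        assert all(e.n_peaks == clean_params.n_spots for e in events)

    def test_detection_time_tags_match_truth(self, clean_params,
                                             clean_transits, detector_config):
        stream = generate_photon_stream(clean_transits, clean_params)
        events = detect_stream(bin_photons(stream, BW), detector_config)
        sigma = clean_params.fwhm / 2.3548
        amp = clean_params.peak_photon_rate * BW
        # analytic position where the first peak crosses start_threshold
        x_cross = clean_params.spot_positions[0] - sigma * np.sqrt(
            2 * np.log(amp / detector_config.start_threshold))
        for tr, ev in zip(clean_transits, events):
            expected = tr.entry_time + x_cross / tr.velocity
            assert abs(ev.detection_time_tag - expected) <= 2 * BW

    def test_cluster_width_matches_span_correction(self, clean_params,
                                                   clean_transits,
                                                   detector_config):
        stream = generate_photon_stream(clean_transits, clean_params)
        events = detect_stream(bin_photons(stream, BW), detector_config)
        corr = pattern_span_correction(clean_params, detector_config)
        expected_dt = corr * clean_params.geometry.mmi_width / 7500.0
        widths = np.array([e.cluster_width for e in events])
        assert np.all(np.abs(widths - expected_dt) <= 3 * BW)

    def test_coincident_transits_merge_to_one_event(self, clean_params,
                                                    detector_config):
        from mmiflow import TransitRecord
        pair = [TransitRecord(1.0, 7500.0), TransitRecord(1.004, 7500.0)]
        stream = generate_photon_stream(pair, clean_params)
        events = detect_stream(bin_photons(stream, BW), detector_config)
        assert len(events) == 1


class TestAutoThreshold:

    def test_short_prefix_rejected(self):
        with pytest.raises(ValueError, match="100"):
            auto_threshold(np.full(99, 3.0))

    def test_constant_prefix(self):
        start, end, bg = auto_threshold(np.full(200, 4.0))
        assert bg == 4.0
        assert end == 5.0
        assert start >= end

    def test_poisson_prefix_matches_sample_statistics(self):
        rng = np.random.default_rng(8)
        prefix = rng.poisson(10.0, size=2000).astype(float)
        start, end, bg = auto_threshold(prefix, k_sigma=5.0)
        mean, std = prefix.mean(), prefix.std(ddof=1)
        assert bg == pytest.approx(mean)
        assert start == pytest.approx(mean + 5 * std)
        assert start == pytest.approx(10 + 5 * np.sqrt(10), rel=0.05)
        assert end == pytest.approx(max(mean + 2.5 * std, mean + 1))

    def test_auto_beats_misset_manual_thresholds(self, clean_params,
                                                 clean_transits):
        params = make_params(clean_params.geometry, background_rate=2e4,
                             seed=12)
        stream = generate_photon_stream(clean_transits, params)
        trace = bin_photons(stream, BW)
        start, end, bg = auto_threshold(trace.counts[:1000])
        auto_cfg = DetectorConfig(bin_width=BW, background_level=bg,
                                  start_threshold=start, end_threshold=end)
        # mis-set: start threshold above the peak amplitude misses everything
        bad_cfg = DetectorConfig(bin_width=BW, start_threshold=80.0,
                                 end_threshold=60.0)
        from mmiflow import match_events
        truth = [t.entry_time + 0.005 for t in clean_transits]
        acc_auto = match_events(truth, detect_stream(trace, auto_cfg),
                                tolerance_ms=20.0).accuracy_pct
        acc_bad = match_events(truth, detect_stream(trace, bad_cfg),
                               tolerance_ms=20.0).accuracy_pct
        assert acc_auto == 100.0
        assert acc_auto >= acc_bad


def test_config_invariants():
    with pytest.raises(ValueError):
        DetectorConfig(start_threshold=3.0, end_threshold=5.0)
    with pytest.raises(ValueError):
        DetectorConfig(wait_time=0.0)
    with pytest.raises(ValueError):
        DetectorConfig(diff_threshold=-1.0)


def test_wait_time_validator_warnings():
    cfg = DetectorConfig(wait_time=1e-3)
    with pytest.warns(UserWarning, match="inter-peak"):
        cfg.validate_for(inter_peak_gap_s=2e-3, mean_inter_event_s=0.5)
    with pytest.warns(UserWarning, match="inter-event"):
        cfg.validate_for(inter_peak_gap_s=1e-4, mean_inter_event_s=5e-4)
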