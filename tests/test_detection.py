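import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st

from finemotor.detection import (
    PRESETS,
    DetectionConfig,
    EventSet,
    MovementEvent,
    candidate_windows,
    confirm_events,
    detect_events,
)
from finemotor.signal_io import ScalarSeries
from finemotor.synthetic import BlockSimParams, simulate_block


def _series(values, fs=1000.0):
    return ScalarSeries(values=np.asarray(values, dtype=float), sampling_rate_hz=fs)


def windows_oracle(amp, jerk, cfg, fs=1000.0):
    """Independent O(n) scan: label actives, merge runs, filter duration."""
    t_amp = np.percentile(amp, cfg.rms_percentile)
    t_jerk = np.percentile(np.abs(jerk), cfg.jerk_percentile)
    if cfg.combine == "or":
        active = (amp >= t_amp) | (np.abs(jerk) >= t_jerk)
    else:
        active = (amp >= t_amp) & (np.abs(jerk) >= t_jerk)
    raw = []
    start = None
    for i, a in enumerate(active):
        if a and start is None:
            start = i
        elif not a and start is not None:
            raw.append([start, i])
            start = None
    if start is not None:
        raw.append([start, len(active)])
    gap = int(round(cfg.merge_gap_ms * 1e-3 * fs))
    merged = []
    for s, e in raw:
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_len = cfg.min_event_duration_ms * 1e-3 * fs
    return [(s / fs, (e - 1) / fs) for s, e in merged if e - s >= min_len]


def prominence_oracle(x):
    """Exhaustive topographic prominence of every strict local maximum."""
    out = {}
    n = len(x)
    for i in range(1, n - 1):
        if not (x[i] > x[i - 1] and x[i] >= x[i + 1]):
            continue
        if x[i] == x[i + 1]:  # plateau: scipy takes the left edge; skip ties
            continue
        left_min = x[i]
        for j in range(i - 1, -1, -1):
            if x[j] > x[i]:
                break
            left_min = min(left_min, x[j])
        else:
            left_min = min(left_min, np.min(x[: i + 1]))
        right_min = x[i]
        for j in range(i + 1, n):
            if x[j] > x[i]:
                break
            right_min = min(right_min, x[j])
        else:
            right_min = min(right_min, np.min(x[i:]))
        out[i] = x[i] - max(left_min, right_min)
    return out


class TestCandidateWindows:
    def test_flat_zero_gives_no_events(self):
        cfg = PRESETS["finger_tapping"]
        zeros = _series(np.zeros(5000))
        # whole block is "active" at threshold 0, but confirmation finds no
        # peaks in a constant signal
        events = confirm_events(zeros, candidate_windows(zeros, zeros, cfg), cfg)
        assert len(events) == 0

    def test_single_burst_in_noise(self, rng):
        fs = 1000.0
        x = rng.normal(0, 0.05, size=5000)
        t = np.arange(5000) / fs
        burst = 5.0 * np.exp(-((t - 2.5) ** 2) / (2 * 0.02**2))
        amp = np.abs(x) + burst
        jerk = np.gradient(amp) * fs
        cfg = PRESETS["finger_tapping"]
        wins = candidate_windows(_series(amp), _series(jerk), cfg)
        covering = [w for w in wins if w[0] <= 2.5 <= w[1]]
        assert len(covering) == 1

    def test_matches_bruteforce_oracle(self, rng):
        cfg = PRESETS["finger_tapping"]
        for trial in range(20):
            r = np.random.default_rng(trial)
            amp = np.abs(r.normal(size=400)) + 2.0 * (r.random(400) > 0.95)
            jerk = r.normal(size=400) * 50
            got = candidate_windows(_series(amp), _series(jerk), cfg)
            expected = windows_oracle(amp, jerk, cfg)
            assert got == expected

    def test_empty_series_rejected(self):
        cfg = PRESETS["finger_tapping"]
        with pytest.raises(ValueError):
            candidate_windows(_series([]), _series([]), cfg)

    @given(st.integers(0, 50))
    @settings(max_examples=15, deadline=None)
    def test_percentile_monotonicity(self, seed):
        # raising either percentile never increases the total supra-threshold
        # support (window count itself is not monotone: a higher threshold
        # can split one long run into two shorter ones)
        r = np.random.default_rng(seed)
        amp = np.abs(r.normal(size=300))
        jerk = r.normal(size=300)
        lo = DetectionConfig(
            rms_percentile=70, jerk_percentile=80, merge_gap_ms=0,
            min_event_duration_ms=0,
        )
        hi = DetectionConfig(
            rms_percentile=90, jerk_percentile=95, merge_gap_ms=0,
            min_event_duration_ms=0,
        )
        def support(cfg):
            wins = candidate_windows(_series(amp), _series(jerk), cfg)
            return sum(b - a for a, b in wins)
        assert support(hi) <= support(lo) + 1e-12


class TestConfirmEvents:
    def test_min_distance_keeps_taller(self):
        # two peaks 50 ms apart: greedy-by-height retention keeps the taller
        fs = 1000.0
        x = np.zeros(1000)
        x[400] = 5.0
        x[450] = 8.0
        cfg = replace(PRESETS["finger_tapping"], min_event_duration_ms=0.0)
        events = confirm_events(_series(x), [(0.3, 0.6)], cfg)
        assert len(events) == 1
        assert events.events[0].peak_s == pytest.approx(0.450)

    def test_window_without_prominent_peak_discarded(self):
        x = np.zeros(1000)
        x[100] = 10.0  # prominent peak outside the candidate window
        cfg = PRESETS["finger_tapping"]
        events = confirm_events(_series(x), [(0.5, 0.8)], cfg)
        assert len(events) == 0

    def test_prominence_matches_exhaustive_oracle(self):
        from scipy.signal import find_peaks

        for seed in range(10):
            r = np.random.default_rng(seed)
            x = np.round(r.normal(size=120), 3)
            idx, props = find_peaks(x, prominence=0)
            oracle = prominence_oracle(x)
            for i, prom in zip(idx, props["prominences"]):
                if i in oracle:
                    assert prom == pytest.approx(oracle[i], abs=1e-9)

    def test_event_ordering_invariants(self, noisy_block):
        trace, _ = noisy_block
        events = detect_events(trace)
        peaks = events.peak_times()
        assert np.all(np.diff(peaks) > 0)
        assert np.all(np.diff(peaks) >= 0.100 - 1e-9)
        for e in events:
            assert e.onset_s < e.peak_s < e.offset_s


class TestDetectEvents:
    def test_noiseless_block_recovers_all_events(self, clean_block):
        trace, truth = clean_block
        events = detect_events(trace)
        assert len(events) == truth.n_events == 40

    def test_event_count_bounded_by_distance(self, noisy_block):
        trace, _ = noisy_block
        cfg = PRESETS["finger_tapping"]
        events = detect_events(trace, cfg)
        bound = int(np.ceil(trace.duration_s / (cfg.min_peak_distance_ms * 1e-3)))
        assert len(events) <= bound

    def test_pure_noise_yields_zero_events(self):
        # realistic sensor-noise-only blocks; Monte-Carlo false positives
        total = 0
        for seed in range(10):
            params = BlockSimParams(
                burst_amplitude=0.0,
                noise_sd=0.3,
                drift_amplitude=0.3,
                rng_seed=seed,
            )
            trace, _ = simulate_block(params)
            total += len(detect_events(trace))
        assert total == 0

    def test_determinism(self, noisy_block):
        trace, _ = noisy_block
        e1 = detect_events(trace)
        e2 = detect_events(trace)
        assert np.array_equal(e1.peak_times(), e2.peak_times())

    def test_preset_selected_from_metadata(self, clean_block):
        trace, _ = clean_block
        trace.meta["movement_type"] = "pronation_supination"
        events = detect_events(trace)
        assert events.config == PRESETS["pronation_supination"]

    def test_invalid_config_values(self):
        with pytest.raises(ValueError, match="rms_percentile"):
            DetectionConfig(rms_percentile=150)
        with pytest.raises(ValueError, match="prominence_sd"):
            DetectionConfig(prominence_sd=0)
        with pytest.raises(ValueError, match="combine"):
            DetectionConfig(combine="xor")


def test_movement_event_validates_order():
    with pytest.raises(ValueError):
        MovementEvent(onset_s=1.0, peak_s=0.5, offset_s=2.0, peak_magnitude=1.0, event_index=0)


def test_event_set_requires_increasing_peaks():
    events = [
        MovementEvent(0.0, 0.5, 1.0, 1.0, 0),
        MovementEvent(0.1, 0.4, 1.1, 1.0, 1),
    ]
    with pytest.raises(ValueError):
        EventSet(events=events)
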