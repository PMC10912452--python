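"""Two-stage single-trial movement-event detection.

Stage 1 marks candidate windows where the RMS envelope or the absolute
jerk of the vector magnitude exceeds block-wise percentile thresholds
(presets: 90th/95th percentile for finger tapping, 80th/85th for
pronation-supination). Stage 2 confirms windows by requiring a magnitude
peak with topographic prominence >= 2.5 x SD of the block magnitude and
pairwise peak spacing >= 100 ms (tallest peaks retained first).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .signal_io import (
    AccelTrace,
    ScalarSeries,
    highpass_filter,
    jerk_series,
    rms_envelope,
    vector_magnitude,
)

__all__ = [
    "DetectionConfig",
    "MovementEvent",
    "EventSet",
    "PRESETS",
    "candidate_windows",
    "confirm_events",
    "detect_events",
]


@dataclass(frozen=True)
class DetectionConfig:
    rms_percentile: float = 90.0
    jerk_percentile: float = 95.0
    prominence_sd: float = 2.5
    min_peak_distance_ms: float = 100.0
    merge_gap_ms: float = 25.0
    min_event_duration_ms: float = 5.0
    combine: str = "or"  # how RMS and jerk thresholds are combined
    threshold_on: str = "magnitude"  # raw "magnitude" (default) or "rms" envelope
    jerk_on: str = "envelope"  # jerk input for stage 1: "envelope" or "magnitude"
    min_prominence_abs: float = 2.0  # m/s^2; absolute floor, kills sensor noise
    rms_window_ms: float = 50.0
    highpass_order: int = 3
    highpass_cutoff_hz: float = 1.0

    def __post_init__(self) -> None:
        for name in ("rms_percentile", "jerk_percentile"):
            value = getattr(self, name)
            if not 0 < value < 100:
                raise ValueError(f"{name}={value} must be in (0, 100)")
        if self.prominence_sd <= 0:
            raise ValueError("prominence_sd must be > 0")
        for name in ("min_peak_distance_ms", "merge_gap_ms", "min_event_duration_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.combine not in ("or", "and"):
            raise ValueError("combine must be 'or' or 'and'")
        if self.threshold_on not in ("rms", "magnitude"):
            raise ValueError("threshold_on must be 'rms' or 'magnitude'")
        if self.jerk_on not in ("envelope", "magnitude"):
            raise ValueError("jerk_on must be 'envelope' or 'magnitude'")


PRESETS: dict[str, DetectionConfig] = {
    "finger_tapping": DetectionConfig(rms_percentile=90.0, jerk_percentile=95.0),
    "pronation_supination": DetectionConfig(rms_percentile=80.0, jerk_percentile=85.0),
}


@dataclass(frozen=True)
class MovementEvent:
    onset_s: float
    peak_s: float
    offset_s: float
    peak_magnitude: float
    event_index: int

    def __post_init__(self) -> None:
        if not self.onset_s < self.peak_s < self.offset_s:
            raise ValueError("event must satisfy onset < peak < offset")


@dataclass
class EventSet:
    events: list
    meta: dict = field(default_factory=dict)
    config: DetectionConfig | None = None

    def __post_init__(self) -> None:
        peaks = self.peak_times()
        if peaks.size > 1 and np.any(np.diff(peaks) <= 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def peak_times(self) -> np.ndarray:
        return np.array([e.peak_s for e in self.events])


def candidate_windows(
    rms: ScalarSeries, jerk: ScalarSeries, config: DetectionConfig
) -> list[tuple[float, float]]:
    """Supra-threshold runs of the block, merged and duration-filtered.

    A sample is active when the envelope exceeds its block percentile
    threshold or (|jerk| exceeds its own); runs closer than ``merge_gap_ms``
    are merged and runs shorter than ``min_event_duration_ms`` dropped.
    Percentiles use the linear-interpolation definition.
    """
    if rms.values.size == 0 or jerk.values.size == 0:
        raise ValueError("empty input series")
    if rms.values.size != jerk.values.size:
        raise ValueError("rms and jerk series must have equal length")
    fs = rms.sampling_rate_hz
    t_rms = np.percentile(rms.values, config.rms_percentile)
    t_jerk = np.percentile(np.abs(jerk.values), config.jerk_percentile)
    rms_active = rms.values >= t_rms
    jerk_active = np.abs(jerk.values) >= t_jerk
    active = (
        rms_active | jerk_active if config.combine == "or" else rms_active & jerk_active
    )

    runs = _runs(active)
    merge_gap = int(round(config.merge_gap_ms * 1e-3 * fs))
    merged: list[list[int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] < merge_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    min_len = config.min_event_duration_ms * 1e-3 * fs
    return [
        (start / fs, (stop - 1) / fs)
        for start, stop in merged
        if (stop - start) >= min_len
    ]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def confirm_events(
    mag: ScalarSeries,
    windows: list[tuple[float, float]],
    config: DetectionConfig,
    meta: dict | None = None,
) -> EventSet:
    """Keep windows containing a prominent magnitude peak.

    Peaks come from the magnitude series with prominence
    >= prominence_sd x SD(block magnitude) and minimum spacing
    min_peak_distance_ms (scipy's tallest-first retention). A kept window
    becomes one event whose peak is the highest confirmed peak inside it.
    """
    fs = mag.sampling_rate_hz
    sd = float(np.std(mag.values))
    distance = max(int(round(config.min_peak_distance_ms * 1e-3 * fs)), 1)
    # relative prominence threshold per the block SD, with an absolute floor
    # (sensor noise lives well below the m/s^2 scale of real movements)
    threshold = max(config.prominence_sd * sd, config.min_prominence_abs)
    if sd > 0:
        peak_idx, _ = sps.find_peaks(
            mag.values, prominence=threshold, distance=distance
        )
    else:
        peak_idx = np.array([], dtype=int)
    peak_t = peak_idx / fs
    events: list[MovementEvent] = []
    for onset, offset in windows:
        inside = peak_idx[(peak_t >= onset) & (peak_t <= offset)]
        if inside.size == 0:
            continue
        best = inside[np.argmax(mag.values[inside])]
        # half-sample padding keeps onset < peak < offset strict when the
        # confirmed peak sits on a window edge
        events.append(
            MovementEvent(
                onset_s=onset - 0.5 / fs,
                peak_s=best / fs,
                offset_s=offset + 0.5 / fs,
                peak_magnitude=float(mag.values[best]),
                event_index=len(events),
            )
        )
    return EventSet(events=events, meta=dict(meta or {}), config=config)


def detect_events(trace: AccelTrace, config: DetectionConfig | None = None) -> EventSet:
    """Full two-stage detection on one block.

    Pipeline: high-pass filter -> vector magnitude -> (RMS envelope,
    jerk) -> percentile candidate windows -> prominence/distance
    confirmation. When ``config`` is None the preset is chosen from
    ``trace.meta['movement_type']`` (finger-tapping preset otherwise).
    """
    if config is None:
        config = PRESETS.get(
            trace.meta.get("movement_type", "finger_tapping"),
            PRESETS["finger_tapping"],
        )
    filtered = highpass_filter(
        trace, order=config.highpass_order, cutoff_hz=config.highpass_cutoff_hz
    )
    mag = vector_magnitude(filtered)
    env = rms_envelope(mag, window_ms=config.rms_window_ms)
    # jerk taken on the envelope by default: differentiating the raw
    # magnitude at kHz rates is noise-dominated and would let the jerk
    # percentile admit sensor noise instead of movement flanks
    jerk = jerk_series(env if config.jerk_on == "envelope" else mag)
    amp = env if config.threshold_on == "rms" else mag
    windows = candidate_windows(amp, jerk, config)
    return confirm_events(mag, windows, config, meta=trace.meta)
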