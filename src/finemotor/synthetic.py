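"""Synthetic accelerometer blocks and cohorts with known ground truth.

Every downstream stage (detection, kinematics, profiles, clinical models)
is exercised against data generated here, so each generated quantity is
recorded alongside the signal: burst times and amplitudes per block, the
per-state simulation parameters, the latent severity and laterality offset
per subject, and the clinical item scores derived from them.

Movement events are smooth biphasic bursts (a Gaussian-windowed cosine of
configurable width) projected onto the three axes by a fixed unit
orientation vector; noise, slow drift and an optional tremor sinusoid are
added on top. Amplitude and inter-event jitter are log-normal so both stay
positive at any coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import AccelTrace

__all__ = [
    "BlockSimParams",
    "noise_sd_for_snr",
    "snr_db",
    "GroundTruthEvents",
    "EffectMultipliers",
    "SyntheticSubject",
    "SyntheticCohort",
    "THERAPY_STATES",
    "DEFAULT_EFFECTS",
    "default_effects",
    "simulate_block",
    "simulate_cohort",
]

THERAPY_STATES = (
    ("OFF", "OFF"),
    ("ON", "OFF"),
    ("OFF", "ON"),
    ("ON", "ON"),
)

# default 3-axis orientation of the burst template (unit vector)
_ORIENTATION = np.array([0.55, 0.75, 0.36])
_ORIENTATION = _ORIENTATION / np.linalg.norm(_ORIENTATION)


@dataclass
class BlockSimParams:
    """Generative parameters for one movement block."""

    duration_s: float = 10.0
    sampling_rate_hz: float = 1000.0
    movement_rate_hz: float = 4.0
    burst_amplitude: float = 10.0
    amplitude_cv: float = 0.10
    interval_cv: float = 0.10
    amplitude_slope_per_event: float = 0.0
    noise_sd: float = 1.0
    drift_amplitude: float = 0.5
    tremor_amplitude: float = 0.0
    tremor_freq_hz: float = 5.0
    burst_width_ms: float = 120.0
    carrier_cycles: float = 3.0  # oscillation cycles within the burst width
    rng_seed: int = 0
    orientation: np.ndarray = field(default_factory=lambda: _ORIENTATION.copy())

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.sampling_rate_hz < 200:
            raise ValueError("sampling_rate_hz must be >= 200")
        if self.movement_rate_hz * self.duration_s < 2:
            raise ValueError("movement_rate_hz * duration_s must be >= 2")
        for name in (
            "burst_amplitude",
            "amplitude_cv",
            "interval_cv",
            "noise_sd",
            "drift_amplitude",
            "tremor_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.burst_width_ms <= 0:
            raise ValueError("burst_width_ms must be > 0")


@dataclass
class GroundTruthEvents:
    """Oracle annotations for one simulated block."""

    onset_s: np.ndarray
    peak_s: np.ndarray
    offset_s: np.ndarray
    amplitude: np.ndarray

    def __post_init__(self) -> None:
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        self.peak_s = np.asarray(self.peak_s, dtype=float)
        self.offset_s = np.asarray(self.offset_s, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.peak_s.size and np.any(np.diff(self.peak_s) <= 0):
            raise ValueError("peak times must be strictly increasing")
        if np.any(self.onset_s >= self.peak_s) or np.any(self.peak_s >= self.offset_s):
            raise ValueError("events must satisfy onset < peak < offset")

    @property
    def n_events(self) -> int:
        return self.peak_s.size

    def intervals_ms(self) -> np.ndarray:
        """True inter-event (peak-to-peak) intervals in ms."""
        return np.diff(self.peak_s) * 1e3


@dataclass(frozen=True)
class EffectMultipliers:
    """Dimensionless therapy-state multipliers applied to block parameters.

    ``amplitude_gain`` scales burst amplitude, ``interval_gain`` scales the
    mean inter-event interval (< 1 means faster pacing), ``variability_gain``
    scales both jitter CVs (< 1 means more consistent movements) and
    ``smoothness_gain`` sharpens the burst (higher jerk = smoother
    execution in this coding).
    """

    amplitude_gain: float = 1.0
    interval_gain: float = 1.0
    variability_gain: float = 1.0
    smoothness_gain: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "amplitude_gain",
            "interval_gain",
            "variability_gain",
            "smoothness_gain",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


# OFF/OFF worst, ON/ON best; the two mixed states are intermediate and
# close to one another.
DEFAULT_EFFECTS: dict[tuple[str, str], EffectMultipliers] = {
    ("OFF", "OFF"): EffectMultipliers(1.00, 1.00, 1.00, 1.00),
    ("ON", "OFF"): EffectMultipliers(1.22, 0.92, 0.80, 1.10),
    ("OFF", "ON"): EffectMultipliers(1.28, 0.90, 0.75, 1.12),
    ("ON", "ON"): EffectMultipliers(1.55, 0.80, 0.55, 1.25),
}


def default_effects() -> dict[tuple[str, str], EffectMultipliers]:
    return dict(DEFAULT_EFFECTS)


def _burst_template(
    width_ms: float, sampling_rate_hz: float, carrier_cycles: float = 3.0
) -> tuple[np.ndarray, int]:
    """Gaussian-windowed cosine, unit peak magnitude at the center sample.

    Support is +/- 3 sigma with sigma = width/6. ``carrier_cycles``
    oscillations fit inside the width, giving the spiky multiphasic
    profile of real impact-like movements (the absolute magnitude dips
    towards zero between carrier crests, which is what makes block-level
    percentile thresholds selective for individual events).
    """
    width_s = width_ms * 1e-3
    sigma = width_s / 6.0
    half = int(round(3 * sigma * sampling_rate_hz))
    t = np.arange(-half, half + 1) / sampling_rate_hz
    carrier_hz = carrier_cycles / width_s
    template = np.exp(-(t**2) / (2 * sigma**2)) * np.cos(2 * np.pi * carrier_hz * t)
    return template, half


def simulate_block(params: BlockSimParams) -> tuple[AccelTrace, GroundTruthEvents]:
    """Generate one movement block and its ground-truth annotations.

    The number of events is exactly ``floor(movement_rate_hz * duration_s)``.
    Inter-event intervals are log-normal with the requested CV; if jitter
    would push events past the block edge, all intervals are rescaled by a
    common factor (which preserves their CV).
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    fs = params.sampling_rate_hz
    n_samples = int(round(params.duration_s * fs))

    n_events = int(np.floor(params.movement_rate_hz * params.duration_s))
    mean_interval = 1.0 / params.movement_rate_hz

    intervals = _lognormal(rng, mean_interval, params.interval_cv, n_events - 1)
    margin = 3.5 * params.burst_width_ms * 1e-3 / 2.0 + 2.0 / fs
    available = params.duration_s - 2 * margin
    span = float(np.sum(intervals))
    if span > available:
        intervals *= available / span  # uniform rescale keeps the CV
        span = available
    first_peak = margin + (available - span) / 2.0
    peak_s = first_peak + np.concatenate([[0.0], np.cumsum(intervals)])

    amplitudes = params.burst_amplitude * _lognormal_unit(
        rng, params.amplitude_cv, n_events
    )
    if params.amplitude_slope_per_event != 0.0:
        k = np.arange(n_events)
        amplitudes = amplitudes * np.clip(
            1.0 + params.amplitude_slope_per_event * k, 0.05, None
        )

    template, half = _burst_template(
        params.burst_width_ms, fs, params.carrier_cycles
    )
    signal = np.zeros(n_samples)
    peak_idx = np.round(peak_s * fs).astype(int)
    for idx, amp in zip(peak_idx, amplitudes):
        lo = idx - half
        hi = idx + half + 1
        signal[max(lo, 0) : min(hi, n_samples)] += (
            amp * template[max(0, -lo) : template.size - max(0, hi - n_samples)]
        )

    axes = np.outer(signal, params.orientation)

    if params.noise_sd > 0:
        axes += rng.normal(0.0, params.noise_sd, size=axes.shape)
    if params.drift_amplitude > 0:
        t = np.arange(n_samples) / fs
        for axis in range(3):
            f = rng.uniform(0.05, 0.4)
            phase = rng.uniform(0, 2 * np.pi)
            axes[:, axis] += params.drift_amplitude * np.sin(2 * np.pi * f * t + phase)
    if params.tremor_amplitude > 0:
        t = np.arange(n_samples) / fs
        phase = rng.uniform(0, 2 * np.pi)
        tremor = params.tremor_amplitude * np.sin(
            2 * np.pi * params.tremor_freq_hz * t + phase
        )
        axes += np.outer(tremor, params.orientation[::-1])

    trace = AccelTrace(
        time=np.arange(n_samples) / fs,
        ax=axes[:, 0],
        ay=axes[:, 1],
        az=axes[:, 2],
        sampling_rate_hz=fs,
        meta={},
    )
    half_s = half / fs
    truth = GroundTruthEvents(
        onset_s=peak_idx / fs - half_s,
        peak_s=peak_idx / fs,
        offset_s=peak_idx / fs + half_s,
        amplitude=amplitudes,
    )
    return trace, truth


def snr_db(params: BlockSimParams) -> float:
    """Power signal-to-noise ratio of a block in dB.

    Signal power is the time-averaged squared burst waveform summed over
    axes (rendered noiseless); noise power is the summed per-axis white
    noise variance, 3 * noise_sd^2.
    """
    if params.noise_sd == 0:
        return np.inf
    clean = replace(
        params, noise_sd=0.0, drift_amplitude=0.0, tremor_amplitude=0.0
    )
    trace, _ = simulate_block(clean)
    p_signal = float(np.mean(trace.ax**2 + trace.ay**2 + trace.az**2))
    return 10.0 * np.log10(p_signal / (3.0 * params.noise_sd**2))


def noise_sd_for_snr(params: BlockSimParams, target_db: float) -> float:
    """Per-axis noise SD that puts the block at the target power SNR."""
    clean = replace(
        params, noise_sd=0.0, drift_amplitude=0.0, tremor_amplitude=0.0
    )
    trace, _ = simulate_block(clean)
    p_signal = float(np.mean(trace.ax**2 + trace.ay**2 + trace.az**2))
    return float(np.sqrt(p_signal / (3.0 * 10.0 ** (target_db / 10.0))))


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """Log-normal draws with the requested arithmetic mean and CV."""
    if n <= 0:
        return np.zeros(0)
    if cv == 0:
        return np.full(n, mean)
    sigma2 = np.log(1.0 + cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def _lognormal_unit(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    return _lognormal(rng, 1.0, cv, n)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

# Latent clinical burden added by each therapy state (OFF/OFF worst),
# calibrated so cohort-level UPDRS means decrease from OFF/OFF to ON/ON.
_STATE_BURDEN: dict[tuple[str, str], float] = {
    ("OFF", "OFF"): 1.1,
    ("ON", "OFF"): 0.45,
    ("OFF", "ON"): 0.25,
    ("ON", "ON"): -0.55,
}

# Ordinal cut points mapping latent item propensity to 0-4 scores.
_ITEM_CUTS = np.array([0.25, 1.0, 1.75, 2.6])

_BRADY_ITEMS = ("3.4", "3.5", "3.6", "3.7", "3.8")
_TREMOR_ITEMS = ("3.15", "3.16", "3.17", "3.18")


@dataclass
class SyntheticSubject:
    subject_id: str
    latent_severity: float
    laterality_offset: float
    # keyed by (med_state, stim_state, movement_type)
    blocks: dict = field(default_factory=dict)
    truths: dict = field(default_factory=dict)
    block_params: dict = field(default_factory=dict)
    # keyed by (med_state, stim_state) -> clinical record dict
    clinical: dict = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    subjects: list
    effects: dict
    rng_seed: int
    baseline: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def iter_blocks(self):
        """Yield (subject, med, stim, movement_type, trace, truth)."""
        for subj in self.subjects:
            for (med, stim, mtype), trace in subj.blocks.items():
                yield subj, med, stim, mtype, trace, subj.truths[(med, stim, mtype)]


def simulate_cohort(
    n_subjects: int = 20,
    effects: dict | None = None,
    rng_seed: int = 0,
    base_params: dict | None = None,
    severity_sd: float = 1.0,
    severity_amplitude_coupling: float = 0.18,
    severity_cv_coupling: float = 0.25,
    item_noise_sd: float = 0.45,
    laterality_sd: float = 0.35,
    movement_types: tuple = ("finger_tapping", "pronation_supination"),
) -> SyntheticCohort:
    """Simulate a cohort tested in all four med x stim therapy states.

    Each subject gets one block per therapy state and movement type plus
    one clinical record per therapy state. Subject severity is a standard
    normal latent scaled by ``severity_sd``; it worsens kinematics
    (smaller, more variable movements) and raises ordinal UPDRS items
    through fixed cut points. ``laterality_offset`` shifts left-side items
    relative to right-side ones.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    effects = dict(DEFAULT_EFFECTS) if effects is None else dict(effects)
    missing = [s for s in THERAPY_STATES if s not in effects]
    if missing:
        raise ValueError(f"missing effect multipliers for state(s): {missing}")

    base = {
        "finger_tapping": dict(movement_rate_hz=4.0, burst_width_ms=120.0),
        "pronation_supination": dict(movement_rate_hz=2.0, burst_width_ms=250.0),
    }
    if base_params:
        for mtype, overrides in base_params.items():
            base.setdefault(mtype, {}).update(overrides)

    rng = np.random.default_rng(rng_seed)
    subjects = []
    for i in range(n_subjects):
        severity = float(rng.normal(0.0, severity_sd))
        laterality = float(rng.normal(0.0, laterality_sd))
        subj = SyntheticSubject(
            subject_id=f"S{i + 1:02d}",
            latent_severity=severity,
            laterality_offset=laterality,
        )
        for med, stim in THERAPY_STATES:
            mult = effects[(med, stim)]
            for mtype in movement_types:
                p = BlockSimParams(
                    rng_seed=int(rng.integers(0, 2**31 - 1)),
                    **base[mtype],
                )
                amp = (
                    p.burst_amplitude
                    * mult.amplitude_gain
                    * float(np.exp(-severity_amplitude_coupling * severity))
                )
                cv_scale = mult.variability_gain * float(
                    np.exp(severity_cv_coupling * severity)
                )
                p = replace(
                    p,
                    burst_amplitude=amp,
                    movement_rate_hz=p.movement_rate_hz / mult.interval_gain,
                    amplitude_cv=min(p.amplitude_cv * cv_scale, 0.8),
                    interval_cv=min(p.interval_cv * cv_scale, 0.8),
                    burst_width_ms=p.burst_width_ms / mult.smoothness_gain,
                )
                trace, truth = simulate_block(p)
                trace.meta.update(
                    subject_id=subj.subject_id,
                    movement_type=mtype,
                    med_state=med,
                    stim_state=stim,
                    hand="right",
                )
                key = (med, stim, mtype)
                subj.blocks[key] = trace
                subj.truths[key] = truth
                subj.block_params[key] = p
            subj.clinical[(med, stim)] = _clinical_record(
                rng, subj, med, stim, item_noise_sd
            )
        subjects.append(subj)
    return SyntheticCohort(
        subjects=subjects,
        effects=effects,
        rng_seed=rng_seed,
        baseline=base,
    )


def _ordinal(latent: float) -> int:
    return int(np.searchsorted(_ITEM_CUTS, latent))


def _clinical_record(
    rng: np.random.Generator,
    subj: SyntheticSubject,
    med: str,
    stim: str,
    item_noise_sd: float,
) -> dict:
    """Threshold the latent severity into 0-4 ordinal UPDRS items."""
    burden = subj.latent_severity + _STATE_BURDEN[(med, stim)]
    items: dict = {}
    for item in _BRADY_ITEMS:
        right = burden - subj.laterality_offset + rng.normal(0, item_noise_sd)
        left = burden + subj.laterality_offset + rng.normal(0, item_noise_sd)
        items[item] = {"right": _ordinal(right), "left": _ordinal(left)}
    # global bradykinesia and tremor items are scalars (not lateralized)
    items["3.14"] = _ordinal(burden + rng.normal(0, item_noise_sd))
    for item in _TREMOR_ITEMS:
        items[item] = _ordinal(burden - 1.0 + rng.normal(0, item_noise_sd))
    modeled = sum(
        v["right"] + v["left"] if isinstance(v, dict) else v for v in items.values()
    )
    other = int(np.clip(round(8 + 5 * burden + rng.normal(0, 2.0)), 0, 60))
    return {
        "subject_id": subj.subject_id,
        "med_state": med,
        "stim_state": stim,
        "items": items,
        "updrs3_total": int(min(modeled + other, 132)),
    }
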