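"""Single-trial and block-level kinematic features.

Per event: duration-normalized acceleration magnitude (mean |a| over the
onset-offset window, m/s^2), mean absolute jerk (m/s^3) and duration.
Per block: means and coefficients of variation of event magnitude,
inter-movement interval and jerk, plus standardized decrement slopes of
magnitude and interval over trial number estimated with random-slope
mixed models across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import EventSet, MovementEvent
from .signal_io import ScalarSeries

__all__ = [
    "EventFeatures",
    "BlockFeatures",
    "BLOCK_FEATURE_NAMES",
    "event_features",
    "inter_movement_intervals",
    "coefficient_of_variation",
    "block_features",
    "event_feature_table",
    "kinematic_slopes",
]

BLOCK_FEATURE_NAMES = (
    "accel_mean",
    "accel_cv",
    "imi_mean",
    "imi_cv",
    "jerk_mean",
    "jerk_cv",
    "accel_slope",
    "imi_slope",
)


@dataclass(frozen=True)
class EventFeatures:
    norm_accel_magnitude: float  # mean |a| over the event window, m/s^2
    jerk_mean: float  # mean |jerk| over the event window, m/s^3
    duration_ms: float
    event_index: int

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be > 0")
        if self.norm_accel_magnitude < 0:
            raise ValueError("norm_accel_magnitude must be >= 0")


@dataclass
class BlockFeatures:
    accel_mean: float
    accel_cv: float
    imi_mean: float
    imi_cv: float
    jerk_mean: float
    jerk_cv: float
    accel_slope: float = np.nan
    imi_slope: float = np.nan
    n_events: int = 0

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in BLOCK_FEATURE_NAMES} | {
            "n_events": self.n_events
        }


def event_features(
    mag: ScalarSeries, jerk: ScalarSeries, event: MovementEvent
) -> EventFeatures:
    """Features of one confirmed movement event.

    The "normalized" magnitude is the time integral of |a| over the event
    divided by its duration, i.e. the window mean, keeping m/s^2 units.
    """
    fs = mag.sampling_rate_hz
    lo = max(int(np.ceil(event.onset_s * fs)), 0)
    hi = min(int(np.floor(event.offset_s * fs)), mag.values.size - 1)
    if hi < lo:
        raise ValueError("event window contains no samples")
    window = slice(lo, hi + 1)
    return EventFeatures(
        norm_accel_magnitude=float(np.mean(mag.values[window])),
        jerk_mean=float(np.mean(np.abs(jerk.values[window]))),
        duration_ms=(event.offset_s - event.onset_s) * 1e3,
        event_index=event.event_index,
    )


def inter_movement_intervals(events: EventSet) -> np.ndarray:
    """Successive peak-to-peak distances in ms (length n_events - 1)."""
    peaks = events.peak_times()
    if peaks.size < 2:
        warnings.warn("fewer than 2 events: no intervals", stacklevel=2)
        return np.zeros(0)
    return np.diff(peaks) * 1e3


def coefficient_of_variation(x: np.ndarray) -> float:
    """100 * sample SD (n-1 denominator) / mean."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("CV requires at least 2 values")
    mean = float(np.mean(x))
    if mean == 0:
        raise ZeroDivisionError("CV undefined for zero-mean series")
    return 100.0 * float(np.std(x, ddof=1)) / mean


def block_features(
    events_features: list[EventFeatures], imis: np.ndarray
) -> BlockFeatures:
    """Means and CVs across a block; slope fields are filled later."""
    if len(events_features) < 2:
        raise ValueError("block features require at least 2 events")
    amp = np.array([f.norm_accel_magnitude for f in events_features])
    jrk = np.array([f.jerk_mean for f in events_features])
    imis = np.asarray(imis, dtype=float)
    return BlockFeatures(
        accel_mean=float(np.mean(amp)),
        accel_cv=coefficient_of_variation(amp),
        imi_mean=float(np.mean(imis)) if imis.size else np.nan,
        imi_cv=coefficient_of_variation(imis) if imis.size >= 2 else np.nan,
        jerk_mean=float(np.mean(jrk)),
        jerk_cv=coefficient_of_variation(jrk),
        n_events=len(events_features),
    )


def event_feature_table(
    records: list[dict],
) -> pd.DataFrame:
    """Long-format single-trial feature table.

    ``records`` holds dicts with keys subject, med_state, stim_state,
    movement_type, event_index, norm_accel_magnitude, jerk_mean, imi_ms
    (NaN for the first event of a block).
    """
    df = pd.DataFrame.from_records(records)
    key = ["subject", "med_state", "stim_state", "movement_type", "event_index"]
    if df.duplicated(key).any():
        raise ValueError("duplicate (subject, state, movement, event) keys")
    return df


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1)
    return (x - np.mean(x)) / sd if sd > 0 else np.zeros_like(x)


def kinematic_slopes(
    table: pd.DataFrame,
    feature: str,
    group_cols: tuple = ("med_state", "stim_state", "movement_type"),
) -> pd.DataFrame:
    """Per-subject standardized decrement slopes over trial number.

    Within each grouping (therapy state x movement type), the z-scored
    feature is regressed on the z-scored trial index in a mixed model with
    a random intercept and random slope per subject; each subject's slope
    is the fixed slope plus their conditional (shrunken) slope deviation.
    Singular or single-subject fits fall back to per-subject OLS slopes,
    flagged in the ``method`` column.
    """
    import statsmodels.api as sm

    if feature not in table.columns:
        raise KeyError(f"unknown feature column '{feature}'")
    out = []
    for keys, grp in table.groupby(list(group_cols), sort=True):
        grp = grp.dropna(subset=[feature])
        y = _zscore(grp[feature].to_numpy(dtype=float))
        t = _zscore(grp["event_index"].to_numpy(dtype=float))
        subjects = grp["subject"].to_numpy()
        slopes, method = _fit_random_slope(y, t, subjects)
        for subj, slope in slopes.items():
            row = dict(zip(group_cols, keys))
            row.update(subject=subj, feature=feature, slope=slope, method=method)
            out.append(row)
    return pd.DataFrame(out)


def _fit_random_slope(
    y: np.ndarray, t: np.ndarray, subjects: np.ndarray
) -> tuple[dict, str]:
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    unique = np.unique(subjects)
    if unique.size < 2 or np.std(t) == 0:
        return _ols_slopes(y, t, subjects), "ols"
    exog = np.column_stack([np.ones_like(t), t])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            model = sm.MixedLM(y, exog, groups=subjects, exog_re=exog)
            res = model.fit(reml=True, method="lbfgs")
        if not np.all(np.isfinite(res.params)):
            raise np.linalg.LinAlgError("non-finite mixed-model fit")
        fixed_slope = res.fe_params[1]
        slopes = {}
        for subj in unique:
            re = res.random_effects[subj]
            slopes[subj] = float(fixed_slope + re.iloc[1])
        return slopes, "lmm"
    except (np.linalg.LinAlgError, ValueError):
        return _ols_slopes(y, t, subjects), "ols"


def _ols_slopes(y: np.ndarray, t: np.ndarray, subjects: np.ndarray) -> dict:
    slopes = {}
    for subj in np.unique(subjects):
        sel = subjects == subj
        ts, ys = t[sel], y[sel]
        denom = np.sum((ts - ts.mean()) ** 2)
        slopes[subj] = (
            float(np.sum((ts - ts.mean()) * (ys - ys.mean())) / denom)
            if denom > 0
            else 0.0
        )
    return slopes
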