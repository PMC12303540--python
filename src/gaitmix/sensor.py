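"""Accelerometer-derived gait parameters.

A ~30 s walk recorded at the lower back (L3) is summarised by five
parameters: step frequency (cadence), acceleration RMS (gait
intensity), step variability (coefficient of variation of step
intervals), and the autocorrelation-based step regularity and step
symmetry.

Regularity and symmetry follow the unbiased-autocorrelation approach
for trunk accelerometry: the autocorrelation coefficient at the
one-step lag (``Ad1``) measures how repeatable consecutive steps are,
the one-stride lag (``Ad2``) how repeatable whole strides are, and the
ratio ``min(Ad1, Ad2) / max(Ad1, Ad2)`` quantifies left/right symmetry
on a [0, 1] scale.  The raw recording is first resampled to a uniform
grid (default 100 Hz) by linear interpolation because the phone's
sampling gaps are irregular.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .errors import (
    DegenerateInputError,
    GaitmixError,
    InconsistentEventsError,
    InsufficientStepsError,
    NoPeriodicityError,
    ParameterError,
    StageError,
)
from .types import AccelerometerRecording, GaitFeatures, SensorQC, UniformSignal


@dataclass(frozen=True)
class SensorConfig:
    """Extraction constants for the sensor pipeline.

    The peak-detection constants target the physiological cadence band
    of roughly 1-3 steps/s: a 10 Hz low-pass keeps the step impulses
    while rejecting jolt noise, the 0.25 s refractory period caps
    detections at 4 steps/s, and the prominence floor is expressed
    relative to the signal RMS so it adapts to gait intensity.
    """

    resample_rate: float = 100.0  # Hz
    lowpass_cutoff_hz: float = 10.0
    min_step_separation_s: float = 0.25
    prominence_rel: float = 0.3  # x RMS of the filtered signal
    acf_max_lag_periods: float = 4.8  # autocorrelation span, in step periods
    regularity_metric: str = "ad1"  # one of {"ad1", "ad2", "mean"}


DEFAULT_SENSOR_CONFIG = SensorConfig()


@dataclass(frozen=True)
class ResampledRecording:
    """All three channels of a recording on a shared uniform grid."""

    rate: float
    origin: float
    samples: np.ndarray  # (n, 3)
    axis_labels: tuple[str, str, str]


@dataclass(frozen=True)
class Autocorrelation:
    """Unbiased normalized autocorrelation, one coefficient per lag."""

    rate: float
    coef: np.ndarray  # coef[k] is the coefficient at lag k / rate seconds

    def lags(self) -> np.ndarray:
        return np.arange(self.coef.size) / self.rate


def resample_uniform(
    rec: AccelerometerRecording, target_rate: float = 100.0
) -> ResampledRecording:
    """Resample an irregular recording to a uniform grid.

    Linear interpolation between recorded samples; the grid runs from
    the first to the last timestamp inclusive, so no extrapolation
    occurs.
    """
    if target_rate <= 0:
        raise ParameterError("target_rate must be positive")
    t = rec.timestamps
    n = int(math.floor((t[-1] - t[0]) * target_rate)) + 1
    grid = t[0] + np.arange(n) / target_rate
    out = np.column_stack(
        [np.interp(grid, t, rec.acceleration[:, j]) for j in range(3)]
    )
    return ResampledRecording(
        rate=target_rate, origin=float(t[0]), samples=out, axis_labels=rec.axis_labels
    )


def vertical_component(res: ResampledRecording) -> tuple[UniformSignal, str]:
    """Select the gravity-dominant channel and remove its mean.

    With the phone at the waist, the axis whose mean absolute value is
    largest carries gravity and is taken as vertical.  Removing the
    mean strips gravity, leaving the dynamic vertical acceleration.
    Returns the zero-mean signal and the selected axis label.
    """
    mags = np.mean(np.abs(res.samples), axis=0)
    if np.all(mags == 0):
        raise DegenerateInputError("all channels are identically zero")
    j = int(np.argmax(mags))
    x = res.samples[:, j] - res.samples[:, j].mean()
    return (
        UniformSignal(rate=res.rate, samples=x, origin=res.origin),
        res.axis_labels[j],
    )


def acceleration_rms(signal: UniformSignal) -> float:
    """Root mean square of the (zero-mean) vertical acceleration, m/s^2."""
    if signal.samples.size == 0:
        raise DegenerateInputError("empty signal")
    return float(np.sqrt(np.mean(signal.samples**2)))


def detect_steps(
    signal: UniformSignal, config: SensorConfig = DEFAULT_SENSOR_CONFIG
) -> np.ndarray:
    """Detect step events as prominent peaks of the low-passed signal.

    Returns ordered event times in seconds.  Raises
    :class:`InsufficientStepsError` when fewer than 3 events are found.
    """
    x = signal.samples
    if x.size < 8:
        raise DegenerateInputError("signal too short for step detection")
    sos = butter(4, config.lowpass_cutoff_hz, btype="low", fs=signal.rate, output="sos")
    filt = sosfiltfilt(sos, x)
    rms = float(np.sqrt(np.mean(filt**2)))
    if rms == 0:
        raise DegenerateInputError("zero-variance signal")
    distance = max(1, int(round(config.min_step_separation_s * signal.rate)))
    # positive peaks only: step impulses rise above the zero-mean baseline
    peaks, _ = find_peaks(
        filt, height=0.0, prominence=config.prominence_rel * rms, distance=distance
    )
    if peaks.size < 3:
        raise InsufficientStepsError(f"only {peaks.size} step events detected")
    return signal.origin + peaks / signal.rate


def temporal_features(events: np.ndarray) -> tuple[float, float]:
    """Step frequency and step variability from ordered event times.

    Frequency is the reciprocal of the mean step interval; variability
    is the coefficient of variation of the intervals (sample SD / mean),
    which is scale-invariant across cadences.
    """
    events = np.asarray(events, dtype=float)
    if events.size < 3:
        raise InsufficientStepsError("need at least 3 events")
    intervals = np.diff(events)
    if np.any(intervals <= 0):
        raise InconsistentEventsError("event times must be strictly increasing")
    mean = float(intervals.mean())
    sd = float(intervals.std(ddof=1))
    return 1.0 / mean, sd / mean


def autocorr_unbiased(signal: UniformSignal, max_lag: float) -> Autocorrelation:
    """Unbiased normalized autocorrelation up to ``max_lag`` seconds.

    At lag ``k`` samples the estimator sums products over the ``N - k``
    overlapping pairs and divides by ``N - k`` (hence *unbiased*), then
    normalizes by the lag-0 variance so the coefficient at lag 0 is
    exactly 1.
    """
    x = signal.samples - signal.samples.mean()
    n = x.size
    if n < 2:
        raise DegenerateInputError("need at least 2 samples")
    if max_lag <= 0 or max_lag >= signal.span / 2:
        raise ParameterError("max_lag must lie in (0, span/2)")
    var = float(np.mean(x**2))
    if var == 0:
        raise DegenerateInputError("zero-variance signal")
    k_max = int(round(max_lag * signal.rate))
    full = np.correlate(x, x, mode="full")[n - 1 : n + k_max]
    r = full / (n - np.arange(k_max + 1))
    return Autocorrelation(rate=signal.rate, coef=r / r[0])


def _window_peak(
    acf: Autocorrelation, lo_s: float, hi_s: float
) -> tuple[float, int]:
    """Highest local maximum of the autocorrelation within [lo_s, hi_s]."""
    lo = max(1, int(math.floor(lo_s * acf.rate)))
    hi = min(acf.coef.size - 2, int(math.ceil(hi_s * acf.rate)))
    if hi <= lo:
        raise NoPeriodicityError(
            f"lag window [{lo_s:.3f}, {hi_s:.3f}] s exceeds the autocorrelation span"
        )
    seg = acf.coef[lo - 1 : hi + 2]
    peaks, _ = find_peaks(seg)
    if peaks.size == 0:
        raise NoPeriodicityError(
            f"no autocorrelation peak in [{lo_s:.3f}, {hi_s:.3f}] s"
        )
    vals = seg[peaks]
    best = int(peaks[np.argmax(vals)])
    return float(seg[best]), lo - 1 + best


def _regularity_symmetry_full(
    acf: Autocorrelation, expected_step_period: float, metric: str
) -> tuple[float, float, int, int]:
    if expected_step_period <= 0:
        raise ParameterError("expected_step_period must be positive")
    ad1, l1 = _window_peak(acf, 0.5 * expected_step_period, 1.5 * expected_step_period)
    # stride window centred on twice the found step lag, kept clear of the
    # one-step peak (at 0.5x) and the three-step peak (at 1.5x)
    stride = 2 * l1 / acf.rate
    ad2, l2 = _window_peak(acf, 0.625 * stride, 1.375 * stride)
    if metric == "ad1":
        regularity = ad1
    elif metric == "ad2":
        regularity = ad2
    elif metric == "mean":
        regularity = 0.5 * (ad1 + ad2)
    else:
        raise ParameterError(f"unknown regularity metric {metric!r}")
    if ad1 > 0 and ad2 > 0:
        symmetry = min(ad1, ad2) / max(ad1, ad2)
        symmetry = float(np.clip(symmetry, 0.0, 1.0))
    else:
        symmetry = 0.0
    return float(regularity), symmetry, l1, l2


def regularity_symmetry(
    acf: Autocorrelation,
    expected_step_period: float,
    metric: str = "ad1",
) -> tuple[float, float]:
    """Step regularity and symmetry from the autocorrelation.

    ``Ad1`` is the highest peak in the one-step lag window
    [0.5, 1.5] x step period; ``Ad2`` the highest peak in the
    one-stride window [0.5, 1.5] x (2 x lag(Ad1)).  Regularity is
    ``Ad1`` by default (``metric`` may select ``Ad2`` or their mean);
    symmetry is ``min/max`` of the two peaks, clamped to [0, 1] and 0
    when either peak is non-positive.
    """
    reg, sym, _, _ = _regularity_symmetry_full(acf, expected_step_period, metric)
    return reg, sym


@dataclass(frozen=True)
class SensorResult:
    features: GaitFeatures
    qc: SensorQC


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except StageError:
        raise
    except GaitmixError as exc:
        raise StageError(name, exc) from exc


def extract_sensor_features(
    rec: AccelerometerRecording, config: SensorConfig = DEFAULT_SENSOR_CONFIG
) -> SensorResult:
    """Run the full sensor pipeline on one recording.

    resample -> vertical axis -> RMS; step detection -> temporal
    features; unbiased autocorrelation -> regularity/symmetry.  Stage
    failures are re-raised as :class:`StageError` carrying the stage
    name.
    """
    if rec.span < 10.0:
        raise DegenerateInputError(
            f"recording spans {rec.span:.1f} s; need at least 10 s"
        )
    res = _stage("resample", resample_uniform, rec, config.resample_rate)
    vert, axis = _stage("vertical", vertical_component, res)
    rms = _stage("rms", acceleration_rms, vert)
    events = _stage("detect_steps", detect_steps, vert, config)
    freq, variability = _stage("temporal", temporal_features, events)
    period = 1.0 / freq
    max_lag = min(config.acf_max_lag_periods * period, 0.49 * vert.span)
    acf = _stage("autocorr", autocorr_unbiased, vert, max_lag)
    regularity, symmetry, l1, l2 = _stage(
        "regularity", _regularity_symmetry_full, acf, period, config.regularity_metric
    )
    features = GaitFeatures(
        step_frequency=freq,
        rms=rms,
        step_variability=variability,
        step_regularity=regularity,
        step_symmetry=symmetry,
    )
    qc = SensorQC(
        step_count=int(events.size),
        vertical_axis=axis,
        ad1_lag_s=l1 / acf.rate,
        ad2_lag_s=l2 / acf.rate,
        resample_rate=config.resample_rate,
    )
    return SensorResult(features=features, qc=qc)
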