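"""GSR and PPG feature extraction.

GSR chain: decimate to 16 Hz -> 0.2 Hz 3rd-order Butterworth zero-phase
low-pass -> linear detrend -> first difference -> 20-point Bartlett
smoothing -> z-score.  Skin conductance responses (SCRs) are the positive
lobes of the result between a negative-to-positive and the following
positive-to-negative zero crossing; the feature stream is the mean SCR peak
amplitude inside a 6-s moving window.

PPG chain: 0.5-5 Hz 3rd-order Butterworth zero-phase band-pass -> first
difference -> 20-point Bartlett smoothing -> z-score.  Pulse peaks give
peak-to-peak intervals (PPIs) and hence an instantaneous heart-rate series,
HR = 60 / PPI beats per minute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core_io import ConfigurationError, FeatureSeries, Recording

__all__ = [
    "SCREvent",
    "PulseTrain",
    "gsr_preprocess",
    "detect_scrs",
    "scr_feature_series",
    "ppg_preprocess",
    "detect_pulses",
    "hr_series",
]

GSR_RATE_HZ = 16.0
GSR_LOWPASS_HZ = 0.2
SMOOTH_POINTS = 20  # Bartlett window length for both chains
SCR_WINDOW_S = 6.0
PPG_BAND_HZ = (0.5, 5.0)
PULSE_REFRACTORY_S = 0.33  # caps detection at ~180 bpm


@dataclass(frozen=True)
class SCREvent:
    """One skin conductance response in the preprocessed (z-scored) signal."""

    onset: float
    offset: float
    peak_time: float
    peak_value: float

    def __post_init__(self) -> None:
        if not self.onset < self.peak_time < self.offset:
            raise ConfigurationError("SCR peak must lie strictly inside the event")


@dataclass
class PulseTrain:
    """Detected pulse peak times and the intervals between them."""

    peak_times: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        if np.any(np.diff(self.peak_times) <= 0):
            raise ConfigurationError("pulse peak times must be strictly increasing")

    @property
    def ppis(self) -> np.ndarray:
        return np.diff(self.peak_times)


def _single_channel(recording: Recording, role: str) -> tuple[np.ndarray, float]:
    idx = recording.channels_with_role(role)
    if not idx:
        raise ConfigurationError(f"recording has no {role}-role channel")
    return recording.samples[idx[0]], recording.sampling_rate


def _bartlett_smooth(x: np.ndarray, points: int = SMOOTH_POINTS) -> np.ndarray:
    # unit-sum normalization keeps the smoother amplitude-preserving
    w = np.bartlett(points)
    return np.convolve(x, w / w.sum(), mode="same")


def _decimate_to(x: np.ndarray, fs: float, target: float) -> np.ndarray:
    factor = fs / target
    if abs(factor - round(factor)) > 1e-9:
        raise ConfigurationError(f"cannot decimate {fs} Hz to {target} Hz by an integer factor")
    remaining = int(round(factor))
    while remaining > 1:
        q = min(remaining, 8)
        while remaining % q:
            q -= 1
        x = signal.decimate(x, q, zero_phase=True)
        remaining //= q
    return x


GSR_EDGE_TRIM_S = 10.0  # settle margin of the 0.2 Hz zero-phase filter
PPG_EDGE_TRIM_S = 4.0


def _zscore_or_flat(x: np.ndarray, reference_scale: float) -> np.ndarray:
    """Z-score, or all-zeros when the signal is numerically constant.

    After detrending and differentiation a drift-only channel is exactly
    zero in ideal arithmetic; what survives is filter round-off.  Blowing
    that up to unit variance would fabricate structure, so signals whose
    spread is negligible against the pre-difference scale come back flat.
    """
    sd = np.std(x)
    if sd <= 1e-5 * max(reference_scale, 1e-30):
        return np.zeros_like(x)
    return (x - np.mean(x)) / sd


def gsr_preprocess(recording: Recording, edge_trim: float = GSR_EDGE_TRIM_S) -> FeatureSeries:
    """Preprocessed skin-conductance slope signal at 16 Hz, z-scored.

    ``edge_trim`` seconds at each end, contaminated by the zero-phase
    filters' settle transients, are discarded before normalization.
    """
    x, fs = _single_channel(recording, "GSR")
    if fs > GSR_RATE_HZ:
        x = _decimate_to(x, fs, GSR_RATE_HZ)
        fs = GSR_RATE_HZ
    sos = signal.butter(3, GSR_LOWPASS_HZ, btype="lowpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x)
    scale = np.std(x - np.mean(x))  # pre-detrend spread, incl. tonic drift
    x = signal.detrend(x, type="linear")
    x = np.diff(x)
    x = _bartlett_smooth(x)
    trim = int(round(edge_trim * fs))
    if len(x) <= 2 * trim:
        raise ConfigurationError("recording too short for the GSR edge-trim margin")
    x = x[trim:len(x) - trim]
    x = _zscore_or_flat(x, scale)
    # first difference lives between samples: stamp at inter-sample midpoints
    times = recording.t0 + (trim + np.arange(len(x)) + 0.5) / fs
    return FeatureSeries(
        name="gsr_slope", units="z", times=times, values=x,
        subject_id=recording.subject_id,
    )


SCR_MIN_AMPLITUDE_Z = 0.1


def detect_scrs(
    series: FeatureSeries, min_amplitude: float = SCR_MIN_AMPLITUDE_Z
) -> list[SCREvent]:
    """SCRs as maximal positive lobes between consecutive zero crossings.

    Crossing times are linearly interpolated between samples; the peak is
    the maximum sample inside the lobe.  Lobes truncated by the record's
    edges are discarded (their true extent is unknown), and lobes whose
    peak is below ``min_amplitude`` are ignored — the z-scale analog of the
    minimum-amplitude criterion conventional in electrodermal response
    counting, without which the zero-phase low-pass filter's own ripple
    around every response would register as extra responses.
    """
    t, v = series.times, series.values
    events: list[SCREvent] = []
    sign = v > 0
    # rising edge at i: v[i] <= 0 < v[i+1]
    rising = np.flatnonzero(~sign[:-1] & sign[1:])
    falling = np.flatnonzero(sign[:-1] & ~sign[1:])
    for r in rising:
        f_candidates = falling[falling > r]
        if not f_candidates.size:
            break
        f = f_candidates[0]

        def cross(i: int) -> float:
            v0, v1 = v[i], v[i + 1]
            if v1 == v0:
                return float(t[i])
            return float(t[i] + (t[i + 1] - t[i]) * (0.0 - v0) / (v1 - v0))

        onset, offset = cross(r), cross(f)
        lobe = slice(r + 1, f + 1)
        k = int(np.argmax(v[lobe])) + r + 1
        if v[k] >= min_amplitude:
            events.append(
                SCREvent(onset=onset, offset=offset, peak_time=float(t[k]),
                         peak_value=float(v[k]))
            )
    return events


def scr_feature_series(
    series: FeatureSeries, events: list[SCREvent], window: float = SCR_WINDOW_S
) -> FeatureSeries:
    """Mean SCR peak amplitude in a moving window, hopped one sample at a time.

    Windows are centered on each sample of the preprocessed series; a window
    with no SCR peak contributes 0 (the grand-average waveform must be
    defined everywhere).
    """
    t = series.times
    peaks_t = np.array([e.peak_time for e in events])
    peaks_v = np.array([e.peak_value for e in events])
    values = np.zeros(len(t))
    if peaks_t.size:
        half = window / 2.0
        for i, tc in enumerate(t):
            inside = (peaks_t >= tc - half) & (peaks_t <= tc + half)
            if np.any(inside):
                values[i] = float(np.mean(peaks_v[inside]))
    return FeatureSeries(
        name="scr_feature", units="z", times=t, values=values,
        subject_id=series.subject_id,
    )


def ppg_preprocess(recording: Recording, edge_trim: float = PPG_EDGE_TRIM_S) -> FeatureSeries:
    """Preprocessed pulse-slope signal at the native rate, z-scored.

    ``edge_trim`` seconds at each end are discarded (0.5 Hz high-pass
    settle).
    """
    x, fs = _single_channel(recording, "PPG")
    sos = signal.butter(3, PPG_BAND_HZ, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, x)
    scale = np.std(x)
    x = np.diff(x)
    x = _bartlett_smooth(x)
    trim = int(round(edge_trim * fs))
    if len(x) <= 2 * trim:
        raise ConfigurationError("recording too short for the PPG edge-trim margin")
    x = x[trim:len(x) - trim]
    if np.std(x) == 0:
        raise ConfigurationError("PPG channel is constant after preprocessing")
    x = _zscore_or_flat(x, scale)
    times = recording.t0 + (trim + np.arange(len(x)) + 0.5) / fs
    return FeatureSeries(
        name="ppg_slope", units="z", times=times, values=x,
        subject_id=recording.subject_id,
    )


def detect_pulses(series: FeatureSeries) -> PulseTrain:
    """Pulse peaks: local maxima above an adaptive threshold.

    Threshold is half the 95th percentile of the series, with a 0.33-s
    refractory separation; ties on flat peaks break to the earlier sample.
    """
    v, t = series.values, series.times
    fs = 1.0 / series.dt
    height = 0.5 * np.percentile(v, 95)
    idx, props = signal.find_peaks(
        v, height=height, distance=max(1, int(round(PULSE_REFRACTORY_S * fs))),
        plateau_size=1,
    )
    # find_peaks reports plateau midpoints; the tie rule wants the earlier edge
    idx = props["left_edges"]
    if len(idx) < 2:
        raise ConfigurationError(
            f"only {len(idx)} pulse peak(s) found; cannot form a peak-to-peak interval"
        )
    return PulseTrain(peak_times=t[idx])


def hr_series(
    train: PulseTrain,
    grid_step: float = 1.0,
    t_start: float | None = None,
    t_end: float | None = None,
    subject_id: str = "subject",
) -> FeatureSeries:
    """Heart rate in bpm on a uniform grid.

    Each interval contributes HR = 60 / PPI at its midpoint; midpoint values
    are linearly interpolated onto the grid (edges hold the nearest value).
    """
    ppis = train.ppis
    if not np.all(ppis > 0):
        raise ConfigurationError("peak-to-peak intervals must be positive")
    mids = (train.peak_times[:-1] + train.peak_times[1:]) / 2.0
    hr = 60.0 / ppis
    lo = train.peak_times[0] if t_start is None else t_start
    hi = train.peak_times[-1] if t_end is None else t_end
    n = int(np.floor((hi - lo) / grid_step)) + 1
    grid = lo + np.arange(n) * grid_step
    values = np.interp(grid, mids, hr)
    return FeatureSeries(
        name="heart_rate", units="bpm", times=grid, values=values,
        subject_id=subject_id,
    )


def subject_hr_series(recording: Recording, grid_step: float = 1.0) -> FeatureSeries:
    """Full PPG chain: preprocess -> pulse detection -> HR on a uniform grid."""
    pre = ppg_preprocess(recording)
    train = detect_pulses(pre)
    return hr_series(
        train, grid_step=grid_step, t_start=recording.t0,
        t_end=recording.t0 + recording.duration, subject_id=recording.subject_id,
    )


def subject_scr_series(recording: Recording, window: float = SCR_WINDOW_S) -> FeatureSeries:
    """Full GSR chain: preprocess -> SCR detection -> windowed feature."""
    pre = gsr_preprocess(recording)
    events = detect_scrs(pre)
    return scr_feature_series(pre, events, window=window)
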