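"""Synthetic multimodal group recordings with known emotional-highlight structure.

Every downstream stage of the pipeline is exercised on data from this module,
so the generators encode exactly the statistical structure the analysis
assumes:

* **EEG** — each channel mixes a *shared* beta-band (14-25 Hz) source with an
  independent beta-band source, with mixing fraction ``s(t)`` that drops
  inside ``desync`` events.  High emotional arousal is modelled as reduced
  global synchronization, so planted ``desync`` events are what the GFS
  highlight detector should recover.  Eye blinks are injected on two EOG
  channels and leak into the frontal EEG channels with fixed gains.
* **GSR** — tonic drift plus one skin conductance response (difference of
  exponentials) per ``scr_burst`` event.
* **PPG** — a pulse train whose instantaneous rate follows a programmable
  heart-rate profile raised inside ``hr_rise`` events.
* **Audio** — white noise amplitude-modulated upward inside ``loud`` events.
* **Questionnaire** — respondents pick the two largest-magnitude events with
  Gaussian timing jitter.

All generators are pure functions of (script, config, seed, subject_index):
identical arguments give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core_io import ConfigurationError, GroundTruthTimeline, Recording

__all__ = [
    "StimulusEvent",
    "StimulusScript",
    "GroupConfig",
    "default_script",
    "simulate_eeg",
    "simulate_gsr",
    "simulate_ppg",
    "simulate_audio",
    "simulate_questionnaire",
    "simulate_subject",
]

EVENT_KINDS = ("desync", "scr_burst", "hr_rise", "loud")

# 10-20 labels for up to 22 scalp electrodes; generators take the first n
SCALP_LABELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz", "C4",
    "T8", "P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2", "FC1", "FC2",
]
#: EEG channels that receive leaked blink activity, with their gains
BLINK_LEAK_GAINS = {"Fp1": 0.45, "Fp2": 0.45, "F3": 0.15, "F4": 0.15}


@dataclass(frozen=True)
class StimulusEvent:
    start: float
    end: float
    kind: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ConfigurationError(f"unknown event kind {self.kind!r}")
        if not self.start < self.end:
            raise ConfigurationError("event start must precede end")
        if not 0.0 <= self.magnitude <= 1.0:
            raise ConfigurationError("event magnitude must be in [0, 1]")

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class StimulusScript:
    """Timeline of ground-truth stimulus events within one clip."""

    duration: float
    events: tuple[StimulusEvent, ...] = ()

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        ev = tuple(
            e if isinstance(e, StimulusEvent) else StimulusEvent(*e)
            for e in self.events
        )
        for e in ev:
            if e.start < 0 or e.end > self.duration:
                raise ConfigurationError(f"event {e} outside [0, {self.duration}]")
        object.__setattr__(self, "events", ev)

    def events_of_kind(self, kind: str) -> list[StimulusEvent]:
        return [e for e in self.events if e.kind == kind]


@dataclass(frozen=True)
class GroupConfig:
    """Scale and noise parameters for a simulated group."""

    n_subjects: int = 10
    n_eeg_channels: int = 12
    sampling_rate: float = 256.0
    baseline_sync: float = 0.7
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not 2 <= self.n_eeg_channels <= len(SCALP_LABELS):
            raise ConfigurationError(
                f"n_eeg_channels must be in [2, {len(SCALP_LABELS)}]"
            )
        if not 0.0 <= self.baseline_sync <= 1.0:
            raise ConfigurationError("baseline_sync must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")


def default_script(duration: float = 120.0) -> StimulusScript:
    """The default two-highlight test clip.

    Two 10-s arousal peaks (at 30-40 s and 80-90 s, magnitude 0.8) drive all
    four modalities at once — synchronization drop, SCR burst, heart-rate
    rise and loudness rise — plus one weaker mid-clip SCR-only moment so the
    questionnaire's "two largest" rule is non-trivial.  The clip length and
    event duty cycle (~17%) mirror a scene-length highlight in a short movie
    clip: a highlight must occupy a minority of the record, because the
    threshold lines sit at a multiple of the waveform's own temporal
    standard deviation and excursions that fill the record would dilute
    themselves.  Ten-second events pass the ten-point (10-s) moving-average
    smoother at full depth.
    """
    if duration < 100.0:
        raise ConfigurationError("default script needs >= 100 s for its event layout")
    ev = [
        (30.0, 40.0, "desync", 0.8),
        (30.0, 40.0, "scr_burst", 0.8),
        (30.0, 40.0, "hr_rise", 0.8),
        (30.0, 40.0, "loud", 0.8),
        (80.0, 90.0, "desync", 0.8),
        (80.0, 90.0, "scr_burst", 0.8),
        (80.0, 90.0, "hr_rise", 0.8),
        (80.0, 90.0, "loud", 0.8),
        (57.0, 60.0, "scr_burst", 0.3),
    ]
    return StimulusScript(duration=duration, events=tuple(StimulusEvent(*e) for e in ev))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _rng(config_seed: int, subject_index: int, stream: int) -> np.random.Generator:
    """Deterministic per-(seed, subject, stream) generator."""
    return np.random.default_rng([config_seed & 0x7FFFFFFF, subject_index, stream])


def _beta_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance narrowband noise in the beta band (14-25 Hz)."""
    sos = signal.butter(4, [14.0, 25.0], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n + int(2 * fs)))[int(2 * fs):]
    sd = np.std(x)
    return x / sd if sd > 0 else x


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    sd = np.std(x)
    return x / sd if sd > 0 else x


def _blink_waveform(fs: float) -> np.ndarray:
    """A smooth biphasic blink transient of ~0.3 s (unit peak)."""
    t = np.arange(int(round(0.3 * fs))) / fs
    w = np.sin(np.pi * t / 0.3) ** 2 * np.sign(np.sin(2 * np.pi * t / 0.3))
    return w


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def simulate_eeg(
    script: StimulusScript, config: GroupConfig, subject_index: int
) -> Recording:
    """EEG + EOG recording with time-varying inter-channel beta synchronization.

    Each EEG channel is ``g_i * (sqrt(s(t)) * shared + sqrt(1 - s(t)) * indep_i)
    + noise_sd * pink_i`` where ``s(t)`` equals ``baseline_sync`` outside
    ``desync`` events and ``baseline_sync * (1 - magnitude)`` inside them.
    The per-channel gains ``g_i`` (fixed per subject, magnitude
    Uniform(0.6, 1.4) with random sign) model a dipolar-like projection of
    the shared source onto the scalp; sign diversity matters because a
    common average reference would exactly cancel a uniformly projected
    shared source.  Two EOG channels carry blink transients that leak into
    frontal channels with the fixed gains in :data:`BLINK_LEAK_GAINS`.
    """
    fs = config.sampling_rate
    n = int(round(script.duration * fs))
    times = np.arange(n) / fs
    epoch_len = 2.0
    for e in script.events_of_kind("desync"):
        if e.end - e.start < epoch_len:
            warnings.warn(
                f"desync event {e.start}-{e.end}s is shorter than one {epoch_len}-s "
                "epoch; detectability is not guaranteed", stacklevel=2,
            )

    rng = _rng(config.seed, subject_index, 1)
    shared = _beta_noise(rng, n, fs)
    # dipolar-like topography: magnitudes in [0.6, 1.4] with random sign, so
    # the projection has near-zero scalp mean and survives a common average
    # reference (a one-signed topography would be cancelled by it)
    n_eeg = config.n_eeg_channels
    gains = rng.uniform(0.6, 1.4, size=n_eeg) * rng.choice([-1.0, 1.0], size=n_eeg)
    sync = np.full(n, config.baseline_sync)
    for e in script.events_of_kind("desync"):
        mask = (times >= e.start) & (times < e.end)
        sync[mask] = config.baseline_sync * (1.0 - e.magnitude)

    eeg = np.empty((n_eeg, n))
    for i in range(n_eeg):
        indep = _beta_noise(rng, n, fs)
        eeg[i] = gains[i] * (np.sqrt(sync) * shared + np.sqrt(1.0 - sync) * indep)
        if config.noise_sd > 0:
            eeg[i] += config.noise_sd * _pink_noise(rng, n)

    # blinks: Poisson at ~12/min on the vertical EOG, weaker on horizontal
    blink = _blink_waveform(fs)
    veog = np.zeros(n)
    n_blinks = rng.poisson(12.0 * script.duration / 60.0)
    starts = np.sort(rng.uniform(0, script.duration - 0.3, size=n_blinks))
    for s in starts:
        i0 = int(round(s * fs))
        seg = min(len(blink), n - i0)
        veog[i0:i0 + seg] += 5.0 * blink[:seg]
    heog = 0.2 * veog + 0.3 * _pink_noise(rng, n)
    veog_noisy = veog + 0.3 * _pink_noise(rng, n)

    labels = SCALP_LABELS[:n_eeg]
    for lab, gain in BLINK_LEAK_GAINS.items():
        if lab in labels:
            eeg[labels.index(lab)] += gain * veog

    samples = np.vstack([eeg, veog_noisy[None, :], heog[None, :]])
    return Recording(
        subject_id=f"sub{subject_index:02d}",
        channel_labels=labels + ["vEOG", "hEOG"],
        channel_roles=["EEG"] * n_eeg + ["EOG_V", "EOG_H"],
        sampling_rate=fs,
        samples=samples,
    )


# SCR kernel constants: difference of exponentials, ~1 s rise, ~3 s decay.
# These are plumbing for the detector tests, not physiology claims.
_SCR_RISE_S = 1.0
_SCR_DECAY_S = 3.0


def _scr_kernel(fs: float) -> np.ndarray:
    t = np.arange(int(round(12.0 * fs))) / fs
    k = np.exp(-t / _SCR_DECAY_S) - np.exp(-t / _SCR_RISE_S)
    return k / np.max(k)


def simulate_gsr(
    script: StimulusScript, config: GroupConfig, subject_index: int
) -> Recording:
    """Skin-conductance channel: tonic drift + one SCR per ``scr_burst`` event.

    SCR onsets are jittered up to 1 s after the event start; amplitude is
    proportional to event magnitude.
    """
    fs = config.sampling_rate
    n = int(round(script.duration * fs))
    rng = _rng(config.seed, subject_index, 2)

    t = np.arange(n) / fs
    # linear tonic drift: detrending and differentiation null it exactly, so
    # with zero noise the only zero-crossing lobes are the planted SCRs
    tonic = 5.0 - 0.008 * t
    x = tonic.copy()
    kernel = _scr_kernel(fs)
    for e in script.events_of_kind("scr_burst"):
        onset = e.start + rng.uniform(0.0, 1.0)
        i0 = int(round(onset * fs))
        seg = min(len(kernel), n - i0)
        if seg > 0:
            x[i0:i0 + seg] += 1.0 * e.magnitude * kernel[:seg]
    if config.noise_sd > 0:
        x += 0.01 * config.noise_sd * rng.standard_normal(n)

    return Recording(
        subject_id=f"sub{subject_index:02d}",
        channel_labels=["GSR1"],
        channel_roles=["GSR"],
        sampling_rate=fs,
        samples=x[None, :],
    )


_HR_BASELINE_BPM = 70.0
_HR_RISE_BPM = 20.0


def _pulse_kernel(fs: float) -> np.ndarray:
    """A fixed PPG pulse shape: sharp systolic peak with a dicrotic shoulder."""
    t = np.arange(int(round(0.5 * fs))) / fs
    k = np.exp(-((t - 0.12) ** 2) / (2 * 0.03**2)) + 0.3 * np.exp(
        -((t - 0.32) ** 2) / (2 * 0.05**2)
    )
    return k / np.max(k)


def hr_profile(script: StimulusScript, times: np.ndarray) -> np.ndarray:
    """Programmed heart rate in bpm: baseline 70, +20*magnitude in hr_rise events."""
    hr = np.full_like(times, _HR_BASELINE_BPM)
    for e in script.events_of_kind("hr_rise"):
        mask = (times >= e.start) & (times < e.end)
        hr[mask] = _HR_BASELINE_BPM + _HR_RISE_BPM * e.magnitude
    return hr


def simulate_ppg(
    script: StimulusScript,
    config: GroupConfig,
    subject_index: int,
    hr_baseline: float = _HR_BASELINE_BPM,
) -> Recording:
    """PPG pulse train whose inter-pulse interval follows 60 / HR(t)."""
    fs = config.sampling_rate
    n = int(round(script.duration * fs))
    rng = _rng(config.seed, subject_index, 3)

    def hr_at(t: float) -> float:
        hr = hr_baseline
        for e in script.events_of_kind("hr_rise"):
            if e.start <= t < e.end:
                hr = hr_baseline + _HR_RISE_BPM * e.magnitude
        return hr

    if hr_baseline <= 0:
        raise ConfigurationError("heart rate profile must be positive")

    # place pulse onsets by integrating the instantaneous period
    peak_times = []
    t = rng.uniform(0.0, 0.1)  # random initial phase
    while t < script.duration:
        hr = hr_at(t)
        if hr <= 0:
            raise ConfigurationError("heart rate profile must be positive")
        peak_times.append(t)
        t += 60.0 / hr

    kernel = _pulse_kernel(fs)
    x = np.zeros(n)
    for pt in peak_times:
        i0 = int(round(pt * fs))
        seg = min(len(kernel), n - i0)
        if seg > 0:
            x[i0:i0 + seg] += kernel[:seg]
    if config.noise_sd > 0:
        x += 0.02 * config.noise_sd * rng.standard_normal(n)

    return Recording(
        subject_id=f"sub{subject_index:02d}",
        channel_labels=["PPG1"],
        channel_roles=["PPG"],
        sampling_rate=fs,
        samples=x[None, :],
    )


def simulate_audio(
    script: StimulusScript, sampling_rate: float, seed: int, baseline: float = 0.05
) -> np.ndarray:
    """Mono stimulus-audio waveform: white noise with a loudness envelope.

    The envelope is ``baseline`` outside ``loud`` events and
    ``baseline * (1 + 3 * magnitude)`` inside, so a magnitude-1 event is 4x
    the baseline RMS.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 4])
    n = int(round(script.duration * sampling_rate))
    times = np.arange(n) / sampling_rate
    env = np.full(n, baseline)
    for e in script.events_of_kind("loud"):
        mask = (times >= e.start) & (times < e.end)
        env[mask] = baseline * (1.0 + 3.0 * e.magnitude)
    return env * rng.standard_normal(n)


def simulate_questionnaire(
    script: StimulusScript,
    n_respondents: int,
    jitter_sd: float = 2.0,
    seed: int = 0,
    clip_id: str = "clip",
    bin_width: float = 10.0,
) -> GroundTruthTimeline:
    """Questionnaire ground truth: two picks per respondent.

    Each respondent picks the two largest-magnitude script events (ties
    broken toward the earlier event) and reports each event center plus
    Gaussian jitter of ``jitter_sd`` seconds, clipped to the clip.
    """
    if len(script.events) < 2:
        raise ConfigurationError("questionnaire needs a script with >= 2 events")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 5])
    order = sorted(
        range(len(script.events)),
        key=lambda i: (-script.events[i].magnitude, script.events[i].start, i),
    )
    # "events" as experienced are moments, not per-modality entries: collapse
    # co-located entries so the two picks are two distinct moments
    targets: list[float] = []
    for i in order:
        c = script.events[i].center
        if all(abs(c - t) > 1e-9 for t in targets):
            targets.append(c)
        if len(targets) == 2:
            break
    if len(targets) < 2:
        raise ConfigurationError("script needs two distinct event moments")

    picks = []
    for r in range(n_respondents):
        for c in targets:
            t = c + rng.normal(0.0, jitter_sd) if jitter_sd > 0 else c
            picks.append((f"resp{r:02d}", clip_id, float(np.clip(t, 0.0, script.duration))))
    return GroundTruthTimeline(picks=picks, bin_width=bin_width, clip_duration=script.duration)


def simulate_subject(
    script: StimulusScript, config: GroupConfig, subject_index: int
) -> Recording:
    """All modalities for one subject merged into a single Recording."""
    eeg = simulate_eeg(script, config, subject_index)
    gsr = simulate_gsr(script, config, subject_index)
    ppg = simulate_ppg(script, config, subject_index)
    return Recording(
        subject_id=eeg.subject_id,
        channel_labels=eeg.channel_labels + gsr.channel_labels + ppg.channel_labels,
        channel_roles=eeg.channel_roles + gsr.channel_roles + ppg.channel_roles,
        sampling_rate=config.sampling_rate,
        samples=np.vstack([eeg.samples, gsr.samples, ppg.samples]),
    )
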