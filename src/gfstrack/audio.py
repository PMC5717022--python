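"""Stimulus-audio content analysis: framewise RMS energy.

Loudness of the soundtrack is a cheap, stimulus-side proxy for emotional
arousal; the feature here is the root-mean-square amplitude per frame,
computed on the same 2-s/1-s grid as the EEG epochs so all streams share a
timeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .core_io import ConfigurationError, FeatureSeries, FormatError

__all__ = ["AudioTrack", "read_audio", "write_audio", "frame_rms"]

DEFAULT_FRAME_S = 2.0
DEFAULT_HOP_S = 1.0


@dataclass
class AudioTrack:
    """Mono audio in float samples (nominally within [-1, 1])."""

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ConfigurationError("audio samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


def read_audio(path: str | Path) -> AudioTrack:
    """Read a PCM WAV file as a mono float track.

    Multichannel audio is mixed down by averaging channels.  Integer PCM is
    scaled to [-1, 1) by the type's full scale; float WAV is passed through.
    """
    try:
        rate, data = wavfile.read(path)
    except (ValueError, FileNotFoundError) as exc:
        raise FormatError(f"cannot read {path} as PCM WAV: {exc}") from exc
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(float) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        x = data.astype(float)
    else:
        raise FormatError(f"unsupported WAV encoding {data.dtype} in {path}")
    if x.ndim == 2:
        x = x.mean(axis=1)
    return AudioTrack(samples=x, sampling_rate=float(rate))


def write_audio(track: AudioTrack, path: str | Path) -> None:
    """Write a track as 16-bit PCM WAV."""
    x = np.clip(track.samples, -1.0, 1.0 - 2.0**-15)
    wavfile.write(path, int(round(track.sampling_rate)), np.round(x * 32768.0).astype(np.int16))


def frame_rms(
    track: AudioTrack, frame_length: float = DEFAULT_FRAME_S, hop: float = DEFAULT_HOP_S
) -> FeatureSeries:
    """Framewise RMS energy, timestamped at frame centers.

    Frame count is ``floor((N - L) / H) + 1``; the final partial frame is
    dropped.
    """
    if not frame_length >= hop > 0:
        raise ConfigurationError("need frame_length >= hop > 0")
    fs = track.sampling_rate
    L = int(round(frame_length * fs))
    H = int(round(hop * fs))
    n = len(track.samples)
    if n < L:
        raise ConfigurationError(
            f"track ({n} samples) shorter than one frame ({L} samples)"
        )
    n_frames = (n - L) // H + 1
    starts = np.arange(n_frames) * H
    values = np.empty(n_frames)
    for k, s0 in enumerate(starts):
        seg = track.samples[s0:s0 + L]
        values[k] = np.sqrt(np.mean(seg * seg))
    times = (starts + L / 2.0) / fs
    return FeatureSeries(name="rms_energy", units="amplitude", times=times, values=values)
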