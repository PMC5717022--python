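"""Run configuration: YAML-backed parameters for every pipeline stage.

Defaults are the field-standard analysis values: beta band 14-25 Hz, 2-s epochs
with 50% overlap, 1-55 Hz EEG band-pass, GSR at 16 Hz with a 0.2 Hz
low-pass and 6-s feature window, PPG band 0.5-5 Hz, ten-point smoothing and
k = 1.96 threshold lines.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core_io import ConfigurationError
from .gfs import GFSConfig


@dataclass
class RunConfig:
    """Everything a pipeline run needs, validated at load time."""

    seed: int = 0
    n_subjects: int = 10
    n_eeg_channels: int = 12
    sampling_rate: float = 256.0
    baseline_sync: float = 0.7
    noise_sd: float = 0.1
    clip_duration: float = 120.0
    n_respondents: int = 37
    jitter_sd: float = 2.0

    bandpass_low: float = 1.0
    bandpass_high: float = 55.0
    epoch_length: float = 2.0
    overlap: float = 0.5
    band_low: float = 14.0
    band_high: float = 25.0
    eog_correlation_threshold: float = 0.7
    exclude_channels: list[str] = field(default_factory=list)

    gsr_rate: float = 16.0
    gsr_lowpass: float = 0.2
    scr_window: float = 6.0
    ppg_band: list[float] = field(default_factory=lambda: [0.5, 5.0])

    frame_length: float = 2.0
    hop: float = 1.0

    smoothing_points: int = 10
    k: float = 1.96
    secondary_k: float = 1.5
    min_duration: float = 1.0
    merge_gap: float = 2.0
    bin_width: float = 10.0
    match_tolerance: float = 10.0

    channel_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        checks = [
            (self.n_subjects >= 1, "n_subjects must be >= 1"),
            (self.sampling_rate > 0, "sampling_rate must be positive"),
            (0 <= self.baseline_sync <= 1, "baseline_sync must be in [0, 1]"),
            (0 < self.bandpass_low < self.bandpass_high, "invalid EEG band-pass"),
            (0 <= self.overlap < 1, "overlap must be in [0, 1)"),
            (self.band_low < self.band_high, "invalid GFS band"),
            (self.epoch_length > 0, "epoch_length must be positive"),
            (self.smoothing_points >= 1, "smoothing_points must be >= 1"),
            (self.k > 0, "k must be positive"),
            (self.frame_length >= self.hop > 0, "need frame_length >= hop > 0"),
            (len(self.ppg_band) == 2 and 0 < self.ppg_band[0] < self.ppg_band[1],
             "invalid PPG band"),
            (self.bin_width > 0, "bin_width must be positive"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigurationError(msg)

    def gfs_config(self) -> GFSConfig:
        return GFSConfig(
            bandpass_low=self.bandpass_low,
            bandpass_high=self.bandpass_high,
            epoch_length=self.epoch_length,
            overlap=self.overlap,
            band_low=self.band_low,
            band_high=self.band_high,
            eog_correlation_threshold=self.eog_correlation_threshold,
            smoothing_points=self.smoothing_points,
            exclude_channels=tuple(self.exclude_channels),
        )

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
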