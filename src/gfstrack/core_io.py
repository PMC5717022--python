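"""Shared domain types and file I/O for the arousal-tracking pipeline.

The pipeline moves four kinds of objects between stages:

* :class:`Recording` — one subject's synchronized multichannel time series
  (EEG, EOG, GSR, PPG) on the stimulus timeline,
* :class:`EpochGrid` — the overlapping-window segmentation shared by the
  spectral stages,
* :class:`FeatureSeries` — any uniformly sampled scalar feature stream
  (GFS, SCR feature, heart rate, audio RMS energy),
* :class:`GroundTruthTimeline` — questionnaire picks of the most arousing
  moments, two per respondent per clip.

Recordings are read with MNE (BDF/EDF); because no installed library writes
those formats, this module carries a small standards-conformant EDF/BDF
writer used by the synthetic-data generators.  Feature series travel as
two-column CSV.  All timestamps are seconds from stimulus onset.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ChannelRole",
    "Recording",
    "EpochGrid",
    "FeatureSeries",
    "GroundTruthTimeline",
    "ConfigurationError",
    "FormatError",
    "read_recording",
    "write_recording",
    "read_series",
    "write_series",
]

#: Valid channel roles.  EOG_V / EOG_H are vertical / horizontal
#: electrooculogram channels; everything else is a single-channel modality.
ROLES = ("EEG", "EOG_V", "EOG_H", "GSR", "PPG")
ChannelRole = str


class ConfigurationError(ValueError):
    """A channel/role map or parameter set is inconsistent with the data."""


class FormatError(IOError):
    """A file could not be parsed as the requested format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """One subject's multichannel recording on the stimulus timeline.

    Parameters
    ----------
    subject_id
        Opaque label for the subject.
    channel_labels
        Ordered, unique channel names.
    channel_roles
        One role per channel, each in :data:`ROLES`.
    sampling_rate
        Sampling rate in Hz (> 0).
    samples
        ``(n_channels, n_samples)`` float array.
    t0
        Offset of the first sample relative to stimulus onset, seconds.
    """

    subject_id: str
    channel_labels: list[str]
    channel_roles: list[ChannelRole]
    sampling_rate: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ConfigurationError("samples must be a 2-D [channels x time] array")
        n = len(self.channel_labels)
        if n == 0:
            raise ConfigurationError("recording must contain at least one channel")
        if self.samples.shape[0] != n:
            raise ConfigurationError(
                f"{n} channel labels but {self.samples.shape[0]} sample rows"
            )
        if len(self.channel_roles) != n:
            raise ConfigurationError("channel_roles must match channel_labels in length")
        if len(set(self.channel_labels)) != n:
            raise ConfigurationError("channel labels must be unique")
        bad = [r for r in self.channel_roles if r not in ROLES]
        if bad:
            raise ConfigurationError(f"unknown channel role(s): {bad}; valid: {ROLES}")
        if not self.sampling_rate > 0:
            raise ConfigurationError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in seconds from stimulus onset."""
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def channels_with_role(self, role: ChannelRole) -> list[int]:
        return [i for i, r in enumerate(self.channel_roles) if r == role]

    def pick(self, labels: Sequence[str]) -> "Recording":
        """Sub-recording containing only *labels*, in the given order."""
        idx = []
        for lab in labels:
            if lab not in self.channel_labels:
                raise ConfigurationError(f"unknown channel {lab!r}")
            idx.append(self.channel_labels.index(lab))
        return replace(
            self,
            channel_labels=[self.channel_labels[i] for i in idx],
            channel_roles=[self.channel_roles[i] for i in idx],
            samples=self.samples[idx].copy(),
        )

    def drop(self, labels: Sequence[str]) -> "Recording":
        keep = [lab for lab in self.channel_labels if lab not in set(labels)]
        return self.pick(keep)

    def copy_with(self, samples: np.ndarray) -> "Recording":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class EpochGrid:
    """Overlapping-window segmentation of a recording.

    ``start_indices`` are 0-based sample indices; consecutive starts differ
    by ``round(epoch_length * rate * (1 - overlap_fraction))`` and every
    epoch lies fully inside the recording.
    """

    epoch_length: float
    overlap_fraction: float
    start_indices: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "start_indices", np.asarray(self.start_indices, dtype=int)
        )
        if not 0 <= self.overlap_fraction < 1:
            raise ConfigurationError("overlap_fraction must be in [0, 1)")
        if self.epoch_length <= 0:
            raise ConfigurationError("epoch_length must be positive")
        step = self.step_samples
        d = np.diff(self.start_indices)
        if d.size and not np.all(d == step):
            raise ConfigurationError("start indices must be uniformly spaced by the hop")

    @property
    def epoch_samples(self) -> int:
        return int(round(self.epoch_length * self.sampling_rate))

    @property
    def step_samples(self) -> int:
        return int(round(self.epoch_samples * (1.0 - self.overlap_fraction)))

    @property
    def n_epochs(self) -> int:
        return len(self.start_indices)

    def center_times(self, t0: float = 0.0) -> np.ndarray:
        """Epoch-center timestamps (seconds from stimulus onset)."""
        half = self.epoch_samples / 2.0
        return t0 + (self.start_indices + half) / self.sampling_rate


@dataclass
class FeatureSeries:
    """A uniformly sampled scalar feature stream.

    ``values`` may contain NaN to mark gaps (epochs where the feature is
    undefined); gaps serialize to empty CSV fields, never sentinel numbers.
    """

    name: str
    units: str
    times: np.ndarray
    values: np.ndarray
    subject_id: str = "group"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ConfigurationError("times and values must be 1-D and equal length")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ConfigurationError("times must be strictly increasing")
            if np.max(dt) - np.min(dt) > 1e-9 * max(abs(dt[0]), 1e-30):
                raise ConfigurationError("times must be uniformly spaced")

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("spacing undefined for series with < 2 points")
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size


@dataclass
class GroundTruthTimeline:
    """Questionnaire picks: two arousing time points per respondent per clip."""

    picks: list[tuple[str, str, float]]  # (respondent_id, clip_id, time_point s)
    bin_width: float = 10.0
    clip_duration: float | None = None

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ConfigurationError("bin_width must be positive")
        counts: dict[tuple[str, str], int] = {}
        for rid, cid, t in self.picks:
            if t < 0:
                raise ConfigurationError(f"negative time point for {rid}/{cid}")
            if self.clip_duration is not None and t > self.clip_duration:
                raise ConfigurationError(f"pick beyond clip duration for {rid}/{cid}")
            counts[(rid, cid)] = counts.get((rid, cid), 0) + 1
        bad = {k: v for k, v in counts.items() if v != 2}
        if bad:
            raise ConfigurationError(
                f"every (respondent, clip) needs exactly two picks; offenders: {bad}"
            )

    def clip_ids(self) -> list[str]:
        return sorted({cid for _, cid, _ in self.picks})

    def times_for_clip(self, clip_id: str) -> np.ndarray:
        return np.array(sorted(t for _, cid, t in self.picks if cid == clip_id))

    def histogram(self, clip_id: str, duration: float | None = None):
        """Histogram of picks for a clip; returns (counts, bin_edges)."""
        t = self.times_for_clip(clip_id)
        dur = duration if duration is not None else (
            self.clip_duration if self.clip_duration is not None else float(t.max())
        )
        n_bins = max(1, int(np.ceil(dur / self.bin_width)))
        edges = np.arange(n_bins + 1) * self.bin_width
        counts, _ = np.histogram(t, bins=edges)
        return counts, edges

    def modes(self, clip_id: str, duration: float | None = None) -> np.ndarray:
        """Centers of the two most populated histogram bins, ascending in time.

        Ties are broken toward the earlier bin.
        """
        counts, edges = self.histogram(clip_id, duration)
        order = np.lexsort((np.arange(len(counts)), -counts))
        top = np.sort(order[:2])
        return (edges[top] + edges[top + 1]) / 2.0


# ---------------------------------------------------------------------------
# EDF / BDF writing
# ---------------------------------------------------------------------------

_EDF_DIG_MAX = 32767
_BDF_DIG_MAX = 8388607


def _fixed(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def _num8(v: float) -> str:
    """Format a float into <= 8 ASCII chars (EDF numeric header field)."""
    for prec in range(7, -1, -1):
        s = f"{v:.{prec}g}"
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot format {v} in 8 chars")


def _physical_range(x: np.ndarray) -> tuple[float, float]:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:  # constant channel: give it a nonzero range
        lo, hi = lo - 1.0, hi + 1.0
    # pad 0.1% so rounding never clips the extremes
    pad = 1e-3 * (hi - lo)
    return lo - pad, hi + pad


def write_recording(recording: Recording, path: str | Path, format: str = "BDF") -> None:
    """Write a :class:`Recording` as EDF (16-bit) or BDF (24-bit).

    The writer uses 1-second data records; recordings whose length is not a
    whole number of seconds are zero-padded to the next record boundary.
    Round-tripping through :func:`read_recording` preserves samples within
    the format's quantization (range / 2^16 for EDF, range / 2^24 for BDF).
    The stimulus-onset offset ``t0`` is not representable in these headers
    and is dropped on write.
    """
    fmt = format.upper()
    if fmt not in ("BDF", "EDF"):
        raise ValueError(f"format must be BDF or EDF, got {format!r}")
    rate = recording.sampling_rate
    if abs(rate - round(rate)) > 1e-9:
        raise ConfigurationError("EDF/BDF writer requires an integer sampling rate")
    ns_rec = int(round(rate))  # samples per channel per 1-s record

    x = recording.samples
    n_ch, n_samp = x.shape
    n_rec = int(np.ceil(n_samp / ns_rec))
    padded = np.zeros((n_ch, n_rec * ns_rec))
    padded[:, :n_samp] = x

    dig_max = _BDF_DIG_MAX if fmt == "BDF" else _EDF_DIG_MAX
    dig_min = -dig_max
    phys = [_physical_range(padded[i]) for i in range(n_ch)]

    buf = io.BytesIO()
    if fmt == "BDF":
        buf.write(b"\xffBIOSEMI")
    else:
        buf.write(_fixed("0", 8))
    buf.write(_fixed(f"X X X {recording.subject_id}", 80))  # patient id
    buf.write(_fixed("Startdate X X X X", 80))  # recording id
    now = _dt.datetime(2000, 1, 1)
    buf.write(_fixed(now.strftime("%d.%m.%y"), 8))
    buf.write(_fixed(now.strftime("%H.%M.%S"), 8))
    buf.write(_fixed(str(256 * (1 + n_ch)), 8))  # header bytes
    buf.write(_fixed("24BIT" if fmt == "BDF" else "", 44))
    buf.write(_fixed(str(n_rec), 8))
    buf.write(_fixed("1", 8))  # record duration, s
    buf.write(_fixed(str(n_ch), 4))

    for lab in recording.channel_labels:
        buf.write(_fixed(lab, 16))
    for _ in range(n_ch):
        buf.write(_fixed("", 80))  # transducer
    for _ in range(n_ch):
        buf.write(_fixed("", 8))  # physical dimension (blank: arbitrary units)
    # re-derive ranges from the 8-char header representation so that the
    # scaling we digitize with is exactly what a reader will see
    phys = [(float(_num8(lo)), float(_num8(hi))) for lo, hi in phys]
    for lo, hi in phys:
        buf.write(_fixed(_num8(lo), 8))
    for lo, hi in phys:
        buf.write(_fixed(_num8(hi), 8))
    for _ in range(n_ch):
        buf.write(_fixed(str(dig_min), 8))
    for _ in range(n_ch):
        buf.write(_fixed(str(dig_max), 8))
    for _ in range(n_ch):
        buf.write(_fixed("", 80))  # prefiltering
    for _ in range(n_ch):
        buf.write(_fixed(str(ns_rec), 8))
    for _ in range(n_ch):
        buf.write(_fixed("", 32))  # reserved

    # digitize
    dig = np.empty_like(padded, dtype=np.int32)
    for i, (lo, hi) in enumerate(phys):
        scale = (dig_max - dig_min) / (hi - lo)
        dig[i] = np.clip(np.round((padded[i] - lo) * scale) + dig_min, dig_min, dig_max)

    for r in range(n_rec):
        sl = slice(r * ns_rec, (r + 1) * ns_rec)
        for i in range(n_ch):
            d = dig[i, sl]
            if fmt == "EDF":
                buf.write(d.astype("<i2").tobytes())
            else:
                b4 = d.astype("<i4").tobytes()
                arr = np.frombuffer(b4, dtype=np.uint8).reshape(-1, 4)
                buf.write(arr[:, :3].tobytes())

    Path(path).write_bytes(buf.getvalue())


def read_recording(
    path: str | Path,
    role_map: Mapping[str, ChannelRole],
    format: str | None = None,
    subject_id: str | None = None,
) -> Recording:
    """Read a BDF/EDF file into a :class:`Recording`.

    Channel roles are never guessed: ``role_map`` must name every channel in
    the file (label -> role).  The sampling rate comes from the file header.

    Raises
    ------
    FormatError
        If the file cannot be parsed as BDF/EDF.
    ConfigurationError
        If a channel in the file is missing from ``role_map``.
    """
    import mne

    p = Path(path)
    if not p.exists():
        raise FormatError(f"no such file: {p}")
    fmt = (format or p.suffix.lstrip(".")).upper()
    try:
        if fmt == "BDF":
            raw = mne.io.read_raw_bdf(p, preload=True, verbose="error")
        elif fmt == "EDF":
            raw = mne.io.read_raw_edf(p, preload=True, verbose="error")
        else:
            raise FormatError(f"unsupported format {fmt!r} (expected BDF or EDF)")
    except FormatError:
        raise
    except Exception as exc:  # mne raises assorted exceptions on bad files
        raise FormatError(f"could not parse {p} as {fmt}: {exc}") from exc

    labels = list(raw.ch_names)
    if len(set(labels)) != len(labels):
        raise ConfigurationError(f"duplicate channel labels in {p}: {labels}")
    missing = [lab for lab in labels if lab not in role_map]
    if missing:
        raise ConfigurationError(
            f"role map does not cover channel(s) {missing}; every channel needs a role"
        )
    data = raw.get_data()
    # blank physical-dimension fields mean mne applies no unit scaling,
    # so the data come back in the units they were written in
    return Recording(
        subject_id=subject_id if subject_id is not None else p.stem,
        channel_labels=labels,
        channel_roles=[role_map[lab] for lab in labels],
        sampling_rate=float(raw.info["sfreq"]),
        samples=data,
    )


# ---------------------------------------------------------------------------
# FeatureSeries CSV
# ---------------------------------------------------------------------------


def write_series(series: FeatureSeries, path: str | Path) -> None:
    """Write a series as two-column CSV (time_s, value), 12 significant digits.

    Gaps (NaN) are written as empty value fields.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "value"])
        w.writerow([f"# name={series.name}", f"units={series.units}"])
        w.writerow([f"# subject={series.subject_id}", ""])
        for t, v in zip(series.times, series.values):
            w.writerow([f"{t:.12g}", "" if np.isnan(v) else f"{v:.12g}"])


def read_series(path: str | Path) -> FeatureSeries:
    """Read a series CSV written by :func:`write_series`."""
    name, units, subject = Path(path).stem, "", "group"
    times: list[float] = []
    values: list[float] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            if row[0].startswith("#"):
                meta = row[0].lstrip("# ")
                if meta.startswith("name="):
                    name = meta[5:]
                    if len(row) > 1 and row[1].startswith("units="):
                        units = row[1][6:]
                elif meta.startswith("subject="):
                    subject = meta[8:]
                continue
            if row[0] == "time_s":
                continue
            try:
                times.append(float(row[0]))
                values.append(float(row[1]) if len(row) > 1 and row[1] != "" else np.nan)
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed row {row!r}") from exc
    return FeatureSeries(
        name=name, units=units, times=np.array(times), values=np.array(values),
        subject_id=subject,
    )


def write_timeline(timeline: GroundTruthTimeline, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["respondent_id", "clip_id", "time_s"])
        for rid, cid, t in timeline.picks:
            w.writerow([rid, cid, f"{t:.12g}"])


def read_timeline(
    path: str | Path, bin_width: float = 10.0, clip_duration: float | None = None
) -> GroundTruthTimeline:
    picks = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or row[0] == "respondent_id":
                continue
            try:
                picks.append((row[0], row[1], float(row[2])))
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed row {row!r}") from exc
    return GroundTruthTimeline(picks=picks, bin_width=bin_width, clip_duration=clip_duration)
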