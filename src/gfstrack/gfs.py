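"""Beta-band global field synchronization (GFS) from multichannel EEG.

GFS quantifies, per frequency, how collinear the channels' Fourier
coefficients are in the complex plane.  For each frequency bin the N
channel coefficients give N points (Re, Im); the two eigenvalues E1 >= E2
of their 2x2 second-moment scatter matrix yield

    GFS(f) = |E1 - E2| / (E1 + E2)

which is 1 when all channels share a single phase axis (one common
oscillation, up to sign) and 0 when the phases are isotropic.  The subject
pipeline is: common average reference -> DC removal -> 1-55 Hz band-pass ->
PCA-based eye-blink removal -> 2-s Hanning-tapered epochs with 50% overlap
-> per-epoch GFS averaged over the beta band (14-25 Hz inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core_io import ConfigurationError, EpochGrid, FeatureSeries, Recording

__all__ = [
    "GFSSpectrum",
    "GFSConfig",
    "common_average_reference",
    "remove_dc",
    "bandpass",
    "remove_eog_pca",
    "make_epochs",
    "gfs_spectrum",
    "band_average",
    "subject_gfs_series",
    "band_psd_series",
]


@dataclass
class GFSSpectrum:
    """Per-epoch GFS values with the eigenvalue pair behind each bin.

    Bins with zero total power (E1 + E2 == 0) are undefined: ``gfs`` holds
    NaN there rather than a fabricated 0/0.
    """

    epoch_index: int
    epoch_center_time: float
    frequencies: np.ndarray
    gfs: np.ndarray
    eigenvalues: np.ndarray  # (n_freqs, 2), E1 >= E2 >= 0

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.gfs)


@dataclass(frozen=True)
class GFSConfig:
    """Stage parameters for the subject-level GFS chain."""

    bandpass_low: float = 1.0
    bandpass_high: float = 55.0
    epoch_length: float = 2.0
    overlap: float = 0.5
    band_low: float = 14.0
    band_high: float = 25.0
    eog_correlation_threshold: float = 0.7
    smoothing_points: int = 10
    exclude_channels: tuple[str, ...] = ()
    center_scatter: bool = False
    decimate_to: float | None = 256.0
    eog_removal: str = "auto"  # auto | on | off

    def __post_init__(self) -> None:
        if not 0 < self.bandpass_low < self.bandpass_high:
            raise ConfigurationError("need 0 < bandpass_low < bandpass_high")
        if not 0 <= self.overlap < 1:
            raise ConfigurationError("overlap must be in [0, 1)")
        if self.eog_removal not in ("auto", "on", "off"):
            raise ConfigurationError("eog_removal must be auto, on or off")


# ---------------------------------------------------------------------------
# preprocessing stages
# ---------------------------------------------------------------------------


def common_average_reference(recording: Recording) -> Recording:
    """Re-reference EEG channels to their instantaneous mean.

    Only EEG-role channels enter the average and only they are modified.
    """
    eeg = recording.channels_with_role("EEG")
    if len(eeg) < 2:
        raise ConfigurationError("common average reference needs >= 2 EEG channels")
    out = recording.samples.copy()
    out[eeg] -= out[eeg].mean(axis=0, keepdims=True)
    return recording.copy_with(out)


def remove_dc(recording: Recording) -> Recording:
    """Subtract each channel's temporal mean."""
    out = recording.samples - recording.samples.mean(axis=1, keepdims=True)
    return recording.copy_with(out)


def bandpass(
    recording: Recording, low: float, high: float, order: int = 4
) -> Recording:
    """Zero-phase Butterworth band-pass applied to every channel.

    Forward-backward (filtfilt) application doubles the effective order, so
    the default meets >= 20 dB attenuation at ``low/2`` and ``2*high``.
    """
    nyq = recording.sampling_rate / 2.0
    if not 0 < low < high < nyq:
        raise ConfigurationError(
            f"invalid band [{low}, {high}] for rate {recording.sampling_rate}"
        )
    sos = signal.butter(
        order, [low, high], btype="bandpass", fs=recording.sampling_rate, output="sos"
    )
    out = signal.sosfiltfilt(sos, recording.samples, axis=1)
    return recording.copy_with(out)


def remove_eog_pca(recording: Recording, correlation_threshold: float = 0.7) -> Recording:
    """Project out principal components of the EEG that track the EOG.

    The EEG submatrix is decomposed by SVD; any component whose absolute
    temporal correlation with any EOG channel exceeds the threshold is
    removed and the EEG is reconstructed from the remainder.  EOG and other
    channels pass through untouched.
    """
    eog = recording.channels_with_role("EOG_V") + recording.channels_with_role("EOG_H")
    if not eog:
        raise ConfigurationError(
            "no EOG-role channel present; skip the EOG-removal stage explicitly "
            "(eog_removal='off') if the recording has none"
        )
    eeg = recording.channels_with_role("EEG")
    if not eeg:
        raise ConfigurationError("no EEG channels to clean")
    X = recording.samples[eeg]
    E = recording.samples[eog]
    mean = X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(X - mean, full_matrices=False)

    keep = np.ones(len(s), dtype=bool)
    for k in range(len(s)):
        if s[k] <= 0:
            continue
        comp = Vt[k]
        for e in E:
            se, sc = np.std(e), np.std(comp)
            if se > 0 and sc > 0:
                r = np.corrcoef(comp, e)[0, 1]
                if abs(r) > correlation_threshold:
                    keep[k] = False
                    break
    out = recording.samples.copy()
    out[eeg] = (U[:, keep] * s[keep]) @ Vt[keep] + mean
    return recording.copy_with(out)


def decimate(recording: Recording, target_rate: float) -> Recording:
    """Anti-aliased integer-factor decimation of every channel."""
    factor = recording.sampling_rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ConfigurationError(
            f"decimation from {recording.sampling_rate} to {target_rate} Hz "
            "is not an integer factor"
        )
    factor = int(round(factor))
    if factor == 1:
        return recording
    out = recording.samples
    # cascade factors of <= 8 to keep the anti-alias filters well conditioned
    remaining = factor
    while remaining > 1:
        q = min(remaining, 8)
        while remaining % q:
            q -= 1
        out = signal.decimate(out, q, axis=1, zero_phase=True)
        remaining //= q
    from dataclasses import replace

    return replace(recording, samples=out, sampling_rate=target_rate)


# ---------------------------------------------------------------------------
# epoching and the GFS statistic
# ---------------------------------------------------------------------------


def make_epochs(
    recording: Recording, epoch_length: float = 2.0, overlap: float = 0.5
) -> EpochGrid:
    """Maximal grid of full overlapping epochs.

    Epoch count is ``floor((N - L) / step) + 1`` with ``L`` the epoch length
    in samples and ``step = L * (1 - overlap)``.
    """
    fs = recording.sampling_rate
    L = int(round(epoch_length * fs))
    step = int(round(L * (1.0 - overlap)))
    if step < 1:
        raise ConfigurationError("overlap too large: hop would be < 1 sample")
    n = recording.n_samples
    if n < L:
        raise ConfigurationError(
            f"recording ({n} samples) shorter than one epoch ({L} samples)"
        )
    n_epochs = (n - L) // step + 1
    starts = np.arange(n_epochs) * step
    return EpochGrid(
        epoch_length=epoch_length,
        overlap_fraction=overlap,
        start_indices=starts,
        sampling_rate=fs,
    )


def gfs_spectrum(
    epoch: np.ndarray,
    rate: float,
    window: str = "hann",
    center: bool = False,
    epoch_index: int = 0,
    epoch_center_time: float = 0.0,
) -> GFSSpectrum:
    """GFS at every FFT bin of one tapered multichannel epoch.

    Each channel is tapered and Fourier-transformed; at each frequency the
    channel coefficients form points (Re, Im) whose 2x2 second-moment
    scatter matrix (non-centered by default, matching the sine/cosine
    coefficient convention of the GFS literature) is eigendecomposed.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2 or epoch.shape[0] < 2:
        raise ConfigurationError("gfs_spectrum needs a [channels x time] matrix with >= 2 channels")
    n_ch, L = epoch.shape
    if L < 4:
        raise ConfigurationError("epoch too short for a meaningful spectrum")

    taper = signal.get_window(window, L, fftbins=True) if window else np.ones(L)
    coeffs = np.fft.rfft(epoch * taper, axis=1)  # (n_ch, n_freq)
    freqs = np.fft.rfftfreq(L, d=1.0 / rate)

    re, im = coeffs.real, coeffs.imag
    if center:
        re = re - re.mean(axis=0, keepdims=True)
        im = im - im.mean(axis=0, keepdims=True)

    # per-bin scatter [[a, b], [b, c]]
    a = np.sum(re * re, axis=0)
    b = np.sum(re * im, axis=0)
    c = np.sum(im * im, axis=0)
    M = np.empty((len(freqs), 2, 2))
    M[:, 0, 0], M[:, 0, 1], M[:, 1, 0], M[:, 1, 1] = a, b, b, c
    ev = np.linalg.eigvalsh(M)  # ascending
    e2 = np.clip(ev[:, 0], 0.0, None)
    e1 = np.clip(ev[:, 1], 0.0, None)
    total = e1 + e2
    gfs = np.full(len(freqs), np.nan)
    ok = total > 0
    gfs[ok] = np.abs(e1[ok] - e2[ok]) / total[ok]
    np.clip(gfs, 0.0, 1.0, out=gfs)

    return GFSSpectrum(
        epoch_index=epoch_index,
        epoch_center_time=epoch_center_time,
        frequencies=freqs,
        gfs=gfs,
        eigenvalues=np.column_stack([e1, e2]),
    )


def band_average(spectrum: GFSSpectrum, low: float = 14.0, high: float = 25.0) -> float:
    """Mean of defined GFS values over bins with low <= f <= high (inclusive).

    Returns NaN when every bin in the band is undefined.
    """
    mask = (spectrum.frequencies >= low) & (spectrum.frequencies <= high)
    if not np.any(mask):
        raise ConfigurationError(
            f"no frequency bins inside [{low}, {high}] Hz "
            f"(resolution {spectrum.frequencies[1] - spectrum.frequencies[0]:g} Hz)"
        )
    vals = spectrum.gfs[mask]
    vals = vals[~np.isnan(vals)]
    return float(np.mean(vals)) if vals.size else float("nan")


# ---------------------------------------------------------------------------
# subject-level series
# ---------------------------------------------------------------------------


def _preprocessed_eeg(recording: Recording, config: GFSConfig) -> Recording:
    rec = recording
    if config.exclude_channels:
        rec = rec.drop(config.exclude_channels)
    rec = common_average_reference(rec)
    rec = remove_dc(rec)
    rec = bandpass(rec, config.bandpass_low, config.bandpass_high)
    has_eog = bool(rec.channels_with_role("EOG_V") + rec.channels_with_role("EOG_H"))
    if config.eog_removal == "on" or (config.eog_removal == "auto" and has_eog):
        rec = remove_eog_pca(rec, config.eog_correlation_threshold)
    if config.decimate_to is not None and rec.sampling_rate > config.decimate_to:
        rec = decimate(rec, config.decimate_to)
    return rec


def subject_gfs_series(recording: Recording, config: GFSConfig = GFSConfig()) -> FeatureSeries:
    """One subject's band-averaged GFS time series.

    Runs the full preprocessing chain, epochs the EEG-role channels and
    returns the beta-band GFS per epoch, timestamped at epoch centers.
    ``config.exclude_channels`` supports control analyses that drop
    channels (e.g. the temporal electrodes) before referencing.
    """
    rec = _preprocessed_eeg(recording, config)
    grid = make_epochs(rec, config.epoch_length, config.overlap)
    eeg = rec.channels_with_role("EEG")
    if len(eeg) < 2:
        raise ConfigurationError("need >= 2 EEG channels after exclusions")
    X = rec.samples[eeg]
    L = grid.epoch_samples
    centers = grid.center_times(rec.t0)
    values = np.empty(grid.n_epochs)
    for k, s0 in enumerate(grid.start_indices):
        spec = gfs_spectrum(
            X[:, s0:s0 + L], rec.sampling_rate, center=config.center_scatter,
            epoch_index=k, epoch_center_time=centers[k],
        )
        values[k] = band_average(spec, config.band_low, config.band_high)
    return FeatureSeries(
        name="gfs_beta", units="", times=centers, values=values,
        subject_id=recording.subject_id,
    )


def subject_gfs_spectra(recording: Recording, config: GFSConfig = GFSConfig()) -> list[GFSSpectrum]:
    """Full per-epoch spectra (for the CSV spectrum table export)."""
    rec = _preprocessed_eeg(recording, config)
    grid = make_epochs(rec, config.epoch_length, config.overlap)
    eeg = rec.channels_with_role("EEG")
    X = rec.samples[eeg]
    L = grid.epoch_samples
    centers = grid.center_times(rec.t0)
    return [
        gfs_spectrum(
            X[:, s0:s0 + L], rec.sampling_rate, center=config.center_scatter,
            epoch_index=k, epoch_center_time=centers[k],
        )
        for k, s0 in enumerate(grid.start_indices)
    ]


def band_psd_series(
    recording: Recording,
    channel: str,
    low: float,
    high: float,
    config: GFSConfig = GFSConfig(),
) -> FeatureSeries:
    """Per-epoch mean band power for one channel on the GFS epoch grid.

    Used for the muscle-artifact control: beta power at the temporal
    electrodes should not track the GFS waveform.  The channel is taken from
    the *raw* recording (band-passed only), so artifact power is visible.
    """
    if channel not in recording.channel_labels:
        raise ConfigurationError(f"unknown channel {channel!r}")
    rec = bandpass(remove_dc(recording), config.bandpass_low, config.bandpass_high)
    if config.decimate_to is not None and rec.sampling_rate > config.decimate_to:
        rec = decimate(rec, config.decimate_to)
    grid = make_epochs(rec, config.epoch_length, config.overlap)
    x = rec.samples[rec.channel_labels.index(channel)]
    L = grid.epoch_samples
    centers = grid.center_times(rec.t0)
    values = np.empty(grid.n_epochs)
    for k, s0 in enumerate(grid.start_indices):
        f, pxx = signal.periodogram(x[s0:s0 + L], fs=rec.sampling_rate, window="hann")
        mask = (f >= low) & (f <= high)
        if not np.any(mask):
            raise ConfigurationError(f"no bins inside [{low}, {high}] Hz")
        values[k] = np.mean(pxx[mask])
    return FeatureSeries(
        name=f"psd_{channel}_{low:g}-{high:g}Hz", units="power",
        times=centers, values=values, subject_id=recording.subject_id,
    )
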