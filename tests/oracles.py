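"""Independent reference implementations used only by the tests.

Each function recomputes a pipeline quantity by a different route than the
package (explicit DFT, closed-form eigenvalues, straight-line chains,
textbook formulas) so agreement is evidence of correctness, not tautology.
"""

import numpy as np
from scipy import signal
from scipy.special import betainc


def dft_matrix(L: int) -> np.ndarray:
    """Explicit one-sided DFT matrix (independent of np.fft)."""
    n = np.arange(L)
    k = np.arange(L // 2 + 1)
    return np.exp(-2j * np.pi * np.outer(k, n) / L)


def gfs_closed_form(epoch: np.ndarray, taper: np.ndarray) -> np.ndarray:
    """Per-bin GFS via explicit DFT and the characteristic quadratic.

    Builds the scatter [[sum Re^2, sum Re Im], [sum Re Im, sum Im^2]] per
    frequency bin and solves its characteristic polynomial in closed form:
    E_{1,2} = (tr +/- sqrt((a-c)^2 + 4 b^2)) / 2, GFS = sqrt(...) / tr.
    """
    F = dft_matrix(epoch.shape[1])
    coeffs = (epoch * taper) @ F.T
    re, im = coeffs.real, coeffs.imag
    a = np.sum(re * re, axis=0)
    b = np.sum(re * im, axis=0)
    c = np.sum(im * im, axis=0)
    tr = a + c
    disc = np.sqrt((a - c) ** 2 + 4.0 * b * b)
    out = np.full(len(tr), np.nan)
    ok = tr > 0
    out[ok] = disc[ok] / tr[ok]
    return out


def frame_rms_direct(x: np.ndarray, L: int, H: int) -> np.ndarray:
    """Per-frame RMS by the direct formula."""
    n_frames = (len(x) - L) // H + 1
    return np.array(
        [np.sqrt(np.sum(x[k * H:k * H + L] ** 2) / L) for k in range(n_frames)]
    )


def band_psd_direct(x: np.ndarray, fs: float, low: float, high: float) -> float:
    """Mean one-sided Hann-windowed periodogram density over a band."""
    L = len(x)
    w = signal.get_window("hann", L)
    X = dft_matrix(L) @ (x * w)
    pxx = (np.abs(X) ** 2) / (fs * np.sum(w**2))
    pxx[1:] *= 2.0
    if L % 2 == 0:
        pxx[-1] /= 2.0
    f = np.arange(L // 2 + 1) * fs / L
    mask = (f >= low) & (f <= high)
    return float(np.mean(pxx[mask]))


def gsr_chain_direct(x: np.ndarray, fs: float = 16.0) -> np.ndarray:
    """Straight-line GSR chain on data already at 16 Hz.

    Low-pass (0.2 Hz, order-3 Butterworth, zero phase) -> least-squares line
    removal -> first difference -> explicit 20-point Bartlett convolution ->
    z-score.
    """
    sos = signal.butter(3, 0.2, btype="lowpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    t = np.arange(len(y), dtype=float)
    A = np.column_stack([t, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    y = y - A @ coef
    y = y[1:] - y[:-1]
    y = _bartlett_direct(y, 20)
    return (y - y.mean()) / y.std()


def ppg_chain_direct(x: np.ndarray, fs: float) -> np.ndarray:
    """Straight-line PPG chain: 0.5-5 Hz order-3 zero-phase band-pass ->
    first difference -> 20-point Bartlett -> z-score."""
    sos = signal.butter(3, [0.5, 5.0], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    y = y[1:] - y[:-1]
    y = _bartlett_direct(y, 20)
    return (y - y.mean()) / y.std()


def _bartlett_direct(x: np.ndarray, points: int) -> np.ndarray:
    """'same'-mode convolution with a unit-sum Bartlett window, by loops."""
    w = np.bartlett(points)
    w = w / w.sum()
    full = np.zeros(len(x) + points - 1)
    for i, xi in enumerate(x):
        full[i:i + points] += xi * w
    start = (points - 1) // 2
    return full[start:start + len(x)]


def scr_scan_direct(t: np.ndarray, v: np.ndarray):
    """Exhaustive scan for positive lobes between -/+ and +/- sign changes.

    Returns (onset_idx, offset_idx, peak_idx, peak_value) tuples using plain
    per-sample iteration.
    """
    out = []
    inside = False
    start = None
    for i in range(len(v) - 1):
        if not inside and v[i] <= 0 < v[i + 1]:
            inside = True
            start = i
        elif inside and v[i] > 0 >= v[i + 1]:
            seg = range(start + 1, i + 1)
            peak = max(seg, key=lambda j: v[j])
            out.append((start, i, peak, v[peak]))
            inside = False
    return out


def paired_t_direct(x: np.ndarray, y: np.ndarray):
    """Textbook paired t: t = mean(d) / (sd(d)/sqrt(n)); two-tailed p via
    the regularized incomplete beta function."""
    d = np.asarray(x, float) - np.asarray(y, float)
    n = len(d)
    dbar = d.sum() / n
    sd = np.sqrt(np.sum((d - dbar) ** 2) / (n - 1))
    t = dbar / (sd / np.sqrt(n))
    df = n - 1
    p = betainc(df / 2.0, 0.5, df / (df + t * t))
    return t, p


def mean_sd_two_pass(values) -> tuple[float, float]:
    """Two-pass sample mean / sd."""
    v = np.asarray(values, float)
    m = v.sum() / len(v)
    sd = np.sqrt(np.sum((v - m) ** 2) / (len(v) - 1)) if len(v) > 1 else 0.0
    return float(m), float(sd)
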