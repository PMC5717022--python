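"""Group-level waveforms, threshold lines, excursion events and statistics.

Per-subject feature series are grand-averaged, smoothed with a ten-point
moving average, and bracketed by horizontal lines at the waveform's overall
mean +/- 1.96 times its temporal standard deviation (the two-sided normal
5% criterion).  Intervals where the waveform crosses a line are the
candidate emotional highlights; they are compared with the questionnaire
ground truth and with the within-subject event-vs-nonevent contrast (paired
t-test).

Polarity is explicit per stream: arousal *lowers* global field
synchronization (``below`` excursions) but *raises* SCR amplitude, heart
rate and loudness (``above``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import ConfigurationError, FeatureSeries, GroundTruthTimeline

__all__ = [
    "GroupWaveform",
    "HighlightEvent",
    "MatchReport",
    "PairedTestResult",
    "resample_to_grid",
    "grand_average",
    "moving_average",
    "threshold_lines",
    "build_group_waveform",
    "detect_excursions",
    "match_events",
    "event_vs_nonevent_test",
    "subject_mean_variability",
]

DEFAULT_K = 1.96  # two-sided normal criterion at p = 0.05
SECONDARY_K = 1.5  # near-threshold "gray area" criterion
DEFAULT_MIN_DURATION_S = 1.0
DEFAULT_MERGE_GAP_S = 2.0


@dataclass
class HighlightEvent:
    """An interval where the group waveform exceeds a threshold line."""

    start: float
    end: float
    polarity: str  # below | above
    extremum_time: float
    extremum_value: float
    label: str | None = None

    def __post_init__(self) -> None:
        if self.polarity not in ("below", "above"):
            raise ConfigurationError("polarity must be 'below' or 'above'")
        if not self.start < self.end:
            raise ConfigurationError("event start must precede end")
        if not self.start <= self.extremum_time <= self.end:
            raise ConfigurationError("extremum must lie inside the event")


@dataclass
class GroupWaveform:
    """Smoothed grand-average waveform with its threshold lines."""

    mean_series: FeatureSeries
    n_subjects: int
    time_sd: float
    upper_line: float
    lower_line: float
    smoothing_points: int
    k: float = DEFAULT_K

    def __post_init__(self) -> None:
        if not self.lower_line < self.upper_line:
            raise ConfigurationError("lower line must sit below upper line")


@dataclass
class MatchReport:
    """Detected events vs questionnaire histogram modes."""

    matches: list[dict]  # per event: label/extremum_time/matched_mode/offset
    hits: int
    misses: int
    false_alarms: int
    tolerance: float
    modes: list[float]


@dataclass
class PairedTestResult:
    t: float
    p: float
    df: int
    pairs: list[tuple[str, float, float]]  # (subject, in-event mean, out mean)
    degenerate: bool = False  # zero-variance nonzero difference


# ---------------------------------------------------------------------------
# averaging and thresholding
# ---------------------------------------------------------------------------


def resample_to_grid(series: FeatureSeries, grid: np.ndarray) -> FeatureSeries:
    """Linear interpolation of a series onto a common time grid.

    Grid points outside the series' support become gaps (NaN).
    """
    v = np.interp(grid, series.times, series.values, left=np.nan, right=np.nan)
    inside = (grid >= series.times[0] - 1e-12) & (grid <= series.times[-1] + 1e-12)
    v[~inside] = np.nan
    return FeatureSeries(
        name=series.name, units=series.units, times=np.asarray(grid, float),
        values=v, subject_id=series.subject_id,
    )


def grand_average(series_list: list[FeatureSeries]) -> FeatureSeries:
    """Pointwise mean across subjects on the first series' grid.

    Series must share a common grid (use :func:`resample_to_grid` first if
    they do not).  Gaps are excluded pointwise; a grid point where every
    subject has a gap stays a gap.
    """
    if len(series_list) < 2:
        raise ConfigurationError("grand average needs >= 2 series")
    ref = series_list[0].times
    for s in series_list[1:]:
        if s.times.shape != ref.shape or not np.allclose(s.times, ref, atol=1e-9):
            raise ConfigurationError(
                "series are not on a common time grid; resample first"
            )
    stack = np.vstack([s.values for s in series_list])
    n_valid = np.sum(~np.isnan(stack), axis=0)
    if np.all(n_valid == 0):
        raise ConfigurationError("series have disjoint support; nothing to average")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    return FeatureSeries(
        name=series_list[0].name, units=series_list[0].units,
        times=ref.copy(), values=mean, subject_id="group",
    )


def moving_average(series: FeatureSeries, points: int = 10) -> FeatureSeries:
    """Centered boxcar smoother with shrinking windows at the edges.

    For even ``points`` the window at index i spans ``[i - points//2,
    i + (points-1)//2]``; output length equals input length.
    """
    if points < 1:
        raise ConfigurationError("points must be >= 1")
    v = series.values
    n = len(v)
    out = np.empty(n)
    lo_off, hi_off = points // 2, (points - 1) // 2
    for i in range(n):
        a, b = max(0, i - lo_off), min(n, i + hi_off + 1)
        win = v[a:b]
        win = win[~np.isnan(win)]
        out[i] = np.mean(win) if win.size else np.nan
    return FeatureSeries(
        name=series.name, units=series.units, times=series.times.copy(),
        values=out, subject_id=series.subject_id,
    )


def threshold_lines(series: FeatureSeries, k: float = DEFAULT_K) -> tuple[float, float]:
    """Horizontal lines at overall mean +/- k * temporal standard deviation.

    The sd is the sample standard deviation over time of the smoothed
    grand-average waveform (the lines are horizontal, so the dispersion is
    temporal, not across subjects).
    """
    v = series.values[~np.isnan(series.values)]
    if v.size < 2:
        raise ConfigurationError("need >= 2 defined points for threshold lines")
    m = float(np.mean(v))
    s = float(np.std(v, ddof=1))
    if s == 0:
        raise ConfigurationError("constant series: threshold lines undefined")
    return m + k * s, m - k * s


def build_group_waveform(
    series_list: list[FeatureSeries],
    smoothing_points: int = 10,
    k: float = DEFAULT_K,
) -> GroupWaveform:
    """Grand average -> moving average -> threshold lines, in one call."""
    smoothed = moving_average(grand_average(series_list), smoothing_points)
    upper, lower = threshold_lines(smoothed, k)
    v = smoothed.values[~np.isnan(smoothed.values)]
    return GroupWaveform(
        mean_series=smoothed, n_subjects=len(series_list),
        time_sd=float(np.std(v, ddof=1)), upper_line=upper, lower_line=lower,
        smoothing_points=smoothing_points, k=k,
    )


# ---------------------------------------------------------------------------
# excursion detection and evaluation
# ---------------------------------------------------------------------------


def detect_excursions(
    series: FeatureSeries,
    line: float,
    polarity: str,
    min_duration: float = DEFAULT_MIN_DURATION_S,
    merge_gap: float = DEFAULT_MERGE_GAP_S,
) -> list[HighlightEvent]:
    """Maximal runs of samples beyond a threshold line.

    Runs separated by less than ``merge_gap`` seconds are merged; merged
    runs shorter than ``min_duration`` are dropped.  Event start/end are the
    first/last sample times beyond the line; the extremum is the most
    extreme sample in the event.
    """
    if polarity not in ("below", "above"):
        raise ConfigurationError("polarity must be 'below' or 'above'")
    t, v = series.times, series.values
    with np.errstate(invalid="ignore"):
        beyond = (v < line) if polarity == "below" else (v > line)
    beyond &= ~np.isnan(v)
    if not np.any(beyond):
        return []
    dt = series.dt if len(series) >= 2 else 0.0

    # maximal runs of consecutive beyond-samples
    idx = np.flatnonzero(beyond)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = [(int(g[0]), int(g[-1])) for g in np.split(idx, breaks + 1)]

    # merge runs whose gap is < merge_gap seconds; a run's interval extends
    # one sample step past its last sample
    merged: list[list[int]] = [list(runs[0])]
    for a, b in runs[1:]:
        if (t[a] - (t[merged[-1][1]] + dt)) < merge_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    events: list[HighlightEvent] = []
    for a, b in merged:
        # a run of one sample still occupies one sample interval
        duration = t[b] - t[a] + dt
        if duration < min_duration:
            continue
        seg = v[a:b + 1]
        seg = np.where(np.isnan(seg), line, seg)  # gaps can't be extrema
        k = int(np.argmin(seg) if polarity == "below" else np.argmax(seg)) + a
        events.append(
            HighlightEvent(
                start=float(t[a]), end=float(t[b] + dt), polarity=polarity,
                extremum_time=float(t[k]), extremum_value=float(v[k]),
            )
        )
    return events


def match_events(
    events: list[HighlightEvent],
    truth: GroundTruthTimeline,
    tolerance: float = 10.0,
    clip_id: str | None = None,
    duration: float | None = None,
) -> MatchReport:
    """Greedy matching of detected events to questionnaire histogram modes.

    The two most populated histogram bins per clip are the ground-truth
    modes.  Events are matched to the nearest unmatched mode within
    ``tolerance`` seconds of their extremum (ties break to the earlier
    mode); unmatched modes are misses, unmatched events false alarms.
    """
    if not truth.picks:
        raise ConfigurationError("ground-truth timeline is empty")
    cid = clip_id if clip_id is not None else truth.clip_ids()[0]
    modes = truth.modes(cid, duration)

    unmatched = list(range(len(modes)))
    matches: list[dict] = []
    hits = 0
    # match events in extremum order for determinism
    for ev in sorted(events, key=lambda e: e.extremum_time):
        best = None
        for j in unmatched:
            off = abs(ev.extremum_time - modes[j])
            if off <= tolerance and (best is None or off < best[1] - 1e-12):
                best = (j, off)
        rec = {
            "label": ev.label,
            "extremum_time": ev.extremum_time,
            "matched_mode": None,
            "offset": None,
        }
        if best is not None:
            j, off = best
            unmatched.remove(j)
            rec["matched_mode"] = float(modes[j])
            rec["offset"] = float(ev.extremum_time - modes[j])
            hits += 1
        matches.append(rec)
    misses = len(unmatched)
    false_alarms = len(events) - hits
    return MatchReport(
        matches=matches, hits=hits, misses=misses, false_alarms=false_alarms,
        tolerance=tolerance, modes=[float(m) for m in modes],
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def _interval_mask(times: np.ndarray, intervals: list[tuple[float, float]]) -> np.ndarray:
    m = np.zeros(len(times), dtype=bool)
    for a, b in intervals:
        m |= (times >= a) & (times <= b)
    return m


def event_vs_nonevent_test(
    per_subject_series: list[FeatureSeries],
    events: list[HighlightEvent],
    secondary_events: list[HighlightEvent] | None = None,
    secondary: str = "exclude",
) -> PairedTestResult:
    """Two-tailed paired t-test of in-event vs out-of-event subject means.

    For each subject the feature is averaged over time points inside the
    detected events and over the remaining time points, and the paired
    difference is tested across subjects (df = n - 1).  Near-threshold
    secondary events can be counted as events (``secondary="event"``),
    as non-events (``"nonevent"``) or excluded from both sets (default).
    """
    if len(per_subject_series) < 3:
        raise ConfigurationError("paired test needs >= 3 subjects")
    if not events:
        raise ConfigurationError("no events to test")
    if secondary not in ("event", "nonevent", "exclude"):
        raise ConfigurationError("secondary must be event, nonevent or exclude")

    ev_iv = [(e.start, e.end) for e in events]
    sec_iv = [(e.start, e.end) for e in (secondary_events or [])]
    if secondary == "event":
        ev_iv += sec_iv
        sec_iv = []

    pairs: list[tuple[str, float, float]] = []
    for s in per_subject_series:
        in_mask = _interval_mask(s.times, ev_iv)
        out_mask = ~in_mask
        if secondary == "exclude" and sec_iv:
            sec_mask = _interval_mask(s.times, sec_iv)
            in_mask &= ~sec_mask
            out_mask &= ~sec_mask
        in_mask &= ~np.isnan(s.values)
        out_mask &= ~np.isnan(s.values)
        if not np.any(in_mask):
            raise ConfigurationError(f"subject {s.subject_id!r} has no in-event samples")
        if not np.any(out_mask):
            raise ConfigurationError(f"subject {s.subject_id!r} has no out-of-event samples")
        pairs.append(
            (s.subject_id, float(np.mean(s.values[in_mask])), float(np.mean(s.values[out_mask])))
        )

    d = np.array([a - b for _, a, b in pairs])
    n = len(d)
    df = n - 1
    sd = np.std(d, ddof=1)
    if sd <= 1e-12 * np.max(np.abs(d), initial=0.0):
        if np.allclose(d, 0.0):
            return PairedTestResult(t=0.0, p=1.0, df=df, pairs=pairs)
        # constant nonzero difference: t diverges; report as p -> 0 with a flag
        return PairedTestResult(
            t=float(np.inf) * np.sign(d[0]), p=0.0, df=df, pairs=pairs, degenerate=True
        )
    tstat = float(np.mean(d) / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(tstat), df))
    return PairedTestResult(t=tstat, p=p, df=df, pairs=pairs)


def subject_mean_variability(
    per_subject_series: list[FeatureSeries],
) -> tuple[float, float]:
    """Across-subject mean +/- sd of the per-subject temporal means.

    This is the "0.488 +/- 0.026"-style summary: how much the average level
    of the feature varies from individual to individual.
    """
    means = []
    for s in per_subject_series:
        v = s.values[~np.isnan(s.values)]
        if v.size == 0:
            raise ConfigurationError(f"subject {s.subject_id!r} has no defined samples")
        means.append(float(np.mean(v)))
    means_arr = np.array(means)
    sd = float(np.std(means_arr, ddof=1)) if len(means_arr) > 1 else 0.0
    return float(np.mean(means_arr)), sd
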