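"""Plotting: group waveform with threshold lines and detected highlights."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .highlights import GroupWaveform, HighlightEvent

__all__ = ["plot_group_waveform"]


def plot_group_waveform(
    waveform: GroupWaveform,
    events: list[HighlightEvent],
    secondary_events: list[HighlightEvent] | None = None,
    path: str | Path | None = None,
    title: str = "",
):
    """Waveform, mean +/- k*sd lines, and shaded highlight intervals.

    Writes to ``path`` (format from suffix, e.g. .svg/.png) when given,
    otherwise returns the figure.
    """
    s = waveform.mean_series
    fig, ax = plt.subplots(figsize=(9, 3))
    ax.plot(s.times, s.values, color="k", lw=1.2)
    for y, style in ((waveform.upper_line, "-"), (waveform.lower_line, "-")):
        ax.axhline(y, color="tab:blue", ls=style, lw=0.9)
    for e in secondary_events or []:
        ax.axvspan(e.start, e.end, color="0.85")
    for e in events:
        ax.axvspan(e.start, e.end, color="tab:red", alpha=0.25)
        ax.annotate(e.label or "", (e.extremum_time, e.extremum_value),
                    textcoords="offset points", xytext=(0, -12), ha="center",
                    fontsize=8)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(f"{s.name} ({s.units})" if s.units else s.name)
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
        return None
    return fig
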