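#!/usr/bin/env python
"""Detect emotional-highlight intervals in every group waveform and match
them against the questionnaire ground truth.

GFS excursions are *below* the lower 1.96-sd line (arousal desynchronizes
the EEG); SCR, heart-rate and loudness excursions are *above* the upper
line.  Writes results/highlights/{stream}_events.json and a summary table.
"""

import json
from pathlib import Path

from gfstrack.config import RunConfig
from gfstrack.core_io import read_series, read_timeline
from gfstrack.highlights import detect_excursions, match_events, threshold_lines
from gfstrack.pipeline import POLARITY, events_to_json

ROOT = Path(__file__).resolve().parent.parent / "results"
WAVEFORMS = {
    "gfs": ROOT / "gfs" / "gfs_group_waveform.csv",
    "scr": ROOT / "peripheral" / "scr_group_waveform.csv",
    "hr": ROOT / "peripheral" / "hr_group_waveform.csv",
    "rms": ROOT / "audio" / "rms_energy.csv",
}


def main() -> None:
    cfg = RunConfig.load(ROOT / "data" / "run_config.yaml")
    truth = read_timeline(ROOT / "data" / "ground_truth.csv", bin_width=cfg.bin_width,
                          clip_duration=cfg.clip_duration)
    out = ROOT / "highlights"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, path in WAVEFORMS.items():
        series = read_series(path)
        if name == "rms":
            from gfstrack.highlights import moving_average

            series = moving_average(series, cfg.smoothing_points)
        upper, lower = threshold_lines(series, cfg.k)
        polarity = POLARITY[name]
        line = lower if polarity == "below" else upper
        events = detect_excursions(series, line, polarity,
                                   cfg.min_duration, cfg.merge_gap)
        for i, e in enumerate(events, 1):
            e.label = f"{name.upper()}{i}"
        report = match_events(events, truth, cfg.match_tolerance,
                              duration=cfg.clip_duration)
        (out / f"{name}_events.json").write_text(json.dumps({
            "upper_line": upper, "lower_line": lower,
            "events": events_to_json(events),
            "match": {"hits": report.hits, "misses": report.misses,
                      "false_alarms": report.false_alarms,
                      "modes_s": report.modes},
        }, indent=2))
        rows.append((name, len(events), report.hits, report.misses,
                     report.false_alarms))
        spans = ", ".join(f"{e.label} {e.start:.0f}-{e.end:.0f}s" for e in events)
        print(f"{name:>4}: {spans or 'no events'}")
    print()
    print("stream  events  hits  misses  false_alarms")
    for r in rows:
        print(f"{r[0]:>6}  {r[1]:>6}  {r[2]:>4}  {r[3]:>6}  {r[4]:>12}")
    print(f"(questionnaire modes at {truth.modes(truth.clip_ids()[0]).round(0)} s)")


if __name__ == "__main__":
    main()
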