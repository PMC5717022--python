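#!/usr/bin/env python
"""Peripheral arousal features per subject: the windowed skin-conductance
response (SCR) amplitude stream and the photoplethysmographic heart-rate
stream, plus their group waveforms.

Reads results/data/, writes results/peripheral/.
"""

import importlib.util
from pathlib import Path

import numpy as np

from gfstrack.config import RunConfig
from gfstrack.core_io import read_recording, write_series
from gfstrack.highlights import build_group_waveform
from gfstrack.peripheral import subject_hr_series, subject_scr_series

ROOT = Path(__file__).resolve().parent.parent / "results"
_mod02 = importlib.util.spec_from_file_location(
    "a02", Path(__file__).with_name("02_gfs.py")
)
a02 = importlib.util.module_from_spec(_mod02)
_mod02.loader.exec_module(a02)


def main() -> None:
    cfg = RunConfig.load(ROOT / "data" / "run_config.yaml")
    out = ROOT / "peripheral"
    out.mkdir(parents=True, exist_ok=True)
    scr_series, hr_series_list = [], []
    for path in sorted((ROOT / "data").glob("sub*.bdf")):
        rec = read_recording(path, a02.role_map())
        scr = subject_scr_series(rec, cfg.scr_window)
        hr = subject_hr_series(rec, grid_step=cfg.hop)
        write_series(scr, out / f"scr_{rec.subject_id}.csv")
        write_series(hr, out / f"hr_{rec.subject_id}.csv")
        scr_series.append(scr)
        hr_series_list.append(hr)
        print(f"{rec.subject_id}: mean HR {np.mean(hr.values):.1f} bpm, "
              f"SCR stream peak {np.max(scr.values):.2f} z")
    for name, series in (("scr", scr_series), ("hr", hr_series_list)):
        wf = build_group_waveform(series, cfg.smoothing_points, cfg.k)
        write_series(wf.mean_series, out / f"{name}_group_waveform.csv")
        print(f"{name} group waveform: lines [{wf.lower_line:.3f}, {wf.upper_line:.3f}]")


if __name__ == "__main__":
    main()
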