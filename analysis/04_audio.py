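#!/usr/bin/env python
"""Stimulus-side loudness cue: framewise RMS energy of the clip audio on
the same 2-s/1-s grid as the EEG epochs.

Reads results/data/stimulus.wav, writes results/audio/rms_energy.csv.
"""

from pathlib import Path

import numpy as np

from gfstrack.audio import frame_rms, read_audio
from gfstrack.config import RunConfig
from gfstrack.core_io import write_series

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = RunConfig.load(ROOT / "data" / "run_config.yaml")
    out = ROOT / "audio"
    out.mkdir(parents=True, exist_ok=True)
    track = read_audio(ROOT / "data" / "stimulus.wav")
    rms = frame_rms(track, cfg.frame_length, cfg.hop)
    write_series(rms, out / "rms_energy.csv")
    loud = rms.values > 2.0 * np.median(rms.values)
    print(f"{len(rms)} frames; {loud.sum()} frames exceed 2x median energy "
          f"(loud passages at t = {rms.times[loud][:5].round(0)} ... s)")


if __name__ == "__main__":
    main()
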