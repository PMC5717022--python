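#!/usr/bin/env python
"""Simulate the study's raw data: a 10-subject multimodal group watching a
120-s clip with two planted emotional highlights, plus a 37-respondent
questionnaire ground truth.

Writes BDF recordings, the stimulus WAV and the ground-truth CSV under
results/data/.
"""

from pathlib import Path

import numpy as np

from gfstrack.audio import AudioTrack, write_audio
from gfstrack.config import RunConfig
from gfstrack.core_io import write_recording, write_timeline
from gfstrack.synthetic import (
    GroupConfig,
    default_script,
    simulate_audio,
    simulate_questionnaire,
    simulate_subject,
)

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    cfg = RunConfig(seed=SEED)
    script = default_script(cfg.clip_duration)
    gc = GroupConfig(
        n_subjects=cfg.n_subjects, n_eeg_channels=cfg.n_eeg_channels,
        sampling_rate=cfg.sampling_rate, baseline_sync=cfg.baseline_sync,
        noise_sd=cfg.noise_sd, seed=cfg.seed,
    )
    OUT.mkdir(parents=True, exist_ok=True)
    for i in range(cfg.n_subjects):
        rec = simulate_subject(script, gc, i)
        write_recording(rec, OUT / f"{rec.subject_id}.bdf", "BDF")
    wave = simulate_audio(script, cfg.sampling_rate, cfg.seed)
    write_audio(AudioTrack(np.clip(wave, -1, 1), cfg.sampling_rate), OUT / "stimulus.wav")
    truth = simulate_questionnaire(
        script, cfg.n_respondents, cfg.jitter_sd, cfg.seed, bin_width=cfg.bin_width
    )
    write_timeline(truth, OUT / "ground_truth.csv")
    cfg.dump(OUT / "run_config.yaml")
    planted = [(e.kind, e.start, e.end, e.magnitude) for e in script.events]
    print(f"wrote {cfg.n_subjects} subjects x {script.duration:.0f} s to {OUT}")
    print(f"planted events: {planted}")


if __name__ == "__main__":
    main()
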