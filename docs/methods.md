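# Methods

## The problem

When a group of people watches the same film, moments of high emotional
arousal leave traces in several physiological channels at once.  This
package implements a group-level arousal-tracking pipeline built around one
EEG statistic — beta-band **global field synchronization (GFS)** — with
three companion streams (electrodermal activity, pulse-derived heart rate,
and stimulus loudness), a threshold rule that turns the group waveforms
into discrete "emotional highlight" intervals, and a questionnaire-style
ground truth for evaluating them.  The premise is that intense emotional
processing *desynchronizes* large-scale beta-band cortical activity, so
highlights appear as dips in the group GFS waveform while the peripheral
streams rise.

## Global field synchronization

For one 2-s epoch of C EEG channels, each channel is tapered (periodic
Hann) and Fourier transformed.  At frequency f the C complex coefficients
form C points (Re, Im) in the complex plane.  Let

    M(f) = [[sum Re^2, sum Re*Im], [sum Re*Im, sum Im^2]]

be their non-centered 2x2 scatter with eigenvalues E1 >= E2 >= 0.  Then

    GFS(f) = |E1 - E2| / (E1 + E2).

GFS(f) = 1 when the coefficients are collinear — all channels oscillate
with a single common phase axis (sign flips allowed) — and 0 when the
phases are isotropic.  GFS is invariant to channel order, to multiplying
all channels by a common nonzero factor, and to a common circular shift of
the tapered frame.  It is *not* corrected for channel count: C independent
channels give a positive baseline value (roughly C^-1/2 scaling), so only
within-recording changes are interpreted, never absolute levels.

Two conventions were genuinely open:

* **Non-centered scatter** (second moment, not covariance) is the default,
  matching the sine/cosine-coefficient convention of the GFS literature;
  `center=true` exposes the mean-centered alternative.
* **Band summary** is the arithmetic mean of per-bin GFS over the closed
  interval 14–25 Hz (23 bins at 0.5 Hz resolution), not the GFS of summed
  eigenvalues.  Bins with zero total power are undefined (gaps), never 0.

### Subject-level chain

common average reference (EEG channels only) → per-channel DC removal →
1–55 Hz zero-phase Butterworth band-pass (order 4; forward–backward
application doubles the effective order, giving ≥ 20 dB at 0.5 and
110 Hz) → PCA-based blink removal → optional anti-aliased decimation to
256 Hz → 2-s epochs with 50% overlap → per-epoch beta-band GFS, stamped at
epoch centers.

Blink removal decomposes the EEG submatrix by SVD and projects out
components whose absolute temporal correlation with any EOG channel
exceeds 0.7 (a conservative default: only clearly blink-driven components
go).  A channel-exclusion list supports control analyses such as dropping
the temporal electrodes T7/T8; `band_psd_series` provides the companion
control of per-epoch beta power at a single electrode.

## Peripheral chains

**GSR** (16 Hz): decimate → 0.2 Hz third-order Butterworth zero-phase
low-pass → linear detrend → first difference → 20-point Bartlett smoothing
(unit-sum, amplitude-preserving) → z-score.  Skin conductance responses
(SCRs) are maximal positive lobes of this signal between a −/+ zero
crossing and the following +/− crossing (crossing times linearly
interpolated); the feature stream is the mean SCR peak amplitude inside a
6-s window hopped one sample at a time, with 0 (not a gap) where no SCR
falls.

Three numerical choices matter here.  (1) *Edge trimming*: 10 s at each end
(4 s for PPG) are discarded before normalization — the zero-phase filters'
settle transients live there, and z-scoring would otherwise inflate them
into spurious lobes.  (2) *Degenerate records*: if the signal entering the
z-score is numerically constant (spread below 1e-5 of the pre-difference
scale — e.g. a drift-only channel, which the chain nulls exactly in ideal
arithmetic), the output is flat zero rather than unit-variance round-off.
(3) *Amplitude floor*: SCR counting ignores lobes with peak below 0.1 z,
the z-scale analog of the minimum-amplitude criterion (classically
0.01 µS) that is standard in electrodermal response counting.  Without a
floor the rule is ill-posed: the 0.2 Hz zero-phase filter rings
symmetrically around every response, manufacturing satellite lobes of a
few percent of the response amplitude.

**PPG**: 0.5–5 Hz third-order Butterworth zero-phase band-pass → first
difference → Bartlett smoothing → z-score.  Pulse peaks are local maxima
above half the series' 95th percentile with a 0.33-s refractory separation
(caps detection at ~180 bpm); flat-peak ties break to the earlier sample.
Each peak-to-peak interval (PPI) contributes HR = 60/PPI bpm at the
interval midpoint, linearly interpolated onto a uniform grid.

**Audio**: framewise RMS energy, 2-s frames with 1-s hop so the loudness
stream shares the EEG epoch grid; the final partial frame is dropped.

## Group waveforms and highlight detection

Per-subject series on a common grid are averaged pointwise (gaps excluded
per point), smoothed with a ten-point centered moving average (shrinking
windows at the edges, output length preserved), and bracketed by horizontal
lines at overall mean ± k·sd, where sd is the *temporal* sample standard
deviation of the smoothed waveform and k = 1.96, the two-sided normal
criterion at p = 0.05.  The dispersion is temporal, not across-subject:
horizontal lines require a single scalar sd.

Excursions beyond a line (below it for GFS, above it for SCR/HR/loudness —
polarity is declared per stream, never inferred) become highlight events:
maximal runs, runs separated by < 2 s merged, merged runs shorter than 1 s
dropped, extremum recorded per event.  A second threshold at k = 1.5 marks
near-threshold "gray areas"; gray intervals overlapping a primary event are
discarded as redundant.

Ground truth is a histogram of questionnaire picks (default 10-s bins); the
two most populated bins per clip are the reference modes.  Events match
modes greedily by extremum distance within a tolerance (default 10 s, one
bin); ties break to the earlier mode.  The event-vs-nonevent contrast
averages each subject's feature inside vs outside the detected events and
applies a two-tailed paired t-test (df = n−1).  Gray areas are excluded
from *both* sets by default (`secondary="exclude"`); counting them as
events or non-events is a flag away.  A zero-variance nonzero difference is
reported as p → 0 with a `degenerate` flag rather than a fabricated
statistic.  No multiple-comparison correction is applied — one test per
clip.

## The synthetic group

No recordings ship with the package; the generator produces groups with
exactly the structure the analysis assumes, and the tests quantify recovery
of what was planted.

* **EEG**: channel i carries `g_i * (sqrt(s(t))*S + sqrt(1-s(t))*N_i)` plus
  pink noise, where S and the N_i are unit-variance 14–25 Hz narrowband
  noises and s(t) is the synchronization profile: `baseline_sync` (default
  0.7) outside `desync` events, `baseline_sync*(1-magnitude)` inside.  The
  gains g_i have magnitude Uniform(0.6, 1.4) and *random sign*, a
  dipolar-like scalp projection; sign diversity is essential because a
  uniformly projected source is exactly cancelled by the common average
  reference, while GFS itself is indifferent to sign flips (collinear
  points).  Blinks (~12/min, 0.3-s biphasic pulses) ride on the vertical
  EOG and leak into the frontal channels with fixed gains.
* **GSR**: linear tonic drift plus one SCR kernel (difference of
  exponentials, 1-s rise, 3-s decay — module constants, not science) per
  `scr_burst` event, onset jittered ≤ 1 s, amplitude proportional to event
  magnitude.  The drift is linear *by design*: detrending and
  differentiation null it exactly, so at zero noise the only lobes are the
  planted responses.
* **PPG**: fixed pulse kernels at intervals 60/HR(t), HR(t) = 70 bpm plus
  20·magnitude bpm inside `hr_rise` events.
* **Audio**: white noise with envelope a0 outside `loud` events and
  a0·(1+3·magnitude) inside (a magnitude-1 event is 4× baseline RMS).
* **Questionnaire**: each respondent picks the two largest-magnitude
  moments with Gaussian jitter (sd 2 s), clipped to the clip.

All generators are pure functions of (script, config, seed, subject index).

### Default study scale

10 subjects, 12 EEG + 2 EOG channels, 256 Hz, a 120-s clip with two 10-s
magnitude-0.8 highlights (centers 35 s and 85 s) and one weak mid-clip SCR
moment, 37 questionnaire respondents.  The channel count, subject count and
rate are a desk-scale reduction of a realistic 22-channel, 25-subject,
2048-Hz study; GFS is dimensionless and the detection mechanics are
scale-free, so behavior is preserved while the full test suite stays under
a minute of simulation per group.

The clip length is not arbitrary.  The threshold lines sit at a multiple of
the waveform's own temporal sd, so the planted dips contribute to the very
dispersion they must exceed.  A deterministic shape analysis (two
rectangular unit dips, 1-s hop, 10-point smoothing) shows the dip minimum
reaches z = −(min−mean)/sd of at best 1.96 in a 60-s record — detection at
k = 1.96 would be knife-edge even without noise — while a 120-s record
with 10-s dips gives z ≈ −2.9.  Ten-second events also pass the 10-s
moving-average smoother at full depth, and a ~17% event duty cycle matches
the regime of scene-length highlights in short clips.  Event centers sit
mid-bin for the default 10-s ground-truth histogram.

### What the generator does *not* emulate

Realistic EEG spectra outside the beta band, muscle (EMG) artifacts —
the T7/T8 control is exercised by channel exclusion, not by simulating
EMG — volume-conduction geometry, respiratory/motion artifacts in GSR/PPG,
and inter-subject timing variability of the emotional response.  Passing
tests therefore demonstrate that the *pipeline mechanics* recover planted
structure under the stated noise model, not that the method would perform
identically on human recordings.

## File formats

BDF/EDF recordings are read with MNE.  Writing uses a minimal
standards-conformant writer in `core_io` (1-s data records, per-channel
physical ranges padded 0.1% and re-derived from their 8-character header
representation so writer and reader agree exactly on scaling); round trips
preserve samples within 16-bit (EDF) or 24-bit (BDF) quantization.  Channel
roles always come from an explicit label→role map — misclassifying an EOG
channel as EEG corrupts GFS silently, so no heuristics.  Feature series are
two-column CSV (12 significant digits, gaps as empty fields); audio is PCM
WAV via scipy.  The stimulus-onset offset t0 is not representable in
EDF/BDF headers and is dropped on write.

## Known limitations

* GFS absolute levels depend on channel count; compare only within a
  montage.
* The SCR amplitude floor (0.1 z) is a z-scale convention; for recordings
  in microsiemens the classical 0.01 µS criterion should be mapped
  explicitly.
* Pulse detection assumes z-scored slope signals; raw PPG with strong
  baseline wander needs the full chain first.
* Two detected streams on the same timeline are compared only via the
  ground-truth matcher; no cross-stream lag analysis is provided.
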