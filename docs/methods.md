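# Methods

This note records the models, defaults and design decisions behind the
package, in the order the data flows: acquisition model → feature
extraction → sonification → MIDI serialization → synthetic generator →
study pipeline.

## Recording model and preprocessing

A session is a uniformly sampled multichannel recording (default 256 Hz) of
up to four channels: `eda` (μS), `temp` (°C), `bvp` and `resp` (arbitrary
units).  Sample *i* is at time *i*/f_s; the reader never resamples or
reorders, and the sampling rate is always supplied out-of-band (argument or
JSON sidecar) rather than inferred.  Files are plain CSV with 17-significant-
digit floats so a write/read round trip is bit-exact.  Condition annotations
are half-open `[start_s, end_s)` intervals in a separate CSV sidecar, because
experimental conditions are defined by protocol timing, not by the signal.

The acquisition chain being emulated low-pass filters each channel with a
5th-order Butterworth before digitization.  The software re-applies that
filter so the pipeline is self-sufficient on raw synthetic signals.  The
hardware cutoff is not documented anywhere we could rely on, so the default
is **40 Hz** — far above cardiac (< 10 Hz) and respiratory (< 1 Hz) content,
safely below the 128-Hz Nyquist limit.  The filter is applied zero-phase
(forward–backward, `sosfiltfilt`) so beat and exhalation timing is not
lag-shifted; the magnitude response is therefore squared, which only deepens
the stopband.  By default only `bvp` and `resp` are filtered; EDA windowing
and nearest-sample temperature lookup need no anti-aliasing help.

EDA windows are non-overlapping 0.25-s windows (the window length is the
published constant; non-overlap is our reading, and makes the window means
mean-preserving over the covered span).

## Feature extraction

* **EDA level** — arithmetic mean per window, timestamped at window start.
* **Temperature** — nearest-sample lookup ("instantaneous" read literally;
  the error is at most half a sample period).
* **Beats** — the original system extracted heart rate in proprietary
  hardware, so the detector here is the package's own: zero-phase 8-Hz
  low-pass, then local maxima above a rolling median + 4 × rolling-MAD
  threshold (2-s window), a 0.25-s refractory period (a physiological upper
  bound of 240 beats/min), and a 0.5-s guard at each end where filtering
  transients make peaks unreliable.  Interbeat intervals outside
  [0.25, 2.0] s flag the train rather than fail it.
* **Mean IBI** — sliding mean of the last four interbeat differences,
  emitted at each beat from the fifth onward; invariant to time translation.
* **Exhalations** — the respiration signal is smoothed with a 0.25-s moving
  average; peaks and troughs need prominence ≥ 10% of the signal IQR and
  0.5-s separation, are forced into strict alternation (keeping the more
  extreme of any same-type run), and each peak→next-trough pair yields one
  exhalation (timestamp = peak, value = trough − peak).  Because breathing
  extrema are locally flat, each extremum is refined by a least-squares
  **cubic** fit over a window of min(0.5 s, 35% of the gap to the nearest
  neighbouring extremum): the wide window averages sensor noise to
  sub-sample precision, and the cubic term absorbs the asymmetry left by a
  breathing period that drifts across the window, which would bias a plain
  parabola vertex by several samples.

On generator output the detectors recover every ground-truth beat and breath
extremum to within 2 samples at the shipped noise levels, with no misses or
false events away from the recording edges (verified in the test suite).

## Sonification

All mapping constants live in `SonifyConfig`.  Published constants: 0.25-s
EDA windows; 21 scale degrees (three 7-note major-scale octaves) per μS; the
first EDA value as tonic anchor; one semitone of key per temperature step;
chord updates every two bars; tempo from the 4-period mean IBI, updated
every bar; whoosh duration equal to exhalation duration.  Everything else is
a documented package decision:

* **Temperature quantum 0.25 °C/semitone** — the published mapping gives the
  direction but not the step size; 0.25 °C makes the ≈1.7 °C relaxed→anxious
  temperature drop of typically-developing children audible as a ≈7-semitone
  key fall.
* **Comfortable range MIDI [48, 96]** with octave folding: notes outside are
  shifted by whole octaves until inside, preserving pitch class.
* **Melody rhythm** — one potential note per EDA window; consecutive equal
  degrees sustain the sounding note, so flat EDA is a drone and active EDA
  produces runs, without inventing interpolated passing tones.
* **Key changes transpose future melody notes** (the tonic moves with the
  key); the currently sounding note is not retuned.
* **4/4 time; initial tempo 60 BPM** until the first IBI estimate; tempo
  clamped to [40, 200] BPM so detector glitches stay playable.  Bar
  boundaries are computed from the evolving tempo map itself.
* **Chord voicing** — root-position major triad one octave below the tonic,
  folded up if it would fall below MIDI 24; re-affirmed (off/on) at every
  update even when the key is unchanged.
* **Quantization** — round-half-away-from-zero, everywhere.
* **Determinism** — simultaneous events are ordered by a fixed tie-break
  (tempo < program < note-off < note-on, then melody < chord < drum <
  whoosh, then note number), so identical input yields byte-identical MIDI.
* **GM programs** — the published instrument names map to General MIDI
  programs 102 (FX 6 goblins), 53 (Choir Aahs), 118 (Melodic Tom),
  123 (Seashore); the whoosh sounds at fixed MIDI note 60.

## MIDI serialization

Format-1 SMF, 480 ticks per quarter note, one meta track (tempo map, 4/4
time signature, and a JSON text event embedding the effective config, the
melody degree sequence and the key timeline) plus one track per voice on
channels 0–3.  Wall-clock times convert to ticks through the stream's own
piecewise-constant tempo map, so quantization error is at most one tick per
event and a parse-back reproduces event times to within one tick's duration.
The parser exists for round-trip verification and song summarization; it
reads only what the writer emits (plus running status) and skips SysEx.

## Synthetic generator

The generator produces the *statistical* structure of the recorded cohorts,
not mechanistic physiology.  Channel means for all six presets
(population × condition) are the published cohort means; the dynamics around
those means are standard phenomenology with package-chosen defaults:

* **EDA** = tonic level + AR(1) wander (30-s time constant, SD 0.02–0.04 μS)
  + skin conductance responses: Poisson arrivals (4/min relaxed, 10/min
  anxious), half-cosine 1-s rise, exponential 4-s decay, exponentially
  distributed amplitudes (mean 0.1 μS relaxed, 0.3 μS anxious), floored at
  zero.  The tonic level is back-computed by Campbell's theorem
  (tonic = mean − rate · mean-amplitude · kernel-integral) so the session
  mean of windowed EDA converges to the preset mean.
* **Temperature** = mean + linear drift centered mid-session (so the session
  mean is exact) + Gaussian noise (SD 0.02 °C).
* **BVP** = Gaussian systolic peak (σ = 40 ms, amplitude jittered ±20%) at
  each beat; interbeat intervals are AR(1) (ρ = 0.6) around the preset mean,
  truncated to [0.4, 1.5] s.  The waveform is a single systolic peak — no
  dicrotic notch — which is the simplest shape that exercises the detector.
* **Respiration** = −cos of an accumulated phase whose instantaneous period
  interpolates linearly between per-breath jittered periods, giving a
  continuous waveform with no corners; ground-truth peak/trough times are
  the phase crossings of odd/even multiples of π.
* Published standard errors describe *between-child* spread over n = 5
  children per cell, not within-session variability, so they are not used as
  generator noise; within-session variability is the package's documented
  choice above.

Full-session timelines concatenate condition blocks (20-min relaxed baseline
then three cycles of 2-min anxious + 5-min relaxed break, 41 min total) with
a 10-s linear signal cross-fade at each boundary; cross-fade windows are
annotated `other` (the transitional states the study deliberately avoided
sampling) and condition annotations shrink away from them.  Synthetic state
scores are drawn from the reported ranges (31–52 relaxed, 42–57 anxious)
with the anxious score forced strictly higher, matching the validity gate.
`generate_pair_session` is a compact two-block variant (default 160 s per
condition) used for cohort-scale studies.

What the generator does *not* model — motion artifacts, sensor detachment,
ASD-specific EDA atypicality beyond the cell means, respiratory sinus
arrhythmia, thermoregulatory dynamics — bounds what passing tests show:
the pipeline is verified against clean, stationary-within-condition signals
with known ground truth, not against the full messiness of real recordings.

## Study pipeline

* **Validity gate**: a session is kept iff the anxious state score strictly
  exceeds the relaxed one ("an increase" read literally); a missing score is
  `unscorable`, and excluded sessions are logged with their reason.
* **Segment extraction**: one 80-s segment per condition, placed uniformly
  at random (seeded) inside a single same-label interval shrunk by a
  transition margin at both ends.  The exclusion width around transitions is
  not published; the default margin is **30 s**.  A 2-min anxious trial then
  leaves less than 80 s, so the margin auto-shrinks symmetrically to
  `floor((interval − length)/2)` with a logged note — the only reading under
  which 80-s anxious segments are constructible from 2-min trials.  Segments
  never span intervals and never overlap.
* **Batch generation** runs feature extraction → scheduling → MIDI per
  segment, records per-segment failures without aborting the batch, writes a
  CSV manifest in seeded-random order, and is end-to-end deterministic.
* **Summary descriptors** (fixed definitions): time-weighted mean BPM of the
  tempo map; melody note onsets per second; mean pre-transposition melody
  degree; melody pitch range in semitones; final-minus-initial key offset;
  whoosh count and mean duration.
* **Separability** is reported as, per descriptor, the fraction of subject
  pairs whose anxious song moves in the physiologically predicted direction
  (faster beat, shorter whooshes, busier melody), with an exact sign-test
  p-value, plus a transparent one-rule rater (anxious iff mean BPM above the
  cohort median) as an internal regression guard.  Human-listener outcomes
  (accuracy, latency, confidence) are properties of listeners and are
  deliberately not simulated.

## Problem sizes and numerical notes

Cohort-level tests use the full 41-min timeline for the five- and
fifteen-child study designs, and the two-block 160-s-per-condition sessions
for the 25-pair separability cohort; generator/extractor closure is measured
on ten 20-minute single-condition sessions.  These sizes give sampling error
comfortably inside each check's tolerance while keeping the suite quick.
Seeds are spawned via `numpy.random.SeedSequence` so every stage is
independently reproducible.  Degenerate inputs (flat signals, empty feature
sets, overlapping exhalations, single-label manifests) raise typed errors
rather than producing silent output.

## Known limitations

* The beat and breath detectors are stand-ins for unpublished hardware-side
  extraction; their parameters are package choices, validated only against
  the synthetic generator.
* Only the major mode is implemented; the mapping's musical aesthetics
  (velocities, drum pitch, whoosh pitch) are fixed defaults, not claims.
* Offline rendering only: the scheduler is causal-capable but no streaming
  backend is provided, and no audio synthesis beyond General MIDI program
  assignments is attempted.
* EDF or vendor acquisition formats are out of scope; sessions are CSV.
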