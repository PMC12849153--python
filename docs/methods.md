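# Methods

## The display model

The package implements an event-based parameter-mapping sonification of
ST-segment deviation.  The display rides on the per-beat QRS beep of a
pulse-oximeter-style monitor: every 8th beat triggers a six-tone scan
of the limb leads in inverse Cabrera order (aVL, I, −aVR, II, aVF, III),
and two beats later a second scan walks the precordials (V1…V6).  The
two-beat stagger keeps the packets perceptually separate; the fixed
lead order lets a listener attribute a deviant tone to a lead position
and hence to an infarct territory.

Each tone's parameters come from a five-class quantization of the
lead's ST deviation.  Quantizing before mapping (rather than mapping st
continuously to pitch) is deliberate: the clinical question is
categorical (is this lead elevated, and how strongly?), a small set of
pitch intervals is easier to memorize than a continuum, and the class
boundaries (±0.1, ±0.2 mV) follow the conventional diagnostic bands.
The boundary memberships are literal and asserted by tests: −0.1 and
−0.2 belong to the suppressed classes, +0.1 and +0.2 to the moderate
elevated class, so the strong-elevation class opens strictly above
0.2 mV.

The per-class tuples (semitones −8/−5/0/4/7; durations
100/80/50/80/100 ms; harmonics 3/3/1/3/3; levels +15/+5/0/+5/+15 dB)
make deviation salient on four redundant perceptual axes at once:
pitch direction and distance, duration, brightness and loudness.  The
isoelectric tone is deliberately the dullest event in the display — a
short, quiet, single-partial tone at the reference pitch — so a healthy
ECG fades into the background.

## ST measurement

The estimation procedure is a package convention (the display design
itself does not prescribe one): st = mean over a 20 ms window starting
at J + 60 ms, minus the mean of the PR segment over [R − 120, R − 40] ms,
with the J point approximated as R + 80 ms for the default template
morphology.  J + 60 ms is a common clinical measurement point; the PR
segment is the usual isoelectric reference.  All windows are
configurable (`StConfig`).  Because the measure is a difference of two
window means it is exactly invariant to constant baseline shifts and
linear in an injected offset — both asserted as properties.

Scans sonify the trigger beat's own measurement by default
(`average_beats = 1`): maximal responsiveness to transients, which is
the point of a monitoring display.  A longer averaging window is
available for noisy inputs.

Beat detection is a simple energy detector on lead II (5–20 Hz
bandpass, squared derivative, 150 ms integration, threshold at 30% of
the maximum, 250 ms refractory, refinement to the local bandpassed
peak).  It is adequate for clean and synthetic signals, which is its
job here; it is not a clinical-grade detector, and pre-annotated beat
times bypass it.

## Synthesis

Tones are additive: n harmonic partials at f, 2f, …, nf with 1/h
amplitude roll-off, a 5 ms linear attack against clicks, and a
power-law fade-out (1 − t/d)^γ.  The curvature γ(|st|) =
max(0.5, 3 − 5·min(|st|, 0.4)) decreases with |st|, so extreme
deviations fade less steeply and sound more sustained; only the
monotone requirement is essential, the specific law is a package
convention and configurable.

Loudness is calibrated per tone: the enveloped waveform is normalized
to a fixed reference RMS before the class's dB gain is applied.
Without this, harmonic count and envelope shape would leak into
loudness and the +15 dB of the extreme classes would not be +15 dB.
With it, the RMS ratio between an e2 and an IE tone of equal duration
is exactly 10^(15/20), which the tests assert to 10%.

The QRS anchor is a 60 ms exponentially decaying sine at the reference
pitch (554 Hz), a stand-in for the familiar pulse-oximeter beep.
Rendering mixes everything additively into one mono timeline and
applies a single global gain capping the peak at −1 dBFS, preserving
all relative levels.  Output is 16-bit PCM WAV at 44.1 kHz by default.

## Synthetic scenarios

The generator emulates the monitoring situation the display targets: a
regular beat train (default 80 bpm) that is isoelectric until a
transition time (default 90 s) and then switches instantaneously into
an anterior (V1–V4 elevated) or inferior (II/III/aVF elevated, I/aVL
reciprocally depressed at half the elevation) pattern.  Severity
magnitudes are conventions chosen so the classes land where a clinician
would expect under the default cutoffs: weak 0.12 mV (e1), moderate
0.25 mV (e2), severe 0.40 mV (e2).

Beats are sums of compact-support raised-cosine bumps (P, Q, R, S, T)
with per-lead amplitudes from a small built-in table.  Compact support
is the load-bearing choice: no bump overlaps the PR-baseline window or
the ST measurement window, and the injected ST offset is an exactly
flat plateau across the measurement window, so on noiseless input the
measured st equals the injected offset to machine precision.  That
makes the generator a ground-truth oracle for the full pipeline —
including at the one knife-edge case the conventions produce (inferior
severe reciprocal depression lands exactly on the −0.2 mV class
boundary).  Noise is additive white Gaussian per sample, seeded; RR
jitter is available behind a flag but off by default.

What the generator does not emulate: realistic QRST morphology
variation, baseline wander, EMG or mains noise, ectopy or atrial
fibrillation, and gradual ST evolution (the transition is a switch,
matching a simulator scenario change, with an optional ramp
deliberately out of scope).  Passing tests therefore demonstrate the
correctness of the measurement→classification→mapping→synthesis chain
under clean and mildly noisy conditions, not detector or estimator
robustness on real-world recordings.

## Numerical and design choices

* Problem sizes in the test suite are desk-scale: scenario records of
  8–25 s for exactness checks and one 160 s record per pattern×severity
  for the noisy level-agreement check (≥ 200 beats, noise SD 0.02 mV),
  keeping the full suite in a few seconds.
* Spectral assertions use Hann-windowed, zero-padded FFTs with
  parabolic peak interpolation (fundamental within 1 Hz) and a partial
  counter requiring peaks 40 dB above the median bin with 20 dB
  prominence and 200 Hz separation, which rejects envelope side lobes.
* The first L1 scan fires on the first detected beat, then every
  `scan_period_beats`; scans whose L2 trigger beat or measurement
  windows fall outside the record are dropped, not extrapolated.
* File formats: a plain CSV lead table (sampling rate via YAML sidecar
  or flag) and a minimal WFDB-compatible subset (text header + 16-bit
  little-endian signal file, gain 1000 ADC units/mV, i.e. 1 µV
  quantization).  Only single-file format-16 records with mV-convertible
  units are accepted; anything else is an explicit error.
* All amplitudes are mV internally; times are seconds from record
  start; beat indexing is 0-based.

## Known limitations

Real ECGs with wandering baselines or wide QRS complexes will need a
better J-point estimate than the fixed R + 80 ms offset; the config
exposes the offsets but not a morphology-adaptive estimator.  The beat
detector assumes a dominant R wave on lead II.  Audio output is offline
rendering only — no real-time streaming to a sound device.
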