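# stsonify

Sonification of ST-segment deviation in 12-lead ECGs, for biosignal
monitoring and auditory-display research.  The package turns a 12-lead
ECG into the "grouped lead scans" auditory display: short structured
tone sequences, anchored to the familiar QRS monitor beep, that convey
which leads show ST elevation or depression and how strongly — the key
sign of an ST-elevation myocardial infarction (STEMI).  A synthetic
scenario generator (isoelectric start, then anterior or inferior ST
elevation of graded severity) makes the whole chain testable without
any patient data.

## Method

For each beat and lead the ST deviation *st* (mV) is estimated as the
mean signal in a window at J + 60 ms minus the mean of the PR-segment
baseline.  Each *st* is assigned to one of five ordered classes:

| class | meaning | rule |
|-------|---------|------|
| s2 | strongly suppressed  | st ≤ −0.2 mV |
| s1 | moderately suppressed| −0.2 mV < st ≤ −0.1 mV |
| IE | close to isoelectric | \|st\| < 0.1 mV |
| e1 | moderately elevated  | 0.1 mV ≤ st ≤ 0.2 mV |
| e2 | strongly elevated    | st > 0.2 mV |

The classes drive an event-based parameter mapping.  Relative to the
QRS reference pitch p₀ (554 Hz), class (s2, s1, IE, e1, e2) maps to a
pitch offset of (−8, −5, 0, 4, 7) semitones — f(k) = f₀·2^(k/12) — a
duration of (100, 80, 50, 80, 100) ms, a brightness of (3, 3, 1, 3, 3)
harmonic partials, and a level boost of (15, 5, 0, 5, 15) dB.  |st|
additionally flattens the tone's fade-out, so extreme deviations sound
more sustained.

Tones are played as two six-tone *lead scans* with a 120 ms inter-tone
interval: list L1 walks the limb leads along the inverse Cabrera circle
(aVL, I, −aVR, II, aVF, III) and is triggered on every 8th QRS; list L2
walks the precordials (V1…V6) two beats later.  A healthy ECG therefore
sounds like two calm six-note arpeggios at the reference pitch every
eight beats; an anterior STEMI raises the V1–V4 slots of the L2 scan by
seven semitones and makes them longer, brighter and louder.

## Worked example

Simulate a severe anterior STEMI appearing 20 s into a 45 s recording
and render it:

```
stsonify simulate --pattern anterior_stemi --severity severe \
    --transition-s 20 --duration-s 45 --seed 1 --output demo
```

This writes the ECG (`demo.csv` + `demo.yaml` sampling-rate sidecar),
the ground truth (`demo_truth.csv`), the audio (`demo.wav`) and a
per-tone event log.  The log starts isoelectric — every tone at the
554 Hz reference pitch:

```
time_s  set  lead  st_mv   level  semitone  freq_hz
0.3600  L1   aVL   0.0000  IE     0         554.00
0.4800  L1   I     0.0000  IE     0         554.00
0.6000  L1   -aVR  0.0000  IE     0         554.00
...
```

After the 20 s transition the first precordial scan reports the
elevation: V1–V4 measure the injected 0.40 mV, classify as e2 and play
seven semitones higher (830.06 Hz = 554·2^(7/12)):

```
25.8600  L2  V1  0.4000  e2  7  830.06
25.9800  L2  V2  0.4000  e2  7  830.06
26.1000  L2  V3  0.4000  e2  7  830.06
26.2200  L2  V4  0.4000  e2  7  830.06
```

Tones within a scan are 120 ms apart, and successive L1 scans are
8 beats (6 s at 80 bpm) apart.  `stsonify sonify <ecg> <wav>` applies
the same pipeline to an existing recording (CSV table or WFDB-style
header+signal record); `stsonify classify <ecg>` prints the per-beat,
per-lead st/class table.

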