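"""Additive synthesis of scan tones and offline rendering to WAV.

Tone model
----------
Each scan tone is an additive stack of ``n`` harmonic partials at
``f, 2f, ..., nf`` with 1/h amplitude roll-off (brighter classes use
three partials, the isoelectric class a single sine).  Frequencies
follow equal temperament relative to the QRS reference pitch:
``f(k) = f0 * 2^(k/12)`` for a semitone offset ``k``.

The tone is shaped by a short linear attack (5 ms default, click
suppression) and a power-law fade-out ``(1 - t/d)^gamma`` whose
curvature gamma decreases with the magnitude of the source ST value:
tones for more extreme ST deviations fade out less steeply and hence
sound more sustained.  Default law:
``gamma(|st|) = max(0.5, 3 - 5 * min(|st|, 0.4))``.

Loudness is calibrated per tone: the enveloped waveform is normalized
to a fixed reference RMS and then scaled by ``10^(l/20)`` for the
mapped level ``l`` in dB, so the level entry of the mapping table alone
controls loudness regardless of harmonic count or envelope shape.

The QRS anchor is a pulse-oximeter-style beep: a 60 ms exponentially
decaying sine at the reference pitch.  Rendering mixes all beeps and
scan tones additively on a single mono timeline and applies one global
gain so the peak never exceeds -1 dBFS.
"""

from __future__ import annotations

import wave as _wave
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .config import SonificationConfig

#: Reference RMS of a 0 dB tone before the level gain is applied.
REF_RMS = 0.05
#: Peak amplitude of the QRS beep.
QRS_AMPLITUDE = 0.25
#: Global peak target: -1 dBFS.
PEAK_TARGET = 10 ** (-1 / 20)


@dataclass(frozen=True)
class ToneSpec:
    """One scheduled scan tone with fully resolved synthesis parameters."""

    onset: float          # seconds on the output timeline
    frequency: float      # Hz, already f0 * 2^(k/12)
    duration_ms: float
    harmonics: int
    level_db: float       # relative to the isoelectric reference tone
    st_source: float      # mV, drives fade-out curvature
    lead: str


@dataclass
class AudioBuffer:
    """Mono floating-point audio in [-1, 1]."""

    sample_rate: int
    samples: np.ndarray

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


def tone_freq(f0: float, k: float) -> float:
    """Equal-temperament frequency of a pitch ``k`` semitones above ``f0``."""
    if f0 <= 0:
        raise ValueError("reference frequency f0 must be positive")
    return f0 * 2.0 ** (k / 12.0)


def db_to_gain(level_db: float) -> float:
    """Linear amplitude factor of a dB level: 10^(l/20)."""
    return 10.0 ** (level_db / 20.0)


def fade_curvature(st_mv: float, cfg: SonificationConfig | None = None) -> float:
    """Fade-out exponent gamma(|st|): non-increasing in |st|, floored."""
    cfg = cfg or SonificationConfig()
    return max(cfg.curvature_min,
               cfg.curvature_gamma0
               - cfg.curvature_slope * min(abs(st_mv), cfg.curvature_st_cap))


def synth_tone(spec: ToneSpec, sample_rate: int | None = None,
               cfg: SonificationConfig | None = None) -> AudioBuffer:
    """Render one scan tone (without its onset offset)."""
    cfg = cfg or SonificationConfig()
    fs = sample_rate or cfg.sample_rate
    if spec.harmonics * spec.frequency >= fs / 2:
        raise ValueError(
            f"harmonic {spec.harmonics} of {spec.frequency:.1f} Hz reaches "
            f"the Nyquist frequency; use a sample rate above "
            f"{2 * spec.harmonics * spec.frequency:.0f} Hz")
    d = spec.duration_ms / 1000.0
    n = int(np.ceil(d * fs))
    t = np.arange(n) / fs
    wave = np.zeros(n)
    for h in range(1, spec.harmonics + 1):
        wave += np.sin(2 * np.pi * h * spec.frequency * t) / h
    attack = min(cfg.attack_ms / 1000.0, d / 2)
    env = np.minimum(1.0, t / attack) if attack > 0 else np.ones(n)
    gamma = fade_curvature(spec.st_source, cfg)
    env *= np.clip(1.0 - t / d, 0.0, None) ** gamma
    wave *= env
    rms = np.sqrt(np.mean(np.square(wave)))
    if rms > 0:
        wave *= REF_RMS * db_to_gain(spec.level_db) / rms
    return AudioBuffer(fs, wave)


def synth_qrs_tone(f0: float, sample_rate: int,
                   duration_ms: float = 60.0,
                   decay_ms: float = 15.0) -> AudioBuffer:
    """Pulse-oximeter-style QRS beep: exponentially decaying sine at f0."""
    if f0 <= 0:
        raise ValueError("reference frequency f0 must be positive")
    n = int(np.ceil(duration_ms / 1000.0 * sample_rate))
    t = np.arange(n) / sample_rate
    attack = 0.002
    env = np.minimum(1.0, t / attack) * np.exp(-t / (decay_ms / 1000.0))
    return AudioBuffer(sample_rate,
                       QRS_AMPLITUDE * env * np.sin(2 * np.pi * f0 * t))


def _mix_at(target: np.ndarray, piece: np.ndarray, onset_s: float,
            fs: int) -> None:
    start = int(round(onset_s * fs))
    stop = min(start + piece.size, target.size)
    if stop > start >= 0:
        target[start:stop] += piece[:stop - start]


def render(scans: Sequence, beats: Sequence,
           cfg: SonificationConfig | None = None,
           duration: float | None = None) -> AudioBuffer:
    """Mix QRS beeps and scan tones on one mono timeline.

    Every beat contributes a beep at its R time; every tone of every
    scan is mixed at its scheduled onset; overlaps sum.  One global gain
    keeps the peak at or below -1 dBFS, so relative levels between tones
    are preserved.  ``duration`` forces the output length in seconds
    (otherwise it extends 250 ms past the last event).
    """
    cfg = cfg or SonificationConfig()
    fs = cfg.sample_rate
    end = 0.0
    for beat in beats:
        end = max(end, beat.r_time + cfg.qrs_tone_ms / 1000.0)
    for scan in scans:
        for tone in scan.tones:
            end = max(end, tone.onset + tone.duration_ms / 1000.0)
    total = duration if duration is not None else (end + 0.25 if end else 0.0)
    out = np.zeros(int(np.ceil(total * fs)))
    if beats:
        beep = synth_qrs_tone(cfg.f0, fs, cfg.qrs_tone_ms, cfg.qrs_decay_ms)
        for beat in beats:
            _mix_at(out, beep.samples, beat.r_time, fs)
    for scan in scans:
        for tone in scan.tones:
            piece = synth_tone(tone, fs, cfg)
            _mix_at(out, piece.samples, tone.onset, fs)
    peak = np.max(np.abs(out)) if out.size else 0.0
    if peak > PEAK_TARGET:
        out *= PEAK_TARGET / peak
    return AudioBuffer(fs, out)


def write_wav(buf: AudioBuffer, path: str | Path) -> None:
    """Write 16-bit PCM mono WAV."""
    pcm = np.round(np.clip(buf.samples, -1.0, 1.0) * 32767.0).astype("<i2")
    with _wave.open(str(path), "wb") as wf:
        wf.setnchannels(1)
        wf.setsampwidth(2)
        wf.setframerate(buf.sample_rate)
        wf.writeframes(pcm.tobytes())


def read_wav(path: str | Path) -> AudioBuffer:
    """Read a 16-bit PCM mono WAV back into floats in [-1, 1]."""
    with _wave.open(str(path), "rb") as wf:
        if wf.getsampwidth() != 2 or wf.getnchannels() != 1:
            raise ValueError("expected 16-bit mono PCM WAV")
        fs = wf.getframerate()
        raw = wf.readframes(wf.getnframes())
    return AudioBuffer(fs, np.frombuffer(raw, dtype="<i2") / 32767.0)


# ---------------------------------------------------------------------------
# Spectral analysis helpers (used by the test oracles and the verification
# script; not part of the synthesis path)
# ---------------------------------------------------------------------------

def _spectrum_db(buf: AudioBuffer, pad_factor: int = 8
                 ) -> tuple[np.ndarray, np.ndarray]:
    x = buf.samples * np.hanning(buf.samples.size)
    n_fft = int(2 ** np.ceil(np.log2(x.size * pad_factor)))
    mag = np.abs(np.fft.rfft(x, n_fft))
    freqs = np.fft.rfftfreq(n_fft, 1.0 / buf.sample_rate)
    db = 20 * np.log10(mag + 1e-300)
    return freqs, db


def estimate_fundamental(buf: AudioBuffer) -> float:
    """Frequency of the strongest spectral peak, refined by parabolic
    interpolation on the log-magnitude spectrum."""
    freqs, db = _spectrum_db(buf)
    i = int(np.argmax(db))
    if 0 < i < db.size - 1:
        denom = db[i - 1] - 2 * db[i] + db[i + 1]
        delta = 0.5 * (db[i - 1] - db[i + 1]) / denom if denom else 0.0
    else:
        delta = 0.0
    return float((i + delta) * (freqs[1] - freqs[0]))


def count_partials(buf: AudioBuffer, floor_db: float = 40.0,
                   min_separation_hz: float = 200.0) -> int:
    """Number of spectral peaks more than ``floor_db`` above the median bin.

    Peaks must be separated by ``min_separation_hz`` and stand out by at
    least 20 dB of prominence, which rejects envelope side lobes.
    """
    freqs, db = _spectrum_db(buf)
    floor = np.median(db) + floor_db
    distance = max(1, int(min_separation_hz / (freqs[1] - freqs[0])))
    peaks, _ = sps.find_peaks(db, height=floor, distance=distance,
                              prominence=20.0)
    return int(peaks.size)


def envelope_area(buf: AudioBuffer) -> float:
    """Area under the peak-normalized amplitude envelope (Hilbert magnitude);
    larger area means a slower, less steep fade."""
    env = np.abs(sps.hilbert(buf.samples))
    peak = env.max()
    if peak == 0:
        return 0.0
    return float(np.mean(env / peak))
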