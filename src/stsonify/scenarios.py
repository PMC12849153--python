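"""Synthetic 12-lead STEMI scenarios with ground truth.

The generator emulates the monitoring situation the sonification was
designed for: a regular beat train at a configurable heart rate
(default 80 bpm) that starts isoelectric and, at a configurable
transition time (default 90 s), switches instantaneously into an
anterior or inferior ST-elevation pattern of graded severity.

Each beat is a sum of compact-support raised-cosine bumps (P, Q, R, S,
T) with per-lead amplitudes from a small built-in table.  The bumps are
placed so that the PR-baseline window and the ST measurement window of
the default measurement settings contain no bump energy at all: on a
noiseless record the measured ST deviation equals the injected offset
exactly, which makes the generator a ground-truth oracle for the whole
pipeline.  The ST offset itself is injected as a plateau between the J
point and the T onset with short raised-cosine shoulders.

Severity magnitudes are conventions chosen so that, under the default
cutoffs, "weak" lands in the moderate class (e1) and "moderate"/"severe"
in the strong class (e2): 0.12 / 0.25 / 0.40 mV on the affected leads.
Inferior patterns add reciprocal depression of half the elevation on
leads I and aVL.  Noise is additive white Gaussian, seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .audio import AudioBuffer, render
from .config import RunConfig
from .leadscan import scans_for_recording
from .signal_model import EcgRecording, LEADS, write_csv, write_wfdb

PATTERNS = ("normal", "anterior_stemi", "inferior_stemi")
SEVERITIES = ("weak", "moderate", "severe")

#: Elevation magnitude (mV) on affected leads per severity class.
SEVERITY_MV = {"weak": 0.12, "moderate": 0.25, "severe": 0.40}
#: Reciprocal depression as a fraction of the elevation (inferior pattern).
RECIPROCAL_FACTOR = -0.5

ANTERIOR_LEADS = ("V1", "V2", "V3", "V4")
INFERIOR_LEADS = ("II", "III", "aVF")
INFERIOR_RECIPROCAL = ("I", "aVL")

# Per-lead bump amplitudes (mV): P, Q, R, S, T.
_TEMPLATE_MV: dict[str, tuple[float, float, float, float, float]] = {
    "I":   (0.08, -0.05, 0.60, -0.10, 0.25),
    "II":  (0.12, -0.08, 1.10, -0.15, 0.30),
    "III": (0.05, -0.04, 0.50, -0.10, 0.10),
    "aVR": (-0.10, 0.04, -0.80, 0.10, -0.25),
    "aVL": (0.04, -0.03, 0.35, -0.08, 0.12),
    "aVF": (0.08, -0.06, 0.80, -0.12, 0.20),
    "V1":  (0.05, 0.00, 0.20, -0.90, -0.10),
    "V2":  (0.06, 0.00, 0.40, -1.00, 0.35),
    "V3":  (0.07, -0.02, 0.70, -0.70, 0.40),
    "V4":  (0.08, -0.04, 1.20, -0.40, 0.35),
    "V5":  (0.08, -0.05, 1.10, -0.25, 0.30),
    "V6":  (0.08, -0.05, 0.90, -0.15, 0.25),
}

# Bump centers and half-widths relative to the R peak, in seconds.
# Supports: P [-220,-140], Q [-35,-15], R [-25,25], S [28,52], T [220,420] ms.
_BUMPS = {  # (center_s, half_width_s)
    "P": (-0.180, 0.040),
    "Q": (-0.025, 0.010),
    "R": (0.000, 0.025),
    "S": (0.040, 0.012),
    "T": (0.320, 0.100),
}
# ST plateau: rises over [J, J+20 ms], exactly flat over [100, 200] ms
# after R, falls over [200, 220 ms]; the default ST measurement window
# [140, 160] ms sits entirely on the flat part.
_ST_RISE = (0.080, 0.100)
_ST_FALL = (0.200, 0.220)
#: Template extent around each R peak (s): nothing outside this window.
_PRE_EXTENT, _POST_EXTENT = 0.25, 0.45


@dataclass
class ScenarioSpec:
    """Description of one synthetic monitoring scenario."""

    pattern: str = "normal"
    severity: str = "moderate"
    heart_rate: float = 80.0        # bpm
    transition_time: float = 90.0   # s; isoelectric before, pattern after
    total_duration: float = 180.0   # s
    noise_sd: float = 0.0           # mV, additive white Gaussian
    seed: int = 0
    sampling_rate: float = 500.0    # samples/s
    rr_jitter_sd: float = 0.0       # s; optional beat-interval jitter

    def validate(self) -> "ScenarioSpec":
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}, "
                             f"got {self.pattern!r}")
        if self.severity not in SEVERITIES:
            raise ValueError(f"severity must be one of {SEVERITIES}, "
                             f"got {self.severity!r}")
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        if not 0 <= self.transition_time <= self.total_duration:
            raise ValueError("transition_time must lie within the record")
        if self.noise_sd < 0 or self.sampling_rate <= 0:
            raise ValueError("noise_sd must be >= 0 and sampling_rate > 0")
        return self


@dataclass
class GroundTruth:
    """What the generator actually injected."""

    beat_times: np.ndarray                    # R-peak times, s
    beat_elevated: np.ndarray                 # bool per beat
    pre_offsets: dict[str, float] = field(default_factory=dict)   # mV
    post_offsets: dict[str, float] = field(default_factory=dict)  # mV
    transition_time: float = 0.0

    def offset_at_beat(self, beat_index: int, lead: str) -> float:
        offsets = (self.post_offsets if self.beat_elevated[beat_index]
                   else self.pre_offsets)
        return offsets.get(lead, 0.0)


def st_profile(pattern: str, severity: str = "moderate") -> dict[str, float]:
    """Per-lead injected ST offset (mV) of a pattern/severity class.

    normal: all zeros.  anterior: elevation on V1-V4.  inferior:
    elevation on II, III, aVF with reciprocal depression (half the
    elevation) on I and aVL.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"pattern must be one of {PATTERNS}, got {pattern!r}")
    profile = {lead: 0.0 for lead in LEADS}
    if pattern == "normal":
        return profile
    mag = SEVERITY_MV[severity]
    if pattern == "anterior_stemi":
        for lead in ANTERIOR_LEADS:
            profile[lead] = mag
    else:
        for lead in INFERIOR_LEADS:
            profile[lead] = mag
        for lead in INFERIOR_RECIPROCAL:
            profile[lead] = RECIPROCAL_FACTOR * mag
    return profile


def _raised_cosine(tau: np.ndarray, center: float, half_width: float
                   ) -> np.ndarray:
    out = np.zeros_like(tau)
    mask = np.abs(tau - center) < half_width
    out[mask] = 0.5 * (1 + np.cos(np.pi * (tau[mask] - center) / half_width))
    return out


def _st_plateau(tau: np.ndarray) -> np.ndarray:
    """Unit plateau between J and T onset; exactly 1.0 on the flat part."""
    out = np.zeros_like(tau)
    r0, r1 = _ST_RISE
    f0, f1 = _ST_FALL
    rise = (tau >= r0) & (tau < r1)
    out[rise] = 0.5 * (1 - np.cos(np.pi * (tau[rise] - r0) / (r1 - r0)))
    out[(tau >= r1) & (tau <= f0)] = 1.0
    fall = (tau > f0) & (tau <= f1)
    out[fall] = 0.5 * (1 + np.cos(np.pi * (tau[fall] - f0) / (f1 - f0)))
    return out


def generate_scenario(spec: ScenarioSpec) -> tuple[EcgRecording, GroundTruth]:
    """Render a scenario into a 12-lead recording plus its ground truth.

    Deterministic for a fixed seed.  Beats whose template would extend
    past either end of the record are not placed.
    """
    spec.validate()
    fs = spec.sampling_rate
    n = int(round(spec.total_duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(spec.seed)

    rr = 60.0 / spec.heart_rate
    beat_times = []
    bt = _PRE_EXTENT + 0.11  # leave room for the P wave and PR baseline
    while bt + _POST_EXTENT <= spec.total_duration:
        beat_times.append(bt)
        step = rr
        if spec.rr_jitter_sd > 0:
            step = max(0.3, rr + rng.normal(0.0, spec.rr_jitter_sd))
        bt += step
    beat_times = np.asarray(beat_times)
    beat_elevated = beat_times >= spec.transition_time

    profile = st_profile(spec.pattern, spec.severity)
    samples: dict[str, np.ndarray] = {}
    for lead in LEADS:
        x = np.zeros(n)
        amps = dict(zip("PQRST", _TEMPLATE_MV[lead]))
        offset = profile[lead]
        for bt, elevated in zip(beat_times, beat_elevated):
            lo = int(np.floor((bt - _PRE_EXTENT) * fs))
            hi = int(np.ceil((bt + _POST_EXTENT) * fs)) + 1
            tau = t[lo:hi] - bt
            seg = np.zeros_like(tau)
            for name, (center, width) in _BUMPS.items():
                seg += amps[name] * _raised_cosine(tau, center, width)
            if elevated and offset != 0.0:
                seg += offset * _st_plateau(tau)
            x[lo:hi] += seg
        if spec.noise_sd > 0:
            x += rng.normal(0.0, spec.noise_sd, n)
        samples[lead] = x

    truth = GroundTruth(
        beat_times=beat_times,
        beat_elevated=beat_elevated,
        pre_offsets={lead: 0.0 for lead in LEADS},
        post_offsets=profile,
        transition_time=spec.transition_time,
    )
    return EcgRecording(fs, samples), truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Sidecar table: one row per beat, columns beat index, R time,
    elevated flag and the per-lead injected offsets."""
    with open(path, "w") as fh:
        fh.write("beat,r_time_s,elevated," +
                 ",".join(f"st_{lead}_mv" for lead in LEADS) + "\n")
        for i, (bt, el) in enumerate(zip(truth.beat_times,
                                         truth.beat_elevated)):
            offsets = ",".join(
                f"{truth.offset_at_beat(i, lead):.4f}" for lead in LEADS)
            fh.write(f"{i},{bt:.4f},{int(el)},{offsets}\n")


def write_scenario(rec: EcgRecording, truth: GroundTruth,
                   prefix: str | Path, fmt: str = "delimited-table") -> list[Path]:
    """Write the recording (either supported format) plus the ground-truth
    sidecar; returns the written paths."""
    prefix = Path(prefix)
    written = []
    if fmt == "delimited-table":
        ecg_path = prefix.with_suffix(".csv")
        write_csv(rec, ecg_path)
        written += [ecg_path, ecg_path.with_suffix(".yaml")]
    elif fmt == "waveform-record":
        ecg_path = prefix.with_suffix(".hea")
        write_wfdb(rec, ecg_path)
        written += [ecg_path, ecg_path.with_suffix(".dat")]
    else:
        raise ValueError(f"unknown ECG format {fmt!r}")
    gt_path = prefix.parent / (prefix.name + "_truth.csv")
    write_ground_truth(truth, gt_path)
    written.append(gt_path)
    return written


def end_to_end_scenario_audio(spec: ScenarioSpec,
                              cfg: RunConfig | None = None) -> AudioBuffer:
    """Full chain: generate -> detect/measure -> classify/map/schedule ->
    render.  Scans before the transition carry only isoelectric tones;
    the first scan after it sonifies the injected pattern."""
    cfg = (cfg or RunConfig()).validate()
    rec, _ = generate_scenario(spec)
    scans, beats = scans_for_recording(rec, cfg.sonification, cfg.st)
    return render(scans, beats, cfg.sonification, duration=rec.duration)
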