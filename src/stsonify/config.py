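"""Configuration objects for the sonification pipeline.

All tunable parameters live in three dataclasses:

* :class:`StConfig` — where on the beat the ST deviation is measured.
* :class:`SonificationConfig` — the parameter-mapping table (cutoffs,
  semitones, durations, harmonics, levels), scheduling constants and
  synthesis settings.
* :class:`RunConfig` — the merged view the command-line tool validates
  before any stage runs.

Configs can be loaded from / dumped to YAML; unknown keys are rejected so
a typo never silently falls back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

#: Order of the five ST classes used by every per-level tuple below:
#: strongly suppressed, moderately suppressed, isoelectric,
#: moderately elevated, strongly elevated.
LEVEL_ORDER = ("s2", "s1", "IE", "e1", "e2")


@dataclass
class StConfig:
    """Where the ST deviation is measured, relative to the R peak.

    The ST value is the mean signal over a short window starting at
    J + ``st_offset_ms`` minus the mean over a PR-segment baseline
    window; the J point is approximated as R + ``j_offset_ms`` for the
    default template morphology.  All windows in milliseconds.
    """

    j_offset_ms: float = 80.0
    st_offset_ms: float = 60.0          # ST window starts at J + this
    st_window_ms: float = 20.0          # averaged over this width
    baseline_start_ms: float = -120.0   # PR segment, relative to R
    baseline_end_ms: float = -40.0
    average_beats: int = 1              # beats averaged per scan measurement

    def validate(self) -> None:
        if self.st_window_ms <= 0:
            raise ValueError("st_window_ms must be positive")
        if self.baseline_end_ms <= self.baseline_start_ms:
            raise ValueError("baseline window is empty or reversed")
        if self.average_beats < 1:
            raise ValueError("average_beats must be >= 1")


@dataclass
class SonificationConfig:
    """Mapping table, scheduling constants and synthesis parameters.

    Defaults implement the grouped-lead-scan design: per-level semitone
    offsets relative to the QRS reference pitch, durations, harmonic
    counts and dB level boosts, with 554 Hz reference pitch, a 120 ms
    inter-tone interval, an L1 scan every 8 beats and the L2 scan two
    beats later.
    """

    f0: float = 554.0                   # QRS / reference pitch p0, Hz
    inter_tone_ms: float = 120.0
    scan_period_beats: int = 8
    l2_offset_beats: int = 2
    cutoffs_mv: tuple[float, float] = (0.1, 0.2)
    semitones: tuple[int, ...] = (-8, -5, 0, 4, 7)
    durations_ms: tuple[float, ...] = (100.0, 80.0, 50.0, 80.0, 100.0)
    harmonics: tuple[int, ...] = (3, 3, 1, 3, 3)
    levels_db: tuple[float, ...] = (15.0, 5.0, 0.0, 5.0, 15.0)
    sample_rate: int = 44100
    attack_ms: float = 5.0
    qrs_tone_ms: float = 60.0
    qrs_decay_ms: float = 15.0
    # fade-out curvature gamma(|st|) = max(gamma_min, gamma0 - gamma_slope*min(|st|, st_cap))
    curvature_gamma0: float = 3.0
    curvature_slope: float = 5.0
    curvature_min: float = 0.5
    curvature_st_cap: float = 0.4

    def validate(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        c1, c2 = self.cutoffs_mv
        if not (0 < c1 < c2):
            raise ValueError("cutoffs must be strictly ordered positives")
        for name in ("inter_tone_ms", "scan_period_beats", "l2_offset_beats",
                     "sample_rate", "attack_ms", "qrs_tone_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("semitones", "durations_ms", "harmonics", "levels_db"):
            if len(getattr(self, name)) != 5:
                raise ValueError(f"{name} needs one entry per ST level")
        if any(n < 1 for n in self.harmonics):
            raise ValueError("harmonic counts must be >= 1")


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run."""

    sonification: SonificationConfig = field(default_factory=SonificationConfig)
    st: StConfig = field(default_factory=StConfig)

    def validate(self) -> "RunConfig":
        self.sonification.validate()
        self.st.validate()
        return self


def _update_dataclass(obj, data: dict, ctx: str) -> None:
    fields = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in fields:
            raise KeyError(f"unknown config key {ctx}{key!r}")
        if isinstance(value, list):
            value = tuple(value)
        setattr(obj, key, value)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file with ``sonification:`` / ``st:`` sections.

    Top-level keys that match a SonificationConfig field are accepted as
    shorthand.  Unknown keys raise ``KeyError``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    cfg = RunConfig()
    sonification_fields = {f.name for f in dataclasses.fields(SonificationConfig)}
    for key, value in data.items():
        if key == "sonification":
            _update_dataclass(cfg.sonification, value or {}, "sonification.")
        elif key == "st":
            _update_dataclass(cfg.st, value or {}, "st.")
        elif key in sonification_fields:
            _update_dataclass(cfg.sonification, {key: value}, "")
        else:
            raise KeyError(f"unknown config key {key!r}")
    return cfg.validate()


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the effective configuration as YAML (round-trips via load_config)."""
    data = {
        "sonification": {f.name: _plain(getattr(cfg.sonification, f.name))
                         for f in dataclasses.fields(SonificationConfig)},
        "st": {f.name: _plain(getattr(cfg.st, f.name))
               for f in dataclasses.fields(StConfig)},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _plain(value):
    if isinstance(value, tuple):
        return list(value)
    return value
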