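"""Five-level ST classification and grouped lead scans.

Each lead's ST deviation is assigned to one of five ordered classes:

* ``s2`` strongly suppressed:   st <= -0.2 mV
* ``s1`` moderately suppressed: -0.2 mV < st <= -0.1 mV
* ``IE`` close to isoelectric:  |st| < 0.1 mV
* ``e1`` moderately elevated:   0.1 mV <= st <= 0.2 mV
* ``e2`` strongly elevated:     st > 0.2 mV

The five half-open intervals partition the real line; the boundary
memberships above are asserted literally by the tests.

A *lead scan* is a sequence of six short tones, one per lead of a fixed
list, played with a 120 ms inter-tone interval.  List L1 covers the limb
leads along the inverse Cabrera circle (aVL, I, -aVR, II, aVF, III);
list L2 covers the precordials (V1..V6).  The L1 scan is triggered on
every ``scan_period_beats``-th QRS (default every 8th, starting at the
first detected beat); the L2 scan follows ``l2_offset_beats`` beats
later (default 2), so the two six-tone packets stay perceptually
separate.  Tone frequency, duration, brightness (harmonic count) and
level come from the per-class mapping table; the tone's source st value
additionally drives the fade-out curvature at synthesis time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .audio import ToneSpec, tone_freq
from .config import LEVEL_ORDER, SonificationConfig, StConfig
from .signal_model import (BeatEvent, EcgRecording, L1_LEADS, L2_LEADS,
                           StMeasurement, detect_beats, measure_beat_window)


@dataclass(frozen=True)
class StLevel:
    """One of the five ST classes; ordinal -2..+2, negative = suppression."""

    label: str
    ordinal: int

    def __post_init__(self):
        if self.label != LEVEL_ORDER[self.ordinal + 2]:
            raise ValueError(f"label {self.label!r} does not match ordinal "
                             f"{self.ordinal}")


S2 = StLevel("s2", -2)
S1 = StLevel("s1", -1)
IE = StLevel("IE", 0)
E1 = StLevel("e1", 1)
E2 = StLevel("e2", 2)
LEVELS = {lvl.label: lvl for lvl in (S2, S1, IE, E1, E2)}


@dataclass(frozen=True)
class ToneMapEntry:
    """Synthesis parameters of one ST class."""

    semitone_offset: int
    duration_ms: float
    harmonics: int
    level_db: float


@dataclass(frozen=True)
class ScanEvent:
    """One scheduled six-tone message (L1 or L2) anchored to a beat."""

    set_label: str  # "L1" or "L2"
    trigger_beat: BeatEvent
    tones: tuple[ToneSpec, ...]

    @property
    def leads(self) -> tuple[str, ...]:
        return L1_LEADS if self.set_label == "L1" else L2_LEADS


def classify_st_level(st: float, cutoffs: tuple[float, float] = (0.1, 0.2)
                      ) -> StLevel:
    """Assign an ST deviation (mV) to its five-level class.

    The default cutoffs place the moderate band at [0.1, 0.2] mV and the
    strong class strictly above 0.2 mV, mirrored for suppression with
    the boundary on the suppressed side (st = -0.1 -> s1, st = -0.2 -> s2).
    """
    if not math.isfinite(st):
        raise ValueError(f"non-finite ST value: {st!r}")
    c1, c2 = cutoffs
    if st <= -c2:
        return S2
    if st <= -c1:
        return S1
    if st < c1:
        return IE
    if st <= c2:
        return E1
    return E2


def map_tone_params(level: StLevel, cfg: SonificationConfig | None = None
                    ) -> ToneMapEntry:
    """Look up the mapping-table row of an ST class."""
    cfg = cfg or SonificationConfig()
    i = level.ordinal + 2
    return ToneMapEntry(semitone_offset=cfg.semitones[i],
                        duration_ms=cfg.durations_ms[i],
                        harmonics=cfg.harmonics[i],
                        level_db=cfg.levels_db[i])


def schedule_scans(beats: Sequence[BeatEvent],
                   cfg: SonificationConfig | None = None
                   ) -> list[tuple[str, BeatEvent]]:
    """Assign scan triggers to beats.

    L1 fires on beat 0 and then every ``scan_period_beats`` beats; each
    L2 fires ``l2_offset_beats`` beats after its L1.  L2 scans whose
    trigger beat falls beyond the record are dropped.  The returned list
    is ordered by trigger time.
    """
    cfg = cfg or SonificationConfig()
    schedule: list[tuple[str, BeatEvent]] = []
    for i in range(0, len(beats), cfg.scan_period_beats):
        schedule.append(("L1", beats[i]))
        j = i + cfg.l2_offset_beats
        if j < len(beats):
            schedule.append(("L2", beats[j]))
    schedule.sort(key=lambda item: item[1].r_time)
    return schedule


def build_scan(set_label: str, trigger_beat: BeatEvent,
               measurements: Sequence[StMeasurement],
               cfg: SonificationConfig | None = None) -> ScanEvent:
    """Resolve one scan into six fully parameterized tones.

    ``measurements`` must hold exactly one StMeasurement per lead of the
    set, in the set's fixed order (with -aVR in the third L1 slot).
    Tone *i* starts ``i`` inter-tone intervals after the trigger beat.
    """
    cfg = cfg or SonificationConfig()
    leads = L1_LEADS if set_label == "L1" else L2_LEADS
    if set_label not in ("L1", "L2"):
        raise ValueError(f"unknown scan set {set_label!r}")
    if len(measurements) != len(leads):
        raise ValueError(f"{set_label} scan needs {len(leads)} measurements, "
                         f"got {len(measurements)}")
    tones = []
    for i, (lead, m) in enumerate(zip(leads, measurements)):
        level = classify_st_level(m.st, cfg.cutoffs_mv)
        entry = map_tone_params(level, cfg)
        tones.append(ToneSpec(
            onset=trigger_beat.r_time + i * cfg.inter_tone_ms / 1000.0,
            frequency=tone_freq(cfg.f0, entry.semitone_offset),
            duration_ms=entry.duration_ms,
            harmonics=entry.harmonics,
            level_db=entry.level_db,
            st_source=m.st,
            lead=lead,
        ))
    return ScanEvent(set_label=set_label, trigger_beat=trigger_beat,
                     tones=tuple(tones))


def scans_for_recording(rec: EcgRecording,
                        cfg: SonificationConfig | None = None,
                        st_cfg: StConfig | None = None,
                        beats: Sequence[BeatEvent] | None = None
                        ) -> tuple[list[ScanEvent], list[BeatEvent]]:
    """Full measurement-to-scan pipeline for one recording.

    Detects beats (unless pre-annotated beat times are supplied),
    schedules L1/L2 triggers, measures the six st values per scan and
    builds the tone sequences.  Scans whose measurement windows fall
    outside the record (first/last beats) are dropped rather than
    extrapolated.
    """
    cfg = cfg or SonificationConfig()
    st_cfg = st_cfg or StConfig()
    beat_list = list(beats) if beats is not None else detect_beats(rec)
    scans: list[ScanEvent] = []
    for set_label, beat in schedule_scans(beat_list, cfg):
        leads = L1_LEADS if set_label == "L1" else L2_LEADS
        try:
            ms = [measure_beat_window(rec, beat_list, beat.index, lead, st_cfg)
                  for lead in leads]
        except ValueError:
            continue  # window outside record near the edges
        scans.append(build_scan(set_label, beat, ms, cfg))
    return scans, beat_list
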