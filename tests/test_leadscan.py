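"""Five-level classification, tone mapping and scan scheduling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stsonify as s
from stsonify.signal_model import L1_LEADS, L2_LEADS


class TestClassify:
    @pytest.mark.parametrize("value,label", [
        (0.25, "e2"), (-0.15, "s1"), (0.0, "IE"),
        # boundary memberships exactly as the cutoff rule prints them
        (0.1, "e1"), (-0.1, "s1"), (0.2, "e1"), (-0.2, "s2"),
        (0.2000001, "e2"), (-0.2000001, "s2"),
        (0.0999999, "IE"), (-0.0999999, "IE"),
    ])
    def test_boundaries(self, value, label):
        assert s.classify_st_level(value).label == label

    def test_non_finite_rejected(self):
        for bad in (float("nan"), float("inf"), float("-inf")):
            with pytest.raises(ValueError):
                s.classify_st_level(bad)

    @given(st.floats(min_value=-0.5, max_value=0.5,
                     allow_nan=False, allow_subnormal=False))
    @settings(max_examples=300, derandomize=True)
    def test_partition_and_monotonicity(self, value):
        """Every st value belongs to exactly one level, and the ordinal is
        non-decreasing in st."""
        level = s.classify_st_level(value)
        assert level.label in ("s2", "s1", "IE", "e1", "e2")
        eps = 1e-6
        assert s.classify_st_level(value + eps).ordinal >= level.ordinal
        assert s.classify_st_level(value - eps).ordinal <= level.ordinal

    def test_dense_grid_monotone(self):
        grid = np.concatenate([np.linspace(-0.5, 0.5, 2001),
                               [-0.2, -0.1, 0.1, 0.2]])
        grid.sort()
        ordinals = [s.classify_st_level(v).ordinal for v in grid]
        assert all(b >= a for a, b in zip(ordinals, ordinals[1:]))


class TestToneMap:
    @pytest.mark.parametrize("level,expected", [
        (s.IE, (0, 50.0, 1, 0.0)),
        (s.E2, (7, 100.0, 3, 15.0)),
        (s.S2, (-8, 100.0, 3, 15.0)),
        (s.E1, (4, 80.0, 3, 5.0)),
        (s.S1, (-5, 80.0, 3, 5.0)),
    ])
    def test_default_rows(self, level, expected):
        entry = s.map_tone_params(level)
        assert (entry.semitone_offset, entry.duration_ms,
                entry.harmonics, entry.level_db) == expected

    def test_symmetry_and_pitch_monotonicity(self, son_cfg):
        """Duration/harmonics/level depend only on |ordinal|; the semitone
        offset increases strictly with the ordinal."""
        entries = {lvl: s.map_tone_params(lvl, son_cfg)
                   for lvl in (s.S2, s.S1, s.IE, s.E1, s.E2)}
        for neg, pos in ((s.S2, s.E2), (s.S1, s.E1)):
            assert entries[neg].duration_ms == entries[pos].duration_ms
            assert entries[neg].harmonics == entries[pos].harmonics
            assert entries[neg].level_db == entries[pos].level_db
        offsets = [entries[lvl].semitone_offset
                   for lvl in (s.S2, s.S1, s.IE, s.E1, s.E2)]
        assert all(b > a for a, b in zip(offsets, offsets[1:]))


def _beats(n, rr=0.75, t0=0.0):
    return [s.BeatEvent(index=i, r_time=t0 + i * rr) for i in range(n)]


class TestSchedule:
    def test_default_trigger_indices(self):
        sched = s.schedule_scans(_beats(20))
        l1 = [b.index for lbl, b in sched if lbl == "L1"]
        l2 = [b.index for lbl, b in sched if lbl == "L2"]
        assert l1 == [0, 8, 16]
        assert l2 == [2, 10, 18]

    def test_single_beat(self):
        sched = s.schedule_scans(_beats(1))
        assert sched == [("L1", s.BeatEvent(0, 0.0))]

    def test_empty(self):
        assert s.schedule_scans([]) == []

    def test_l1_trigger_times_at_80_bpm(self):
        """8-beat period at 80 bpm gives one L1 scan every 6 s."""
        sched = s.schedule_scans(_beats(80, rr=0.75))
        l1_times = [b.r_time for lbl, b in sched if lbl == "L1"]
        assert l1_times == pytest.approx([6.0 * k for k in range(10)])

    def test_spacing_invariant(self):
        sched = s.schedule_scans(_beats(57))
        l1 = [b.index for lbl, b in sched if lbl == "L1"]
        assert all(b - a == 8 for a, b in zip(l1, l1[1:]))
        l2 = [b.index for lbl, b in sched if lbl == "L2"]
        assert all(j - i == 2 for i, j in zip(l1, l2))


def _measurements(beat, leads, values):
    return [s.StMeasurement(beat=beat, lead=lead, st=v)
            for lead, v in zip(leads, values)]


class TestBuildScan:
    def test_all_isoelectric(self, son_cfg):
        beat = s.BeatEvent(index=8, r_time=6.0)
        scan = s.build_scan("L1", beat, _measurements(beat, L1_LEADS, [0.0] * 6))
        assert len(scan.tones) == 6
        for i, tone in enumerate(scan.tones):
            assert tone.frequency == pytest.approx(son_cfg.f0)
            assert tone.duration_ms == 50.0
            assert tone.harmonics == 1
            assert tone.level_db == 0.0
            assert tone.onset == pytest.approx(6.0 + 0.12 * i)
        assert scan.tones[-1].onset - scan.tones[0].onset == pytest.approx(0.600)

    def test_l2_anterior_pattern(self, son_cfg):
        beat = s.BeatEvent(index=2, r_time=1.5)
        values = [0.3, 0.3, 0.3, 0.3, 0.0, 0.0]
        scan = s.build_scan("L2", beat, _measurements(beat, L2_LEADS, values))
        f_e2 = s.tone_freq(son_cfg.f0, 7)
        for tone in scan.tones[:4]:
            assert tone.frequency == pytest.approx(f_e2)
            assert (tone.duration_ms, tone.harmonics, tone.level_db) == \
                (100.0, 3, 15.0)
        for tone in scan.tones[4:]:
            assert tone.frequency == pytest.approx(son_cfg.f0)
            assert tone.harmonics == 1

    def test_wrong_measurement_count(self):
        beat = s.BeatEvent(index=0, r_time=0.0)
        with pytest.raises(ValueError, match="6 measurements"):
            s.build_scan("L1", beat, _measurements(beat, L1_LEADS[:4], [0] * 4))

    def test_matches_brute_force_oracle(self, son_cfg):
        """build_scan equals an independent enumeration of the full
        cutoff + mapping table on random st vectors."""
        # independent oracle: explicit interval walk over the printed table
        table = {  # label -> (k, d_ms, n, l_db)
            "s2": (-8, 100.0, 3, 15.0), "s1": (-5, 80.0, 3, 5.0),
            "IE": (0, 50.0, 1, 0.0), "e1": (4, 80.0, 3, 5.0),
            "e2": (7, 100.0, 3, 15.0),
        }

        def oracle_label(v):
            if v <= -0.2:
                return "s2"
            if -0.2 < v <= -0.1:
                return "s1"
            if -0.1 < v < 0.1:
                return "IE"
            if 0.1 <= v <= 0.2:
                return "e1"
            return "e2"

        rng = np.random.default_rng(42)
        beat = s.BeatEvent(index=0, r_time=2.0)
        for _ in range(1000):
            values = rng.uniform(-0.5, 0.5, 6)
            scan = s.build_scan("L2", beat,
                                _measurements(beat, L2_LEADS, values))
            for i, (tone, v) in enumerate(zip(scan.tones, values)):
                k, d, n, l = table[oracle_label(v)]
                assert tone.frequency == son_cfg.f0 * 2.0 ** (k / 12.0)
                assert tone.duration_ms == d
                assert tone.harmonics == n
                assert tone.level_db == l
                assert tone.onset == beat.r_time + i * 0.12
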