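import numpy as np
import pytest

import stsonify as s


@pytest.fixture(scope="session")
def run_cfg() -> s.RunConfig:
    return s.RunConfig().validate()


@pytest.fixture(scope="session")
def son_cfg(run_cfg) -> s.SonificationConfig:
    return run_cfg.sonification


@pytest.fixture(scope="session")
def short_normal():
    """20 s noiseless normal-ST recording with ground truth."""
    spec = s.ScenarioSpec(pattern="normal", total_duration=20.0,
                          transition_time=0.0)
    return s.generate_scenario(spec)


@pytest.fixture(scope="session")
def short_anterior():
    """25 s noiseless recording turning anterior-severe at 10 s."""
    spec = s.ScenarioSpec(pattern="anterior_stemi", severity="severe",
                          transition_time=10.0, total_duration=25.0)
    return s.generate_scenario(spec)


def ie_tone_spec(son_cfg, duration_ms=None, st=0.0, onset=0.0):
    level = s.classify_st_level(st, son_cfg.cutoffs_mv)
    entry = s.map_tone_params(level, son_cfg)
    return s.ToneSpec(onset=onset,
                      frequency=s.tone_freq(son_cfg.f0, entry.semitone_offset),
                      duration_ms=duration_ms or entry.duration_ms,
                      harmonics=entry.harmonics, level_db=entry.level_db,
                      st_source=st, lead="II")


@pytest.fixture
def make_tone(son_cfg):
    """Factory: ToneSpec with parameters resolved from an st value."""
    def _make(st=0.0, duration_ms=None, onset=0.0):
        return ie_tone_spec(son_cfg, duration_ms=duration_ms, st=st,
                            onset=onset)
    return _make
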