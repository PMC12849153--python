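"""12-lead ECG records, beat events and ST-segment measurement.

The acquired leads are the standard 12 (I, II, III, aVR, aVL, aVF,
V1..V6).  One derived lead, ``-aVR`` (aVR with inverted polarity), is
used by the limb-lead scan so the six limb leads follow the Cabrera
ordering; it is never stored, always computed on demand.

ST deviation is measured per beat and per lead as

    st = mean(signal over the ST window) - mean(signal over the PR baseline)

in mV, with the ST window anchored at an approximated J point
(R + ``j_offset_ms``) plus a conventional J+60 ms measurement offset,
and the baseline taken from the PR segment.  Both windows are
configurable through :class:`~stsonify.config.StConfig`.

Two on-disk formats are supported: a plain comma-separated table (header
row of lead names, one column per lead, samples in mV, sampling rate via
sidecar YAML or argument) and a minimal subset of the WFDB physiological
waveform record format (text ``.hea`` header plus 16-bit ``.dat`` signal
file, format 16, gain in ADC units per mV).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy import signal as sps

from .config import StConfig

logger = logging.getLogger("stsonify")

#: The 12 acquired leads, in conventional recording order.
LEADS: tuple[str, ...] = ("I", "II", "III", "aVR", "aVL", "aVF",
                          "V1", "V2", "V3", "V4", "V5", "V6")

#: Derived lead label: aVR with inverted polarity (Cabrera ordering).
NEG_AVR = "-aVR"

#: Limb-lead scan list L1 (inverse Cabrera circle) and precordial list L2.
L1_LEADS: tuple[str, ...] = ("aVL", "I", NEG_AVR, "II", "aVF", "III")
L2_LEADS: tuple[str, ...] = ("V1", "V2", "V3", "V4", "V5", "V6")

_CANONICAL = {name.lower(): name for name in LEADS}


def canonical_lead(name: str) -> str:
    """Map a header label to its canonical lead name (case-insensitive)."""
    key = name.strip().lower()
    if key in ("-avr", "negavr", "minusavr"):
        return NEG_AVR
    if key not in _CANONICAL:
        raise ValueError(f"unknown ECG lead label {name!r}")
    return _CANONICAL[key]


@dataclass(frozen=True)
class BeatEvent:
    """One cardiac cycle, located by its R-peak time."""

    index: int
    r_time: float  # seconds from record start


@dataclass(frozen=True)
class StMeasurement:
    """ST deviation of one lead at one beat, in mV."""

    beat: BeatEvent
    lead: str
    st: float


class EcgRecording:
    """Multichannel ECG waveform in mV with a uniform sampling rate."""

    def __init__(self, sampling_rate: float, samples: dict[str, np.ndarray]):
        if sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        missing = [name for name in LEADS if name not in samples]
        if missing:
            raise ValueError(f"missing ECG leads: {', '.join(missing)}")
        arrays = {name: np.asarray(samples[name], dtype=float) for name in LEADS}
        lengths = {a.size for a in arrays.values()}
        if len(lengths) != 1:
            raise ValueError("all leads must have the same number of samples")
        self.sampling_rate = float(sampling_rate)
        self.samples = arrays

    @property
    def n_samples(self) -> int:
        return self.samples["I"].size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    def lead(self, name: str) -> np.ndarray:
        """Samples of an acquired lead, or the derived ``-aVR``."""
        name = canonical_lead(name)
        if name == NEG_AVR:
            return derive_neg_avr(self)
        return self.samples[name]


def derive_neg_avr(rec: EcgRecording) -> np.ndarray:
    """Sample-wise inversion of lead aVR (an involution)."""
    return -rec.samples["aVR"]


# ---------------------------------------------------------------------------
# Readers and writers
# ---------------------------------------------------------------------------

def read_ecg(path: str | Path, fmt: str | None = None,
             sampling_rate: float | None = None) -> EcgRecording:
    """Read a 12-lead ECG record.

    Parameters
    ----------
    path
        ``.csv`` table or WFDB-style ``.hea`` header (the matching
        ``.dat`` must sit next to it).
    fmt
        ``"delimited-table"`` or ``"waveform-record"``; inferred from the
        file extension when omitted.
    sampling_rate
        Required for tables unless a ``<stem>.yaml`` sidecar with a
        ``sampling_rate`` key exists; ignored for waveform records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "waveform-record" if path.suffix == ".hea" else "delimited-table"
    if fmt == "delimited-table":
        return _read_csv(path, sampling_rate)
    if fmt == "waveform-record":
        return _read_wfdb(path)
    raise ValueError(f"unknown ECG format {fmt!r}")


def _read_csv(path: Path, sampling_rate: float | None) -> EcgRecording:
    if sampling_rate is None:
        sidecar = path.with_suffix(".yaml")
        if not sidecar.exists():
            raise ValueError(
                f"sampling rate for {path} not given and no sidecar {sidecar}")
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
        sampling_rate = float(meta["sampling_rate"])
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        names = [canonical_lead(h) for h in header]
        if NEG_AVR in names:
            raise ValueError("-aVR is a derived lead and cannot be acquired")
        missing = [name for name in LEADS if name not in names]
        if missing:
            raise ValueError(f"missing ECG leads: {', '.join(missing)}")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    samples = {name: data[:, i] for i, name in enumerate(names)}
    return EcgRecording(sampling_rate, samples)


def write_csv(rec: EcgRecording, path: str | Path,
              write_sidecar: bool = True) -> None:
    """Write the record as a comma-separated table plus sampling-rate sidecar."""
    path = Path(path)
    data = np.column_stack([rec.samples[name] for name in LEADS])
    np.savetxt(path, data, delimiter=",", fmt="%.6f",
               header=",".join(LEADS), comments="")
    if write_sidecar:
        with open(path.with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump({"sampling_rate": rec.sampling_rate}, fh)


_WFDB_GAIN = 1000.0  # ADC units per mV -> 1 uV quantization


def _read_wfdb(header_path: Path) -> EcgRecording:
    with open(header_path) as fh:
        lines = [ln.strip() for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    record_line = lines[0].split()
    n_sig = int(record_line[1])
    sampling_rate = float(record_line[2])
    n_samp = int(record_line[3]) if len(record_line) > 3 else None
    sig_lines = lines[1:1 + n_sig]
    if len(sig_lines) != n_sig:
        raise ValueError(f"header {header_path} truncated")
    names, gains, dat_file = [], [], None
    for ln in sig_lines:
        parts = ln.split()
        fname, fmt_field, gain_field = parts[0], parts[1], parts[2]
        if dat_file is None:
            dat_file = fname
        elif fname != dat_file:
            raise ValueError("multi-file waveform records are not supported")
        if fmt_field.split("x")[0] != "16":
            raise ValueError(f"unsupported signal format {fmt_field!r}")
        if "x" in fmt_field and fmt_field.split("x")[1] != "1":
            raise ValueError("non-uniform sampling (samples per frame != 1)")
        gain_str, _, units = gain_field.partition("/")
        gain_str = gain_str.split("(")[0]
        if units and units.lower() not in ("mv",):
            raise ValueError(f"signal units {units!r} are not convertible to mV")
        gains.append(float(gain_str) if gain_str else _WFDB_GAIN)
        names.append(canonical_lead(parts[-1]))
    missing = [name for name in LEADS if name not in names]
    if missing:
        raise ValueError(f"missing ECG leads: {', '.join(missing)}")
    raw = np.fromfile(header_path.with_name(dat_file), dtype="<i2")
    if n_samp is None:
        n_samp = raw.size // n_sig
    raw = raw[:n_samp * n_sig].reshape(n_samp, n_sig)
    samples = {name: raw[:, i] / gains[i] for i, name in enumerate(names)}
    return EcgRecording(sampling_rate, samples)


def write_wfdb(rec: EcgRecording, header_path: str | Path) -> None:
    """Write a WFDB-subset record: text header plus 16-bit signal file.

    Amplitudes are quantized to 1 uV (gain 1000 ADC units per mV); a
    write-then-read round trip therefore matches the source to within
    half a quantization step.
    """
    header_path = Path(header_path)
    record = header_path.stem
    dat_name = record + ".dat"
    adc = np.column_stack([
        np.clip(np.rint(rec.samples[name] * _WFDB_GAIN), -32768, 32767)
        for name in LEADS
    ]).astype("<i2")
    with open(header_path, "w") as fh:
        fh.write(f"{record} {len(LEADS)} {rec.sampling_rate:g} {rec.n_samples}\n")
        for i, name in enumerate(LEADS):
            checksum = int(np.sum(adc[:, i], dtype=np.int64) % 65536)
            first = int(adc[0, i]) if rec.n_samples else 0
            fh.write(f"{dat_name} 16 {_WFDB_GAIN:g}/mV 16 0 "
                     f"{first} {checksum} 0 {name}\n")
    adc.tofile(header_path.with_name(dat_name))


# ---------------------------------------------------------------------------
# Beat detection
# ---------------------------------------------------------------------------

def detect_beats(rec: EcgRecording, refractory_s: float = 0.25) -> list[BeatEvent]:
    """Locate R peaks on lead II.

    Bandpass (5-20 Hz), differentiate, square, integrate over a 150 ms
    moving window, then threshold at 30% of the maximum with a
    refractory period; each detection is refined to the local maximum of
    the rectified bandpassed signal.  Adequate for clean or synthetic
    signals; not a clinical-grade detector.
    """
    if rec.duration < 2.0:
        raise ValueError("record too short for beat detection (< 2 s)")
    fs = rec.sampling_rate
    x = rec.samples["II"]
    if not np.any(x):
        logger.warning("beat detection: flat signal, no beats found")
        return []
    sos = sps.butter(2, [5.0, min(20.0, 0.45 * fs)], btype="bandpass",
                     fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, x)
    energy = np.square(np.gradient(band))
    win = max(1, int(round(0.150 * fs)))
    integrated = np.convolve(energy, np.ones(win) / win, mode="same")
    peak = integrated.max()
    if peak <= 0:
        logger.warning("beat detection: no QRS energy, no beats found")
        return []
    distance = max(1, int(round(refractory_s * fs)))
    locs, _ = sps.find_peaks(integrated, height=0.3 * peak, distance=distance)
    refine = int(round(0.120 * fs))
    r_samples = []
    for loc in locs:
        lo, hi = max(0, loc - refine), min(x.size, loc + refine + 1)
        r_samples.append(lo + int(np.argmax(np.abs(band[lo:hi]))))
    r_samples = sorted(set(r_samples))
    # collapse refinements that landed on the same R within the refractory
    beats: list[int] = []
    for s in r_samples:
        if beats and s - beats[-1] < distance:
            continue
        beats.append(s)
    if not beats:
        logger.warning("beat detection: no beats found")
    return [BeatEvent(index=i, r_time=s / fs) for i, s in enumerate(beats)]


# ---------------------------------------------------------------------------
# ST measurement
# ---------------------------------------------------------------------------

def _window_indices(r_time: float, start_ms: float, end_ms: float,
                    fs: float, n: int) -> slice:
    lo = int(round((r_time + start_ms / 1000.0) * fs))
    hi = int(round((r_time + end_ms / 1000.0) * fs))
    if lo < 0 or hi > n or hi <= lo:
        raise ValueError(
            f"measurement window [{start_ms}, {end_ms}] ms around beat at "
            f"{r_time:.3f} s lies outside the record")
    return slice(lo, hi)


def measure_st(rec: EcgRecording, beat: BeatEvent, lead: str,
               st_cfg: StConfig | None = None) -> StMeasurement:
    """ST deviation of one lead at one beat: ST-window mean minus PR baseline.

    Baseline-relative by construction, hence invariant to constant
    shifts of the lead.  Accepts the derived ``-aVR`` lead.
    """
    cfg = st_cfg or StConfig()
    lead = canonical_lead(lead)
    x = rec.lead(lead)
    fs = rec.sampling_rate
    st_start = cfg.j_offset_ms + cfg.st_offset_ms
    st_win = _window_indices(beat.r_time, st_start,
                             st_start + cfg.st_window_ms, fs, x.size)
    base_win = _window_indices(beat.r_time, cfg.baseline_start_ms,
                               cfg.baseline_end_ms, fs, x.size)
    st = float(np.mean(x[st_win]) - np.mean(x[base_win]))
    return StMeasurement(beat=beat, lead=lead, st=st)


def measure_beat_window(rec: EcgRecording, beats: Sequence[BeatEvent],
                        trigger_index: int, lead: str,
                        st_cfg: StConfig | None = None) -> StMeasurement:
    """ST measurement for a scan trigger, averaged over the last
    ``average_beats`` beats ending at the trigger beat (default 1: the
    trigger beat alone, maximally responsive to transients)."""
    cfg = st_cfg or StConfig()
    first = max(0, trigger_index - cfg.average_beats + 1)
    values = [measure_st(rec, beats[i], lead, cfg).st
              for i in range(first, trigger_index + 1)]
    return StMeasurement(beat=beats[trigger_index], lead=canonical_lead(lead),
                         st=float(np.mean(values)))
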