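"""Synthetic uterine records for desk-scale testing of the whole pipeline.

Each generated record carries four channels (EHG S1-S3 and TOCO) at 20 Hz
and mixes the components visible in real uterine recordings:

* white sensor noise per channel;
* a maternal respiration sinusoid (0.2-0.34 Hz);
* a maternal cardiac component: fundamental in band B1 (1.2-1.5 Hz,
  72-90 bpm) with 2nd and 3rd harmonics decaying geometrically, plus a slow
  ±0.05 Hz sinusoidal frequency modulation so the spectral peak has a
  realistic width.  The tocogram receives the fundamental at full strength
  but strongly attenuated harmonics — the mechanical pathway transmits the
  heart *rate*, not the sharp electrical waveform;
* contraction bursts: band-limited (0.1-1.0 Hz) noise under a Gaussian
  envelope on the EHG channels during scheduled intervals, mirrored into
  TOCO as the smooth pressure deflection that annotators use to mark
  contraction boundaries.

Three archetypes set the cardiac amplitudes: ``term_nonlabor`` (strong
electro-mechanical cardiac influence), ``preterm_like`` (weak influence —
the danger signature), and ``nonpregnant_like`` (no contractions and
essentially no cardiac transmission into the tocogram).  Dummy
(non-contraction) intervals are placed in the gaps between contractions
with lengths matched to their neighbors, mirroring how real records are
annotated.  Default interval lengths (~85 s) and per-record schedules track
the published characteristics of annotated uterine records.

All randomness flows from a single integer seed through
``numpy.random.Philox`` counters, so identical configurations yield
byte-identical emitted files on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .records_io import IntervalAnnotation, UterineRecord, write_annotations, \
    write_record

__all__ = ["CardiacConfig", "RespirationConfig", "ContractionConfig",
           "SynthConfig", "ARCHETYPES", "archetype_config", "synth_record",
           "synth_cohort"]

CHANNELS = ("S1", "S2", "S3", "TOCO")


@dataclass(frozen=True)
class CardiacConfig:
    """Maternal cardiac component: fundamental + 2 harmonics."""

    f_hr: float = 1.35                       # Hz, 72-90 bpm range
    amp: dict = field(default_factory=lambda: {
        "S1": 3.0, "S2": 2.0, "S3": 1.5, "TOCO": 3.0})   # µV
    harmonic_decay: float = 0.45             # amplitude ratio per harmonic
    toco_harmonic_atten: float = 0.25        # extra harmonic damping in TOCO
    fm_depth: float = 0.05                   # Hz, slow heart-rate wobble
    fm_period: float = 60.0                  # s

    def __post_init__(self) -> None:
        if not 1.0 <= self.f_hr <= 2.2:
            raise ValueError(f"f_hr {self.f_hr} Hz outside band B1")


@dataclass(frozen=True)
class RespirationConfig:
    f_resp: float = 0.27                     # Hz, within 0.2-0.34
    amp: float = 2.5                         # µV, all channels; keeps P_max in B0

    def __post_init__(self) -> None:
        if not 0.2 <= self.f_resp <= 0.34:
            raise ValueError(
                f"f_resp {self.f_resp} Hz outside the respiration band")


@dataclass(frozen=True)
class ContractionConfig:
    schedule: tuple = ((200.0, 285.0), (700.0, 790.0), (1300.0, 1380.0))
    burst_band: tuple = (0.1, 1.0)           # Hz
    amp: float = 12.0                        # µV EHG burst scale
    toco_deflection: float = 15.0            # tocograph units


@dataclass(frozen=True)
class SynthConfig:
    duration_s: float = 1800.0
    fs: float = 20.0
    cardiac: CardiacConfig = CardiacConfig()
    respiration: RespirationConfig = RespirationConfig()
    contractions: ContractionConfig = ContractionConfig()
    noise_sd: dict = field(default_factory=lambda: {
        "S1": 0.5, "S2": 0.5, "S3": 0.5, "TOCO": 0.3})
    archetype: str = "term_nonlabor"
    seed: int = 0

    def __post_init__(self) -> None:
        last = 0.0
        for on, off in self.contractions.schedule:
            if on < last or off <= on or off > self.duration_s:
                raise ValueError(
                    f"contraction schedule conflict at [{on}, {off}]")
            last = off


#: cardiac amplitude scaling and schedule presence per archetype
ARCHETYPES = {
    "term_nonlabor": {"cardiac_scale": 1.0, "toco_cardiac_scale": 1.0,
                      "contractions": True, "group": "term",
                      "delivery_wk": (37.0, 40.0)},
    "preterm_like": {"cardiac_scale": 0.15, "toco_cardiac_scale": 0.15,
                     "contractions": True, "group": "preterm",
                     "delivery_wk": (32.0, 35.5)},
    "nonpregnant_like": {"cardiac_scale": 0.8, "toco_cardiac_scale": 0.0,
                         "contractions": False, "group": "nonpregnant",
                         "delivery_wk": None},
}


def archetype_config(archetype: str, seed: int = 0,
                     duration_s: float = 1800.0) -> SynthConfig:
    """Default configuration for one archetype."""
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; "
                         f"choose from {sorted(ARCHETYPES)}")
    spec = ARCHETYPES[archetype]
    base = CardiacConfig()
    amp = {ch: a * spec["cardiac_scale"] for ch, a in base.amp.items()}
    amp["TOCO"] = base.amp["TOCO"] * spec["toco_cardiac_scale"]
    if spec["contractions"]:
        contractions = ContractionConfig()
        if duration_s != 1800.0:
            # keep the default 3-contraction layout proportionally placed
            scale = duration_s / 1800.0
            contractions = replace(contractions, schedule=tuple(
                (on * scale, off * scale)
                for on, off in contractions.schedule))
    else:
        contractions = ContractionConfig(schedule=())
    return SynthConfig(duration_s=duration_s,
                       cardiac=replace(base, amp=amp),
                       contractions=contractions,
                       archetype=archetype, seed=seed)


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent counter-based stream for one component."""
    return np.random.Generator(np.random.Philox(key=np.uint64(seed),
                                                counter=[0, 0, 0, stream]))


def _cardiac(config: SynthConfig, t: np.ndarray, channel: str,
             rng: np.random.Generator) -> np.ndarray:
    c = config.cardiac
    amp = c.amp.get(channel, 0.0)
    if amp <= 0:
        return np.zeros_like(t)
    f_inst = c.f_hr + c.fm_depth * np.sin(
        2 * np.pi * t / c.fm_period + rng.uniform(0, 2 * np.pi))
    phase = 2 * np.pi * np.cumsum(f_inst) / config.fs
    out = np.zeros_like(t)
    for h in (1, 2, 3):
        a = amp * c.harmonic_decay ** (h - 1)
        if channel == "TOCO" and h > 1:
            a *= c.toco_harmonic_atten
        out += a * np.sin(h * phase + rng.uniform(0, 2 * np.pi))
    return out


def _burst_carrier(n: int, fs: float, band: tuple,
                   rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited noise for contraction bursts."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def synth_record(config: SynthConfig
                 ) -> tuple[UterineRecord, list[IntervalAnnotation]]:
    """Generate one four-channel record plus its interval annotations.

    Contraction annotations coincide with the scheduled bursts; one dummy
    annotation is placed in each inter-contraction gap (or spread evenly
    when there are no contractions), with lengths matched to neighboring
    contractions.
    """
    fs = config.fs
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs
    seed = config.seed

    signals = np.zeros((len(CHANNELS), n))
    for i, ch in enumerate(CHANNELS):
        rng = _rng(seed, 10 + i)
        x = config.noise_sd.get(ch, 0.0) * rng.standard_normal(n)
        x += config.respiration.amp * np.sin(
            2 * np.pi * config.respiration.f_resp * t
            + rng.uniform(0, 2 * np.pi))
        x += _cardiac(config, t, ch, _rng(seed, 20 + i))
        signals[i] = x

    # contraction bursts: shared envelope, independent EHG carriers
    cc = config.contractions
    anns: list[IntervalAnnotation] = []
    rid = f"synth_{config.archetype}_{seed:08d}"
    for j, (on_s, off_s) in enumerate(cc.schedule):
        on, off = int(round(on_s * fs)), int(round(off_s * fs))
        dur = off - on
        env = np.exp(-0.5 * ((np.arange(dur) - dur / 2) / (dur / 6)) ** 2)
        for i, ch in enumerate(CHANNELS[:3]):
            carrier = _burst_carrier(dur, fs, cc.burst_band,
                                     _rng(seed, 100 + 10 * j + i))
            signals[i, on:off] += cc.amp * env * carrier
        signals[3, on:off] += cc.toco_deflection * env
        anns.append(IntervalAnnotation(rid, on, off, "contraction"))

    anns.extend(_dummy_annotations(rid, anns, n, fs))

    meta = _metadata(config, _rng(seed, 3))
    record = UterineRecord(rid, signals, list(CHANNELS), fs, meta)
    return record, sorted(anns, key=lambda a: a.onset)


def _dummy_annotations(rid: str, contractions: list[IntervalAnnotation],
                       n: int, fs: float) -> list[IntervalAnnotation]:
    pad = int(round(15.0 * fs))              # stand-off from contractions
    dummies = []
    if contractions:
        bounds = [0] + [a.offset for a in contractions]
        ends = [a.onset for a in contractions] + [n]
        lengths = [a.length for a in contractions]
        for g, (lo, hi) in enumerate(zip(bounds, ends)):
            want = lengths[min(g, len(lengths) - 1)]
            lo, hi = lo + pad, hi - pad
            if hi - lo < want:
                continue
            mid = (lo + hi) // 2
            dummies.append(IntervalAnnotation(
                rid, mid - want // 2, mid - want // 2 + want, "dummy"))
            if len(dummies) == len(contractions):
                break
    else:
        # non-pregnant records: evenly spread dummy intervals, ~85 s each
        count = 3
        step = n // count
        want = min(int(round(85.0 * fs)), max(step - 2 * pad, step // 2))
        for g in range(count):
            start = g * step + (step - want) // 2
            dummies.append(IntervalAnnotation(rid, start, start + want,
                                              "dummy"))
    return dummies


def _metadata(config: SynthConfig, rng: np.random.Generator) -> dict:
    spec = ARCHETYPES[config.archetype]
    meta = {"group": spec["group"], "archetype": config.archetype}
    if spec["delivery_wk"] is None:
        meta["gestation_at_recording"] = None
        meta["gestation_at_delivery"] = None
    else:
        meta["gestation_at_recording"] = round(float(rng.uniform(28.0, 32.0)), 1)
        meta["gestation_at_delivery"] = round(
            float(rng.uniform(*spec["delivery_wk"])), 1)
    return meta


def _jittered(config: SynthConfig, rng: np.random.Generator,
              seed: int) -> SynthConfig:
    """Per-record variation of heart rate, amplitudes, and schedule."""
    c = config.cardiac
    f_hr = float(rng.uniform(1.2, 1.5))
    amp = {ch: a * float(rng.lognormal(0.0, 0.15)) for ch, a in c.amp.items()}
    resp = replace(config.respiration,
                   f_resp=float(rng.uniform(0.2, 0.34)))
    sched = []
    t_cursor = 0.0
    gap = min(30.0, 0.017 * config.duration_s)
    for on, off in config.contractions.schedule:
        shift = float(rng.uniform(-20.0, 20.0))
        stretch = float(rng.uniform(0.85, 1.15))
        dur = (off - on) * stretch
        new_on = max(t_cursor + gap, on + shift)
        new_off = min(new_on + dur, config.duration_s - 1.0)
        if new_off - new_on > max(20.0, 0.4 * (off - on)):
            sched.append((new_on, new_off))
            t_cursor = new_off
    return replace(config,
                   cardiac=replace(c, f_hr=f_hr, amp=amp),
                   respiration=resp,
                   contractions=replace(config.contractions,
                                        schedule=tuple(sched)),
                   seed=seed)


_TASK_ARCHETYPES = {
    "preterm_vs_term": ("preterm_like", "term_nonlabor"),
    "nonpregnant_vs_pregnant": ("nonpregnant_like", "term_nonlabor"),
}


def synth_cohort(n_per_class: int, archetype_pair: str | tuple = "preterm_vs_term",
                 seed: int = 0, duration_s: float = 1800.0,
                 out_dir: str | Path | None = None
                 ) -> list[tuple[UterineRecord, list[IntervalAnnotation]]]:
    """Generate a labeled two-class cohort of records.

    ``archetype_pair`` is a task name or an explicit pair of archetype
    names.  Heart rate, amplitudes and schedules are jittered per record
    from seeded distributions.  With ``out_dir`` the records and annotation
    TSVs are also written in the on-disk dialect.
    """
    if n_per_class < 2:
        raise ValueError(f"need n_per_class >= 2, got {n_per_class}")
    pair = _TASK_ARCHETYPES.get(archetype_pair, archetype_pair)
    if not (isinstance(pair, tuple) and len(pair) == 2):
        raise ValueError(f"unknown archetype pair/task {archetype_pair!r}")
    ss = np.random.SeedSequence(seed)
    record_seeds = ss.generate_state(2 * n_per_class) % (2**31)
    dataset = []
    for c, arch in enumerate(pair):
        for i in range(n_per_class):
            rseed = int(record_seeds[c * n_per_class + i])
            base = archetype_config(arch, seed=rseed, duration_s=duration_s)
            cfg = _jittered(base, _rng(rseed, 1), rseed)
            rec, anns = synth_record(cfg)
            rec.record_id = f"{rec.record_id}_{c}{i:03d}"
            anns = [replace(a, record_id=rec.record_id) for a in anns]
            dataset.append((rec, anns))
    if out_dir is not None:
        out_dir = Path(out_dir)
        for rec, anns in dataset:
            write_record(rec, out_dir)
            write_annotations(anns, out_dir / f"{rec.record_id}.ann.tsv")
    return dataset
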