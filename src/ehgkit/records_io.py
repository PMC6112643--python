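"""Reading and writing uterine records and interval annotations.

Records follow a WFDB-compatible dialect: a plain-text header (``.hea``)
describing the channels plus a 16-bit little-endian interleaved signal file
(``.dat``, WFDB format 16).  Uterine records carry up to four channels:
three bipolar abdominal EHG signals (S1, S2, S3) and optionally the external
tocogram (TOCO).  Interval annotations mark ``contraction`` and ``dummy``
(non-contraction) spans; the canonical on-disk form is a three-column TSV
(onset_sample, offset_sample, label), with a paired begin/end marker dialect
accepted on input.

Sample indexing is 0-based and intervals are half-open ``[onset, offset)``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "UterineRecord",
    "IntervalAnnotation",
    "Segment",
    "FormatError",
    "AnnotationError",
    "read_record",
    "write_record",
    "read_annotations",
    "write_annotations",
    "extract_segment",
]

EHG_CHANNELS = ("S1", "S2", "S3")
KNOWN_CHANNELS = ("S1", "S2", "S3", "TOCO")
LABELS = ("contraction", "dummy")

# short annotation tokens accepted on input (case-insensitive)
_LABEL_ALIASES = {"c": "contraction", "contraction": "contraction",
                  "d": "dummy", "dummy": "dummy"}


class FormatError(ValueError):
    """Header/signal file disagreement or malformed record."""


class AnnotationError(ValueError):
    """Malformed, overlapping, or out-of-range interval annotations."""


@dataclass
class UterineRecord:
    """Multi-channel uterine record (channels x samples, physical units)."""

    record_id: str
    signals: np.ndarray            # (n_channels, n_samples) float64, µV for EHG
    channel_names: list[str]
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=np.float64))
        if self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        if self.signals.shape[0] != len(self.channel_names):
            raise FormatError(
                f"{self.signals.shape[0]} signal rows but "
                f"{len(self.channel_names)} channel names")
        if self.signals.shape[1] < 1:
            raise FormatError("record must contain at least one sample")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise FormatError(f"duplicate channel names: {self.channel_names}")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channel_names:
            raise KeyError(
                f"channel {name!r} not in record {self.record_id!r} "
                f"(has {self.channel_names})")
        return self.signals[self.channel_names.index(name)]

    def with_signals(self, signals: np.ndarray) -> "UterineRecord":
        """Copy of this record with the sample array replaced."""
        return UterineRecord(self.record_id, signals, list(self.channel_names),
                             self.fs, dict(self.meta))


@dataclass(frozen=True)
class IntervalAnnotation:
    """Labeled half-open interval ``[onset, offset)`` on a record."""

    record_id: str
    onset: int
    offset: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise AnnotationError(f"unknown interval label {self.label!r}")
        if not 0 <= self.onset < self.offset:
            raise AnnotationError(
                f"invalid interval [{self.onset}, {self.offset})")

    @property
    def length(self) -> int:
        return self.offset - self.onset


@dataclass
class Segment:
    """Per-channel slice of a record over one annotated interval."""

    data: np.ndarray               # (n_channels, length)
    channel_names: list[str]
    fs: float
    record_id: str
    label: str                     # contraction | dummy | whole_record

    @property
    def length(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]


# --------------------------------------------------------------------------
# WFDB-dialect record I/O

_HEADER_LINE = re.compile(
    r"^(?P<name>\S+)\s+(?P<nsig>\d+)\s+(?P<fs>[\d.]+)(?:\s+(?P<nsamp>\d+))?")


def read_record(path: str | Path) -> UterineRecord:
    """Read a header+signal record pair.

    ``path`` may point at the ``.hea`` file or be the record base name.
    Gains and baselines from the header are applied, so EHG samples come
    back in physical units (µV).
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"header file not found: {hea}")
    lines = [ln.rstrip("\n") for ln in hea.read_text().splitlines()
             if ln.strip()]
    m = _HEADER_LINE.match(lines[0])
    if m is None:
        raise FormatError(f"unparseable header line: {lines[0]!r}")
    record_id = m.group("name")
    nsig = int(m.group("nsig"))
    fs = float(m.group("fs"))
    if fs <= 0:
        raise FormatError(f"non-positive sampling rate in header: {fs}")
    nsamp = int(m.group("nsamp")) if m.group("nsamp") else None

    sig_lines = [ln for ln in lines[1:] if not ln.startswith("#")]
    comments = [ln[1:].strip() for ln in lines[1:] if ln.startswith("#")]
    if len(sig_lines) != nsig:
        raise FormatError(
            f"header declares {nsig} signals but lists {len(sig_lines)}")

    dat_name = None
    gains, baselines, names = [], [], []
    for ln in sig_lines:
        toks = ln.split()
        if len(toks) < 3:
            raise FormatError(f"unparseable signal line: {ln!r}")
        fname, fmt, gainspec = toks[0], toks[1], toks[2]
        if dat_name is None:
            dat_name = fname
        elif fname != dat_name:
            raise FormatError("all signals must share one .dat file")
        if fmt != "16":
            raise FormatError(f"unsupported signal format {fmt!r} (need 16)")
        gm = re.match(r"^([-\d.eE+]+)(?:\((-?\d+)\))?(?:/(\S+))?$", gainspec)
        if gm is None:
            raise FormatError(f"unparseable gain spec {gainspec!r}")
        gains.append(float(gm.group(1)))
        baselines.append(int(gm.group(2)) if gm.group(2) else 0)
        names.append(toks[-1])

    raw = np.fromfile(hea.parent / dat_name, dtype="<i2")
    if raw.size % nsig != 0:
        raise FormatError(
            f"signal file length {raw.size} not divisible by {nsig} channels")
    n = raw.size // nsig
    if nsamp is not None and n != nsamp:
        raise FormatError(
            f"header declares {nsamp} samples but signal file holds {n}")
    adc = raw.reshape(n, nsig).T.astype(np.float64)
    signals = np.empty_like(adc)
    for i, (g, b) in enumerate(zip(gains, baselines)):
        signals[i] = (adc[i] - b) / (g if g != 0 else 1.0)

    meta = {"gestation_at_recording": None, "gestation_at_delivery": None,
            "group": "unknown"}
    for c in comments:
        if ":" in c:
            key, _, val = c.partition(":")
            key = key.strip().lower().replace(" ", "_")
            val = val.strip()
            if key in ("gestation_at_recording", "gestation_at_delivery"):
                meta[key] = float(val) if val.lower() != "none" else None
            elif key == "group":
                meta[key] = val
            else:
                meta[key] = val
    return UterineRecord(record_id, signals, names, fs, meta)


def write_record(record: UterineRecord, directory: str | Path,
                 gain: float = 100.0) -> Path:
    """Write ``record`` as a ``.hea``/``.dat`` pair; returns the header path.

    Samples are quantized to 16-bit ADC units at the given gain
    (ADC units per physical unit).  Values already produced by
    :func:`read_record` survive a write/read cycle bit-exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    hea = directory / f"{record.record_id}.hea"
    dat = directory / f"{record.record_id}.dat"
    adc = np.rint(record.signals * gain)
    if np.any(np.abs(adc) > 32767):
        raise FormatError(
            f"record {record.record_id!r} overflows int16 at gain {gain}")
    buf = io.StringIO()
    buf.write(f"{record.record_id} {len(record.channel_names)} "
              f"{record.fs:g} {record.n_samples}\n")
    for name in record.channel_names:
        buf.write(f"{dat.name} 16 {gain:g}(0)/uV 16 0 0 0 0 {name}\n")
    for key in ("gestation_at_recording", "gestation_at_delivery", "group"):
        val = record.meta.get(key)
        if val is not None:
            buf.write(f"# {key}: {val}\n")
    hea.write_text(buf.getvalue())
    adc.astype("<i2").T.tofile(dat)
    return hea


# --------------------------------------------------------------------------
# Annotation I/O

def _validate_annotations(anns: list[IntervalAnnotation],
                          record: UterineRecord | None) -> list[IntervalAnnotation]:
    anns = sorted(anns, key=lambda a: a.onset)
    for prev, cur in zip(anns, anns[1:]):
        if cur.onset < prev.offset:
            raise AnnotationError(
                f"overlapping intervals [{prev.onset},{prev.offset}) and "
                f"[{cur.onset},{cur.offset}) on {cur.record_id!r}")
    if record is not None:
        for a in anns:
            if a.offset > record.n_samples:
                raise AnnotationError(
                    f"interval [{a.onset},{a.offset}) exceeds record length "
                    f"{record.n_samples}")
    return anns


def read_annotations(path: str | Path,
                     record: UterineRecord | None = None
                     ) -> list[IntervalAnnotation]:
    """Read interval annotations (TSV, or paired begin/end markers).

    TSV rows are ``onset<TAB>offset<TAB>label``; the marker dialect has rows
    ``sample<TAB>(`` / ``sample<TAB>)<TAB>label`` pairing each begin with the
    next end.  Returned intervals are sorted and validated against
    ``record`` when given.
    """
    path = Path(path)
    rid = record.record_id if record is not None else path.stem
    rows = []
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        rows.append(ln.split("\t") if "\t" in ln else ln.split())

    anns: list[IntervalAnnotation] = []
    if any(len(r) >= 2 and r[1] in "()" for r in rows):
        open_sample = None
        for r in rows:
            sample, marker = int(r[0]), r[1]
            if marker == "(":
                if open_sample is not None:
                    raise AnnotationError("nested '(' marker without ')'")
                open_sample = sample
            elif marker == ")":
                if open_sample is None:
                    raise AnnotationError("')' marker without '('")
                if len(r) < 3:
                    raise AnnotationError("')' marker missing its label")
                anns.append(IntervalAnnotation(
                    rid, open_sample, sample, _parse_label(r[2])))
                open_sample = None
        if open_sample is not None:
            raise AnnotationError("unclosed '(' marker at end of file")
    else:
        for r in rows:
            if len(r) != 3:
                raise AnnotationError(f"expected 3 columns, got {r!r}")
            anns.append(IntervalAnnotation(
                rid, int(r[0]), int(r[1]), _parse_label(r[2])))
    return _validate_annotations(anns, record)


def _parse_label(token: str) -> str:
    try:
        return _LABEL_ALIASES[token.strip().lower()]
    except KeyError:
        raise AnnotationError(f"unknown label token {token!r}") from None


def write_annotations(anns: list[IntervalAnnotation], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"{a.onset}\t{a.offset}\t{a.label}"
             for a in sorted(anns, key=lambda a: a.onset)]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def extract_segment(record: UterineRecord, ann: IntervalAnnotation | None,
                    channels: list[str] | None = None) -> Segment:
    """Slice ``record`` over an annotation (``None`` = whole record)."""
    if channels is None:
        channels = list(record.channel_names)
    if not channels:
        raise ValueError("channel subset must be non-empty")
    missing = [c for c in channels if c not in record.channel_names]
    if missing:
        raise ValueError(
            f"record {record.record_id!r} lacks channel(s) {missing}; "
            f"has {record.channel_names}")
    idx = [record.channel_names.index(c) for c in channels]
    if ann is None:
        data = record.signals[idx]
        label = "whole_record"
    else:
        if ann.offset > record.n_samples:
            raise AnnotationError(
                f"interval [{ann.onset},{ann.offset}) exceeds record length")
        data = record.signals[idx, ann.onset:ann.offset]
        label = ann.label
    return Segment(np.array(data, copy=True), list(channels), record.fs,
                   record.record_id, label)


def annotations_to_csv(anns: list[IntervalAnnotation], path: str | Path) -> Path:
    """Export an annotation table as CSV (record_id, onset, offset, label)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("record_id,onset,offset,label\n")
        for a in sorted(anns, key=lambda a: (a.record_id, a.onset)):
            fh.write(f"{a.record_id},{a.onset},{a.offset},{a.label}\n")
    return path
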