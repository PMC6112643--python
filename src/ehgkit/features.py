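"""Per-interval feature assembly: SE per subband, MF/PA from the wide band.

For every requested signal of an annotated interval (or of the whole
record) the pipeline computes 11 features:

* ``SE`` in bands B0-B3, from the time-domain subband-filtered signals;
* ``MF`` in bands B0-B3 and ``PA`` in bands B1-B3, read from a single
  smoothed, normalized power spectrum of the wide-band (0.08-5.0 Hz)
  signal.

``PA`` in B0 is omitted: the global spectral maximum used for
normalization almost always lies in B0 (respiration, contractions), which
would pin that feature at 1.  Feature names follow
``"<signal>.<band>.<feature>"`` (e.g. ``S2.B1.PA``), ordered by signal,
then band B0→B3, then SE, MF, PA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import filterbank, spectral
from .entropy import SampleEntropyParams, sample_entropy
from .records_io import IntervalAnnotation, UterineRecord, extract_segment

__all__ = ["FeatureVector", "FeatureMatrix", "feature_names", "WHOLE_RECORD",
           "extract_interval_features", "extract_record_features",
           "build_feature_matrix", "TASKS"]

WHOLE_RECORD = None                      # sentinel: no interval slicing

TASKS = ("preterm_vs_term", "labor_vs_nonlabor", "nonpregnant_vs_pregnant")

#: clinically alarming class, used as the positive class downstream
POSITIVE_LABEL = {"preterm_vs_term": "preterm",
                  "labor_vs_nonlabor": "labor",
                  "nonpregnant_vs_pregnant": "nonpregnant"}

_SE_BANDS = ("B0", "B1", "B2", "B3")
_MF_BANDS = ("B0", "B1", "B2", "B3")
_PA_BANDS = ("B1", "B2", "B3")           # no B0 (normalization peak lives there)
_BAND_BY_NAME = {b.name: b for b in filterbank.SUBBANDS}


def feature_names(signals: list[str]) -> list[str]:
    """Canonical column order: signal, band B0→B3, then SE, MF, PA."""
    names = []
    for s in signals:
        for b in _SE_BANDS:
            names.append(f"{s}.{b}.SE")
            names.append(f"{s}.{b}.MF")
            if b in _PA_BANDS:
                names.append(f"{s}.{b}.PA")
    return names


@dataclass
class FeatureVector:
    """Named per-signal-per-band feature values for one interval."""

    values: dict[str, float]
    record_id: str
    interval_label: str                  # contraction | dummy | whole_record
    class_label: str | None = None

    def __getitem__(self, key: str) -> float:
        return self.values[key]


@dataclass
class FeatureMatrix:
    """Feature table with class labels and per-row provenance."""

    X: pd.DataFrame                      # rows x feature columns
    y: pd.Series                         # class label per row
    meta: pd.DataFrame                   # record_id, interval_label, synthetic
    positive_label: str | None = None
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y) or len(self.X) != len(self.meta):
            raise ValueError("X, y and meta must have equal row counts")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing cells")
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate feature columns")

    @property
    def n_rows(self) -> int:
        return len(self.X)

    def class_counts(self) -> dict[str, int]:
        return self.y.value_counts().to_dict()

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.meta.copy()
        out["class"] = self.y.values
        out = pd.concat([out.reset_index(drop=True),
                         self.X.reset_index(drop=True)], axis=1)
        out.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path,
                 positive_label: str | None = None) -> "FeatureMatrix":
        df = pd.read_csv(path)
        meta_cols = [c for c in ("record_id", "interval_label", "synthetic")
                     if c in df.columns]
        if "class" not in df.columns:
            raise ValueError(f"{path}: missing required 'class' column")
        feat_cols = [c for c in df.columns
                     if c not in meta_cols and c != "class"]
        meta = df[meta_cols].copy()
        if "synthetic" not in meta.columns:
            meta["synthetic"] = False
        return cls(df[feat_cols].copy(), df["class"].copy(), meta,
                   positive_label)


def _segment_features(seg_by_band: dict[str, np.ndarray], fs: float,
                      signal: str, se_params: SampleEntropyParams,
                      smooth_width: float) -> dict[str, float]:
    """Features for one signal given its per-band sample arrays."""
    ps = spectral.power_spectrum(seg_by_band["WIDE"], fs)
    ps = spectral.normalize_spectrum(spectral.smooth_spectrum(ps, smooth_width))
    out: dict[str, float] = {}
    for bname in _SE_BANDS:
        band = _BAND_BY_NAME[bname]
        out[f"{signal}.{bname}.SE"] = sample_entropy(seg_by_band[bname],
                                                     se_params)
        out[f"{signal}.{bname}.MF"] = spectral.median_frequency(ps, band)
        if bname in _PA_BANDS:
            out[f"{signal}.{bname}.PA"] = spectral.peak_amplitude(ps, band)
    return out


def extract_interval_features(
        record: UterineRecord,
        ann: IntervalAnnotation | None,
        signals: list[str],
        se_params: SampleEntropyParams = SampleEntropyParams(),
        smooth_width: float = 0.1,
        decomposition: dict[str, UterineRecord] | None = None,
        trim_seconds: float = 0.0,
        class_label: str | None = None) -> FeatureVector:
    """Compute the 11 features per signal for one interval (or the whole
    record when ``ann`` is ``None``).

    ``decomposition`` may carry a precomputed filter-bank output for the
    record so that repeated calls do not refilter; ``trim_seconds``
    optionally drops filter transients at both record ends in whole-record
    mode (default keeps everything).
    """
    if not signals:
        raise ValueError("signal subset must be non-empty")
    missing = [s for s in signals if s not in record.channel_names]
    if missing:
        raise ValueError(
            f"record {record.record_id!r} lacks requested signal(s) {missing}")
    if decomposition is None:
        decomposition = filterbank.decompose_record(record)

    length = record.n_samples if ann is None else ann.length
    if length <= se_params.m + 1 or length < 16:
        raise ValueError(
            f"interval of {length} samples too short (need > {se_params.m + 1} "
            f"and >= 16)")

    values: dict[str, float] = {}
    for sig in signals:
        per_band: dict[str, np.ndarray] = {}
        for bname, subrec in decomposition.items():
            x = subrec.channel(sig)
            if ann is not None:
                x = x[ann.onset:ann.offset]
            elif trim_seconds > 0:
                k = int(round(trim_seconds * record.fs))
                x = x[k:x.size - k if k else None]
            per_band[bname] = x
        values.update(_segment_features(per_band, record.fs, sig,
                                        se_params, smooth_width))
    label = "whole_record" if ann is None else ann.label
    return FeatureVector(values, record.record_id, label, class_label)


def extract_record_features(record: UterineRecord,
                            annotations: list[IntervalAnnotation],
                            signals: list[str],
                            interval_kind: str = "contraction",
                            **kwargs) -> list[FeatureVector]:
    """All feature vectors of one record, filtering the record only once."""
    decomposition = filterbank.decompose_record(record)
    if interval_kind == "whole_record":
        return [extract_interval_features(record, None, signals,
                                          decomposition=decomposition,
                                          **kwargs)]
    return [extract_interval_features(record, a, signals,
                                      decomposition=decomposition, **kwargs)
            for a in annotations if a.label == interval_kind]


def _class_label(record: UterineRecord, task: str,
                 labor_boundary_weeks: float) -> str:
    group = record.meta.get("group", "unknown")
    if task == "preterm_vs_term":
        if group not in ("preterm", "term"):
            raise ValueError(f"group {group!r} unusable for preterm_vs_term")
        return group
    if task == "nonpregnant_vs_pregnant":
        if group == "nonpregnant":
            return "nonpregnant"
        if group in ("preterm", "term"):
            return "pregnant"
        raise ValueError(f"group {group!r} unusable for nonpregnant_vs_pregnant")
    if task == "labor_vs_nonlabor":
        rec_wk = record.meta.get("gestation_at_recording")
        del_wk = record.meta.get("gestation_at_delivery")
        if rec_wk is None or del_wk is None:
            raise ValueError("missing gestation metadata for labor task")
        return "labor" if (del_wk - rec_wk) <= labor_boundary_weeks \
            else "nonlabor"
    raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")


def build_feature_matrix(
        dataset: list[tuple[UterineRecord, list[IntervalAnnotation]]],
        task: str,
        interval_kind: str,
        signals: list[str],
        se_params: SampleEntropyParams = SampleEntropyParams(),
        smooth_width: float = 0.1,
        labor_boundary_weeks: float = 3.0,
        trim_seconds: float = 0.0) -> FeatureMatrix:
    """One row per selected interval (or per record in whole-record mode).

    Records whose metadata cannot support the task, or intervals failing the
    length preconditions, are skipped and reported in ``FeatureMatrix.skipped``
    rather than aborting the build.  The labor/nonlabor boundary is the
    recording-to-delivery gap in weeks (default 3, intentionally early).
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    cols = feature_names(signals)
    rows, labels, meta_rows = [], [], []
    skipped: list[tuple[str, str]] = []
    for record, anns in dataset:
        try:
            label = _class_label(record, task, labor_boundary_weeks)
        except ValueError as exc:
            skipped.append((record.record_id, str(exc)))
            continue
        try:
            fvs = extract_record_features(
                record, anns, signals, interval_kind,
                se_params=se_params, smooth_width=smooth_width,
                trim_seconds=trim_seconds)
        except ValueError as exc:
            skipped.append((record.record_id, str(exc)))
            continue
        for fv in fvs:
            rows.append([fv.values[c] for c in cols])
            labels.append(label)
            meta_rows.append((fv.record_id, fv.interval_label, False))
    X = pd.DataFrame(rows, columns=cols)
    y = pd.Series(labels, name="class", dtype=object)
    meta = pd.DataFrame(meta_rows,
                        columns=["record_id", "interval_label", "synthetic"])
    return FeatureMatrix(X, y, meta, POSITIVE_LABEL[task], skipped)
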