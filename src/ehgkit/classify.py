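"""Class balancing, QDA classification, and repeated cross-validation.

Clinical EHG datasets are imbalanced (preterm deliveries are the minority),
so two oversampling schemes are provided:

* SMOTE — synthetic minority rows placed uniformly on the segment between
  a minority sample and one of its k nearest minority neighbors, until the
  classes are equal;
* ADASYN — like SMOTE, but the number of synthetic rows seeded at each
  minority sample is proportional to the fraction of majority samples among
  its k nearest neighbors in the full data, concentrating synthesis where
  the classes overlap.  The resulting minority count approximates (within
  rounding) the majority count.

Classification uses quadratic discriminant analysis and is evaluated by
stratified k-fold cross-validation (5 or 10 folds) repeated 30 times.
Within each repetition, confusion counts are pooled across folds to give
sensitivity Se = TP/(TP+FN), specificity Sp = TN/(TN+FP) and accuracy
CA = (TP+TN)/total; AUC is the trapezoidal area under the ROC of the pooled
positive-class posterior scores.  Reported values are means over
repetitions, in percent.  By default balancing is applied inside each
training fold only — test rows are never synthetic; ``balance_upfront``
instead balances once before CV, replicating protocols that report balanced
class sizes as the experimental population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import NearestNeighbors

from ._qda import FastQDA
from .features import FeatureMatrix

__all__ = ["ConfusionCounts", "ClassificationReport", "balance_smote",
           "balance_adasyn", "qda_fit", "qda_predict",
           "cross_validated_metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FN: int
    TN: int
    FP: int

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP

    @property
    def se(self) -> float:
        return 100.0 * self.TP / (self.TP + self.FN)

    @property
    def sp(self) -> float:
        return 100.0 * self.TN / (self.TN + self.FP)

    @property
    def ca(self) -> float:
        return 100.0 * (self.TP + self.TN) / self.total


@dataclass
class ClassificationReport:
    """Mean Se/Sp/CA/AUC (percent) with per-repetition detail."""

    se: float
    sp: float
    ca: float
    auc: float
    folds: int
    repetitions: int
    balance: str
    seed: int
    positive_label: str
    per_repetition: pd.DataFrame = field(repr=False, default=None)
    fold_counts: list[list[ConfusionCounts]] = field(repr=False,
                                                     default_factory=list)

    def to_dict(self) -> dict:
        return {"Se": self.se, "Sp": self.sp, "CA": self.ca, "AUC": self.auc,
                "folds": self.folds, "repetitions": self.repetitions,
                "balance": self.balance, "seed": self.seed,
                "positive_label": self.positive_label}


# --------------------------------------------------------------------------
# Oversampling

def _split_minority(fm: FeatureMatrix):
    counts = fm.y.value_counts()
    if len(counts) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(counts.index)}")
    minority = counts.idxmin()
    majority = counts.idxmax()
    if counts[minority] == counts[majority]:
        return None, None, 0
    return minority, majority, int(counts[majority] - counts[minority])


def _append_synthetic(fm: FeatureMatrix, rows: np.ndarray,
                      label: str) -> FeatureMatrix:
    Xs = pd.DataFrame(rows, columns=fm.X.columns)
    ys = pd.Series([label] * len(rows), dtype=object)
    meta = pd.DataFrame({"record_id": ["synthetic"] * len(rows),
                         "interval_label": ["synthetic"] * len(rows),
                         "synthetic": [True] * len(rows)})
    return FeatureMatrix(
        pd.concat([fm.X, Xs], ignore_index=True),
        pd.concat([fm.y, ys], ignore_index=True),
        pd.concat([fm.meta, meta], ignore_index=True),
        fm.positive_label, list(fm.skipped))


def _minority_neighbor_interp(Xmin: np.ndarray, base_idx: np.ndarray,
                              k: int, rng: np.random.Generator) -> np.ndarray:
    """Synthetic points on segments between minority rows and their k-NN."""
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(Xmin))).fit(Xmin)
    _, neigh = nn.kneighbors(Xmin)
    neigh = neigh[:, 1:]                           # drop self
    picks = neigh[base_idx, rng.integers(0, neigh.shape[1], base_idx.size)]
    gaps = rng.uniform(0.0, 1.0, (base_idx.size, 1))
    return Xmin[base_idx] + gaps * (Xmin[picks] - Xmin[base_idx])


def balance_smote(fm: FeatureMatrix, k_neighbors: int = 5,
                  seed: int = 0) -> FeatureMatrix:
    """Oversample the minority class to exact parity (SMOTE).

    Every synthetic row is a convex combination of a minority row and one
    of its ``k_neighbors`` nearest minority neighbors.  Majority rows are
    untouched; an already balanced matrix is returned unchanged.
    """
    minority, _, gap = _split_minority(fm)
    if gap == 0:
        return fm
    Xmin = fm.X.values[fm.y.values == minority].astype(np.float64)
    if len(Xmin) < k_neighbors + 1:
        raise ValueError(
            f"minority class of {len(Xmin)} rows too small for "
            f"k_neighbors={k_neighbors}; use a smaller k")
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(Xmin), gap)
    synth = _minority_neighbor_interp(Xmin, base, k_neighbors, rng)
    return _append_synthetic(fm, synth, minority)


def balance_adasyn(fm: FeatureMatrix, k_neighbors: int = 5,
                   seed: int = 0) -> FeatureMatrix:
    """Density-adaptive minority oversampling (ADASYN).

    Synthetic counts are allocated per minority sample proportionally to
    the fraction of majority points among its ``k_neighbors`` nearest
    neighbors in the whole data set; generation interpolates between
    minority neighbors as in SMOTE.  When every minority sample sees only
    minority neighbors the allocation degenerates to uniform.  Rounding
    makes the final minority count approximate (not exactly equal) the
    majority count.
    """
    minority, _, gap = _split_minority(fm)
    if gap == 0:
        return fm
    X = fm.X.values.astype(np.float64)
    is_min = fm.y.values == minority
    Xmin = X[is_min]
    if len(Xmin) < k_neighbors + 1:
        raise ValueError(
            f"minority class of {len(Xmin)} rows too small for "
            f"k_neighbors={k_neighbors}; use a smaller k")
    rng = np.random.default_rng(seed)

    nn_all = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, neigh = nn_all.kneighbors(Xmin)
    neigh = neigh[:, 1:]
    maj_frac = (~is_min[neigh]).mean(axis=1)
    if maj_frac.sum() == 0:
        maj_frac = np.ones_like(maj_frac)
    weights = maj_frac / maj_frac.sum()
    alloc = np.rint(weights * gap).astype(int)
    # rounding may overshoot exact parity; trim the largest allocations
    while alloc.sum() > gap:
        alloc[int(np.argmax(alloc))] -= 1

    base = np.repeat(np.arange(len(Xmin)), alloc)
    if base.size == 0:
        return fm
    synth = _minority_neighbor_interp(Xmin, base, k_neighbors, rng)
    return _append_synthetic(fm, synth, minority)


# --------------------------------------------------------------------------
# QDA

def qda_fit(X: np.ndarray, y: np.ndarray):
    """Fit a per-class-covariance Gaussian discriminant.

    A singular class covariance (e.g. a constant feature column) falls back
    to the internal discriminant with an explicit λ·trace(Σ)/d diagonal
    regularization instead of failing.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = QuadraticDiscriminantAnalysis(
                store_covariance=False).fit(X, y)
            scores = model.decision_function(X)
            if np.all(np.isfinite(scores)):
                return model
        except np.linalg.LinAlgError:
            pass
        return FastQDA().fit(X, y)


def qda_predict(model, X: np.ndarray, positive: str | None = None):
    """Predicted labels and positive-class posterior scores."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    labels = model.predict(X)
    if positive is None:
        positive = model.classes_[-1]
    if isinstance(model, FastQDA):
        return labels, model.predict_proba_of(X, positive)
    j = int(np.nonzero(model.classes_ == positive)[0][0])
    return labels, model.predict_proba(X)[:, j]


# --------------------------------------------------------------------------
# Repeated stratified cross-validation

_BALANCERS = {"none": None, "smote": balance_smote, "adasyn": balance_adasyn}


def _stratified_fold_ids(y: np.ndarray, n_folds: int,
                         rng: np.random.Generator) -> np.ndarray:
    fold = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < n_folds:
            raise ValueError(
                f"class {cls!r} has {idx.size} rows; cannot form "
                f"{n_folds} stratified folds")
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def _subset(fm: FeatureMatrix, mask: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(fm.X[mask].reset_index(drop=True),
                         fm.y[mask].reset_index(drop=True),
                         fm.meta[mask].reset_index(drop=True),
                         fm.positive_label)


def cross_validated_metrics(fm: FeatureMatrix, folds: int = 10,
                            repetitions: int = 30, balance: str = "none",
                            seed: int = 0, k_neighbors: int = 5,
                            balance_upfront: bool = False,
                            use_fast_qda: bool = True
                            ) -> ClassificationReport:
    """Repeated stratified k-fold QDA evaluation.

    With ``balance != 'none'`` and the default ``balance_upfront=False``,
    oversampling happens inside each training fold only, so evaluated rows
    are never synthetic.  Confusion counts are pooled across folds within a
    repetition; Se/Sp/CA/AUC are averaged over repetitions.
    """
    if folds not in (5, 10):
        raise ValueError(f"folds must be 5 or 10, got {folds}")
    if balance not in _BALANCERS:
        raise ValueError(f"unknown balance mode {balance!r}")
    positive = fm.positive_label
    if positive is None:
        positive = sorted(fm.y.unique())[0]

    rng_master = np.random.default_rng(seed)
    rep_seeds = rng_master.integers(0, 2**31 - 1, repetitions)

    if balance_upfront and balance != "none":
        fm = _BALANCERS[balance](fm, k_neighbors,
                                 int(rng_master.integers(0, 2**31 - 1)))
        inner_balance = "none"
    else:
        inner_balance = balance

    rep_rows = []
    all_fold_counts: list[list[ConfusionCounts]] = []
    for rep, rs in enumerate(rep_seeds):
        rng = np.random.default_rng(int(rs))
        fold_ids = _stratified_fold_ids(fm.y.values, folds, rng)
        tp = fn = tn = fp = 0
        pooled_scores, pooled_truth = [], []
        fold_counts = []
        for f in range(folds):
            te = fold_ids == f
            train = _subset(fm, ~te)
            if inner_balance != "none":
                train = _BALANCERS[inner_balance](
                    train, k_neighbors, int(rng.integers(0, 2**31 - 1)))
            Xtr, ytr = train.X.values, train.y.values
            Xte = fm.X.values[te]
            yte = fm.y.values[te]
            if use_fast_qda:
                clf = FastQDA().fit(Xtr, ytr)
                pred = clf.predict(Xte)
                score = clf.predict_proba_of(Xte, positive)
            else:
                model = qda_fit(Xtr, ytr)
                pred, score = qda_predict(model, Xte, positive)
            is_pos = yte == positive
            pred_pos = pred == positive
            ftp = int((is_pos & pred_pos).sum())
            ffn = int((is_pos & ~pred_pos).sum())
            ftn = int((~is_pos & ~pred_pos).sum())
            ffp = int((~is_pos & pred_pos).sum())
            tp, fn, tn, fp = tp + ftp, fn + ffn, tn + ftn, fp + ffp
            fold_counts.append(ConfusionCounts(ftp, ffn, ftn, ffp))
            pooled_scores.append(score)
            pooled_truth.append(is_pos)
        counts = ConfusionCounts(tp, fn, tn, fp)
        auc = 100.0 * roc_auc_score(np.concatenate(pooled_truth),
                                    np.concatenate(pooled_scores))
        rep_rows.append({"repetition": rep, "Se": counts.se, "Sp": counts.sp,
                         "CA": counts.ca, "AUC": auc})
        all_fold_counts.append(fold_counts)

    per_rep = pd.DataFrame(rep_rows)
    return ClassificationReport(
        se=float(per_rep["Se"].mean()), sp=float(per_rep["Sp"].mean()),
        ca=float(per_rep["CA"].mean()), auc=float(per_rep["AUC"].mean()),
        folds=folds, repetitions=repetitions, balance=balance, seed=seed,
        positive_label=positive, per_repetition=per_rep,
        fold_counts=all_fold_counts)
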