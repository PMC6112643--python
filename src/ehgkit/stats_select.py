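"""Separability criteria, criterion-based ranking, and SFS feature selection.

Three univariate separability measures are computed per feature from the
two class-conditional sample moments:

* ``p`` — two-sided p-value of the pooled-variance two-sample t-test;
* ``C_B`` — the Gaussian Bhattacharyya distance
  ``(μx−μy)²/(4(σx²+σy²)) + ½·ln[(σx²+σy²)/(2σxσy)]``, an upper bound on
  attainable class overlap (Chernoff bound);
* ``D_KL`` — the symmetrized Gaussian Kullback-Leibler divergence.

Multivariate subsets are selected by a wrapper: sequential forward
selection (SFS) scored by the 10-fold cross-validated misclassification
error (MCE) of a quadratic discriminant on an 80% training split, with the
MCE curve evaluated over the *entire* feature range so the global minimum
(not the first local one) decides the subset size.  Because single SFS runs
are unstable, a frequency-based aggregation repeats the run (default 200
times), accumulates a selection histogram, and returns the most frequently
selected features, their count set by the minimum of the run-averaged MCE
curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from ._qda import FastQDA
from .features import FeatureMatrix

__all__ = ["pooled_ttest", "bhattacharyya_criterion", "kl_criterion",
           "rank_features", "SfsRun", "sfs_select", "SelectionResult",
           "aggregate_selection"]


def _moments(x: np.ndarray, y: np.ndarray):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 samples")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    return x.mean(), y.mean(), vx, vy


def pooled_ttest(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p of the equal-variance two-sample t-test."""
    mx, my, vx, vy = _moments(x, y)
    pooled = ((len(x) - 1) * vx + (len(y) - 1) * vy) / (len(x) + len(y) - 2)
    if pooled <= 0:
        raise ValueError("degenerate (zero) pooled variance")
    return float(sstats.ttest_ind(x, y, equal_var=True).pvalue)


def bhattacharyya_criterion(x: np.ndarray, y: np.ndarray) -> float:
    """Gaussian Bhattacharyya distance from sample moments (>= 0)."""
    mx, my, vx, vy = _moments(x, y)
    if vx <= 0 or vy <= 0:
        raise ValueError("zero variance in a group")
    return float(0.25 * (mx - my) ** 2 / (vx + vy)
                 + 0.5 * np.log((vx + vy) / (2.0 * np.sqrt(vx * vy))))


def kl_criterion(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetrized Gaussian KL divergence ``½[KL(x‖y) + KL(y‖x)]``."""
    mx, my, vx, vy = _moments(x, y)
    if vx <= 0 or vy <= 0:
        raise ValueError("zero variance in a group")
    d2 = (mx - my) ** 2
    kl_xy = 0.5 * (np.log(vy / vx) + (vx + d2) / vy - 1.0)
    kl_yx = 0.5 * (np.log(vx / vy) + (vy + d2) / vx - 1.0)
    return float(0.5 * (kl_xy + kl_yx))


_CRITERIA = {"C_B": bhattacharyya_criterion, "D_KL": kl_criterion,
             "p": pooled_ttest}


def _two_groups(fm: FeatureMatrix):
    classes = sorted(fm.y.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    a = fm.y.values == classes[0]
    return a, ~a


def rank_features(fm: FeatureMatrix, criterion: str = "C_B") -> pd.DataFrame:
    """Separability table: p, C_B, D_KL per feature plus a 1-based rank.

    The rank orders features by descending criterion value (ascending for
    ``p``); ties resolve to the earlier column.
    """
    if criterion not in _CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    in_a, in_b = _two_groups(fm)
    rows = {}
    for col in fm.X.columns:
        x, y = fm.X[col].values[in_a], fm.X[col].values[in_b]
        rows[col] = {name: fn(x, y) for name, fn in _CRITERIA.items()}
    table = pd.DataFrame(rows).T
    vals = table[criterion].values
    key = vals if criterion == "p" else -vals
    order = np.lexsort((np.arange(len(vals)), key))
    ranks = np.empty(len(vals), dtype=int)
    ranks[order] = np.arange(1, len(vals) + 1)
    table["rank"] = ranks
    return table


# --------------------------------------------------------------------------
# SFS wrapper selection

@dataclass
class SfsRun:
    """One SFS run: greedy feature order, MCE curve, and chosen subset."""

    order: list[str]               # features in order of addition
    mce_curve: np.ndarray          # curve[k-1] = CV MCE with k features
    subset: list[str]              # order truncated at the curve's global min
    holdout_mce: float
    seed: int


def _stratified_folds(y01: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Fold id per row, stratified and shuffled."""
    fold = np.empty(y01.size, dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y01 == cls)
        if idx.size < n_folds:
            raise ValueError(
                f"class {cls} has {idx.size} rows; need >= {n_folds} for "
                f"{n_folds}-fold CV")
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def _cv_mce(X: np.ndarray, y01: np.ndarray, cols: list[int],
            fold: np.ndarray, n_folds: int) -> float:
    Xs = X[:, cols]
    errors = 0
    for f in range(n_folds):
        te = fold == f
        clf = FastQDA().fit(Xs[~te], y01[~te])
        errors += int((clf.predict(Xs[te]) != y01[te]).sum())
    return errors / y01.size


def sfs_select(fm: FeatureMatrix, seed: int, n_folds: int = 10,
               holdout: float = 0.2) -> SfsRun:
    """One SFS run with a stratified 20% holdout and 10-fold CV QDA scoring.

    Greedy forward addition over all features; candidates are enumerated in
    descending Bhattacharyya order (tie/enumeration order only).  The full
    MCE-vs-k curve is computed and the run subset is cut at its global
    minimum (smallest k on ties).  The holdout split is used only to report
    ``holdout_mce``; it does not influence the selection.
    """
    if fm.n_rows < 20:
        raise ValueError(f"need >= 20 rows for SFS, got {fm.n_rows}")
    rng = np.random.default_rng(seed)
    classes = sorted(fm.y.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    y01 = (fm.y.values == classes[1]).astype(int)
    X = fm.X.values.astype(np.float64)
    names = list(fm.X.columns)

    # stratified holdout
    test_mask = np.zeros(y01.size, dtype=bool)
    for cls in (0, 1):
        idx = np.flatnonzero(y01 == cls)
        rng.shuffle(idx)
        test_mask[idx[:max(1, int(round(holdout * idx.size)))]] = True
    Xtr, ytr = X[~test_mask], y01[~test_mask]

    # enumeration order: descending C_B on the training split
    cb = []
    for j in range(X.shape[1]):
        try:
            cb.append(bhattacharyya_criterion(Xtr[ytr == 0, j],
                                              Xtr[ytr == 1, j]))
        except ValueError:
            cb.append(-np.inf)
    enum_order = list(np.lexsort((np.arange(len(cb)), -np.asarray(cb))))

    fold = _stratified_folds(ytr, n_folds, rng)
    selected: list[int] = []
    remaining = list(enum_order)
    curve = np.empty(X.shape[1])
    for k in range(X.shape[1]):
        best_j, best_mce = None, np.inf
        for j in remaining:
            mce = _cv_mce(Xtr, ytr, selected + [j], fold, n_folds)
            if mce < best_mce:
                best_j, best_mce = j, mce
        selected.append(best_j)
        remaining.remove(best_j)
        curve[k] = best_mce

    n_sel = int(np.argmin(curve)) + 1
    subset_idx = selected[:n_sel]
    clf = FastQDA().fit(Xtr[:, subset_idx], ytr)
    hold_mce = float(
        (clf.predict(X[test_mask][:, subset_idx]) != y01[test_mask]).mean())
    return SfsRun([names[j] for j in selected], curve,
                  [names[j] for j in subset_idx], hold_mce, seed)


@dataclass
class SelectionResult:
    """Aggregated SFS selection over many runs."""

    histogram: dict[str, int]      # feature -> selection count over runs
    avg_mce_curve: np.ndarray
    n_selected: int
    final_subset: list[str]
    runs: int
    master_seed: int
    run_curves: np.ndarray = field(repr=False, default=None)
    run_subsets: list[list[str]] = field(repr=False, default_factory=list)
    holdout_mces: list[float] = field(repr=False, default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "histogram": self.histogram,
            "avg_mce_curve": list(map(float, self.avg_mce_curve)),
            "n_selected": self.n_selected,
            "final_subset": self.final_subset,
            "runs": self.runs,
            "master_seed": self.master_seed,
            "holdout_mces": list(map(float, self.holdout_mces)),
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def aggregate_selection(fm: FeatureMatrix, runs: int = 200,
                        master_seed: int = 0, n_folds: int = 10
                        ) -> SelectionResult:
    """Frequency-based aggregation of ``runs`` SFS runs.

    The subset size is the argmin of the run-averaged MCE curve; the final
    subset contains the most frequently selected features, ranked by
    histogram count (ties: earlier average selection position, then column
    order).
    """
    if runs < 1:
        raise ValueError(f"runs must be >= 1, got {runs}")
    seeds = np.random.SeedSequence(master_seed).generate_state(runs) % (2**31)
    names = list(fm.X.columns)
    counts = {n: 0 for n in names}
    pos_sum = {n: 0.0 for n in names}
    curves = np.empty((runs, len(names)))
    subsets, holdouts = [], []
    for i, s in enumerate(seeds):
        run = sfs_select(fm, int(s), n_folds=n_folds)
        curves[i] = run.mce_curve
        subsets.append(run.subset)
        holdouts.append(run.holdout_mce)
        for pos, f in enumerate(run.subset):
            counts[f] += 1
            pos_sum[f] += pos
    avg_curve = curves.mean(axis=0)
    n_selected = int(np.argmin(avg_curve)) + 1
    col_idx = {n: j for j, n in enumerate(names)}

    def sort_key(n):
        mean_pos = pos_sum[n] / counts[n] if counts[n] else np.inf
        return (-counts[n], mean_pos, col_idx[n])

    ranked = sorted([n for n in names if counts[n] > 0], key=sort_key)
    final = ranked[:n_selected]
    return SelectionResult(counts, avg_curve, n_selected, final, runs,
                           master_seed, curves, subsets, holdouts)
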