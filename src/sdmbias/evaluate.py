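"""Spatial block cross-validated evaluation of SDMs against truth.

Models are trained on events whose cells lie outside a fold's blocks and
asked to predict every active cell inside them; because the folds
partition the extent, pooling the held-out predictions yields exactly one
prediction per active cell, evaluated against the species' true realised
presence/absence.  The evaluation set is therefore spatially even and
identical across every bias / sample-size / method arm.

Metrics: rank-based AUC (ties contribute one half), Cohen's Kappa
maximised over binarisation thresholds (score midpoints plus extremes;
smallest maximiser reported), and RMSE of the scores against the 0/1
truth (calibration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .envfields import EnvStack
from .errors import UndefinedMetricError
from .grid import BlockPartition, GridExtent
from .sampling import DetectionMatrix
from .sdm import (
    STATUS_FAILED,
    STATUS_FITTED,
    STATUS_SKIPPED,
    build_training_set,
    fit_brt,
    fit_glm,
    fit_idw,
)
from .species import Community


def auc(scores, labels) -> float:
    """Mann-Whitney (rank-based) AUC; tied scores contribute one half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("AUC needs both classes")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def kappa_max(scores, labels) -> tuple[float, float]:
    """Maximum Cohen's Kappa over thresholds, with the smallest maximiser.

    Candidate thresholds are the midpoints between sorted unique scores
    plus one below the minimum and one above the maximum; a score counts
    as a predicted presence when it exceeds the threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = y.size
    n1 = int(y.sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("Kappa needs both classes")
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    thresholds = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    # cumulative counts of labels sorted by score give the confusion
    # matrix at every threshold in one pass
    order = np.argsort(s, kind="stable")
    s_sorted = s[order]
    ones_below = np.concatenate(([0], np.cumsum(y[order])))
    best_kappa, best_t = -np.inf, None
    for t in thresholds:
        k = int(np.searchsorted(s_sorted, t, side="right"))
        fn = ones_below[k]              # true 1 predicted 0
        tp = n1 - fn
        tn = k - fn
        fp = n0 - tn
        po = (tp + tn) / n
        pyes = (tp + fp) / n
        ptrue = n1 / n
        pe = pyes * ptrue + (1 - pyes) * (1 - ptrue)
        kappa = 0.0 if abs(1 - pe) < 1e-15 else (po - pe) / (1 - pe)
        if kappa > best_kappa + 1e-12:
            best_kappa, best_t = kappa, float(t)
    return float(best_kappa), best_t


def rmse(scores, labels) -> float:
    """Root mean squared error of scores against the 0/1 truth."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.size == 0:
        raise UndefinedMetricError("rmse of an empty vector")
    return float(np.sqrt(np.mean((s - y) ** 2)))


@dataclass(frozen=True)
class FoldResult:
    """Predictions for the cells of one held-out fold."""

    fold: int
    cell_index: np.ndarray   # positional indices of held-out cells
    predictions: np.ndarray | None
    truth: np.ndarray
    status: str


@dataclass
class PerformanceRecord:
    """One species x method x arm evaluation outcome."""

    species: int
    method: str
    bias_label: str = "custom"
    bias_evenness: float = np.nan
    sample_size: float = np.nan
    status: str = "skipped"
    auc: float = np.nan
    kappa: float = np.nan
    kappa_threshold: float = np.nan
    rmse: float = np.nan
    prevalence: float = np.nan
    n_folds_fitted: int = 0
    n_folds: int = 0
    folds: list = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("species", "method", "bias_label", "bias_evenness",
                 "sample_size", "status", "auc", "kappa", "kappa_threshold",
                 "rmse", "prevalence", "n_folds_fitted", "n_folds")}


_FITTERS = {
    "glm": lambda train, grid, seed, kw: fit_glm(train),
    "brt": lambda train, grid, seed, kw: fit_brt(train, seed=seed, **kw),
    "idw": lambda train, grid, seed, kw: fit_idw(train, grid, **kw),
}


def run_blocked_cv(focal: int, community: Community, matrix: DetectionMatrix,
                   env: EnvStack, grid: GridExtent,
                   partition: BlockPartition, method: str,
                   predictor_names, seed: int = 0,
                   method_kwargs: dict | None = None,
                   keep_folds: bool = False) -> PerformanceRecord:
    """Train/test one species with one method under spatial block CV.

    For each fold, events in cells outside the fold's blocks train the
    model (subject to the >5-presences gate) and every active cell inside
    the fold is predicted.  A species counts as successfully modeled only
    when every fold's model fitted; held-out predictions are then pooled
    across folds — exactly one prediction per active cell — before
    computing the three metrics once.  Requiring all folds keeps the
    pooled evaluation set identical across bias/sample-size/method arms,
    so arm contrasts are never confounded by which parts of space could
    be evaluated.
    """
    if method not in _FITTERS:
        raise ValueError(f"unknown method {method!r}")
    kw = method_kwargs or {}
    truth_all = community.presence[:, focal]
    fold_of_cell = partition.fold_of_cell
    event_folds = fold_of_cell[matrix.event_cells]
    record = PerformanceRecord(species=focal, method=method,
                               prevalence=float(truth_all.mean()),
                               n_folds=partition.k_folds)
    pooled_cells, pooled_scores = [], []
    fold_results = []
    for f in range(1, partition.k_folds + 1):
        test_cells = np.flatnonzero(fold_of_cell == f)
        train_rows = np.flatnonzero(event_folds != f)
        sub = DetectionMatrix(matrix=matrix.matrix[train_rows],
                              species=matrix.species,
                              event_cells=matrix.event_cells[train_rows])
        if sub.n_events == 0:
            fold_results.append(FoldResult(f, test_cells, None,
                                           truth_all[test_cells],
                                           STATUS_SKIPPED))
            continue
        train = build_training_set(sub, env, focal, predictor_names)
        fit = _FITTERS[method](train, grid, seed + f, kw)
        if fit.status != STATUS_FITTED:
            fold_results.append(FoldResult(f, test_cells, None,
                                           truth_all[test_cells], fit.status))
            continue
        scores = fit.predict_surface(env, grid)[test_cells]
        fold_results.append(FoldResult(f, test_cells, scores,
                                       truth_all[test_cells], STATUS_FITTED))
        pooled_cells.append(test_cells)
        pooled_scores.append(scores)
    statuses = [fr.status for fr in fold_results]
    record.n_folds_fitted = statuses.count(STATUS_FITTED)
    if keep_folds:
        record.folds = fold_results
    if record.n_folds_fitted < partition.k_folds:
        record.status = (STATUS_FAILED if STATUS_FAILED in statuses
                         else "skipped")
        return record
    cells = np.concatenate(pooled_cells)
    scores = np.concatenate(pooled_scores)
    truth = truth_all[cells]
    try:
        record.auc = auc(scores, truth)
        record.kappa, record.kappa_threshold = kappa_max(scores, truth)
        record.rmse = rmse(scores, truth)
        record.status = "evaluated"
    except UndefinedMetricError:
        record.status = STATUS_FAILED
    return record


def records_to_frame(records: list[PerformanceRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records])
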