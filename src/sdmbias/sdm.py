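"""The three species distribution model families.

Each method is a small model class built from an :class:`SDMTrainingSet`
whose ``fit()`` returns an :class:`SDMResults` carrying the fitted
parameters, a status, diagnostics and a ``summary()`` table; prediction
surfaces hang off the results object.  The modelled quantity is the
probability of the focal species being recorded on a checklist.

All methods share one gate: a model is only attempted when the training
data contain more than five presences; otherwise the results object has
status ``skipped_insufficient_presences`` and no predictions.

* :class:`ChecklistGLM` — logistic regression with linear and quadratic
  terms, complexity-controlled by a term budget of one non-intercept term
  per ten observations of the rarer response class, searched by
  forward-backward stepwise AIC under the hierarchy rule (a quadratic
  term requires its linear term).
* :class:`BoostedTreesSDM` — stagewise gradient boosting with logistic
  loss at tree complexities 2 and 5; the learning rate starts at 0.01 and
  halves until the 10-fold-CV-optimal tree count reaches at least 1,000
  (or the 1e-5 rate floor), with a hard cap of 30,000 trees.
* :class:`InverseDistanceSDM` — covariate-free inverse distance-weighted
  interpolation of the 0/1 responses from training event locations, with
  power and neighbourhood size tuned by internal 5-fold random CV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from .envfields import EnvStack
from .errors import ConfigurationError, UnavailablePredictionError
from .grid import GridExtent
from .sampling import DetectionMatrix

N_PREDICTORS = 5
MIN_PRESENCES = 5          # fit only with strictly more presences than this
STATUS_FITTED = "fitted"
STATUS_SKIPPED = "skipped_insufficient_presences"
STATUS_FAILED = "failed"


@dataclass(frozen=True)
class SDMTrainingSet:
    """Per-event responses and standardised predictors for one species."""

    y: np.ndarray                 # (n_events,) 0/1 detections
    x: np.ndarray                 # (n_events, 5) standardised predictors
    cells: np.ndarray             # (n_events,) positional cell index
    predictor_names: tuple[str, ...]
    means: np.ndarray             # training-row predictor means
    sds: np.ndarray               # training-row predictor standard deviations

    @property
    def n_presences(self) -> int:
        return int(self.y.sum())

    def cell_design(self, env: EnvStack) -> np.ndarray:
        """Standardised predictor matrix for every active cell."""
        raw = env.matrix(list(self.predictor_names))
        return (raw - self.means) / self.sds


def build_training_set(matrix: DetectionMatrix, env: EnvStack,
                       focal: int, predictor_names) -> SDMTrainingSet:
    """One row per event; predictors standardised with training statistics."""
    names = tuple(predictor_names)
    if len(names) != N_PREDICTORS or len(set(names)) != N_PREDICTORS:
        raise ConfigurationError(
            f"exactly {N_PREDICTORS} distinct predictor names required")
    for n in names:
        if n not in env.names:
            raise ConfigurationError(f"unknown predictor {n!r}")
    cols = np.flatnonzero(matrix.species == focal)
    if cols.size != 1:
        raise ConfigurationError(
            f"species {focal} is not a column of the detection matrix")
    y = matrix.matrix[:, cols[0]].astype(float)
    raw = env.matrix(list(names))[matrix.event_cells]
    means = raw.mean(axis=0)
    sds = raw.std(axis=0)
    sds = np.where(sds == 0, 1.0, sds)  # constant column guard
    x = (raw - means) / sds
    return SDMTrainingSet(y=y, x=x, cells=matrix.event_cells.copy(),
                          predictor_names=names, means=means, sds=sds)


@dataclass
class SDMResults:
    """Fit results common to all three methods.

    ``model_description`` holds method-specific parameters; prediction is
    available only when ``status == "fitted"``.
    """

    method: str
    status: str
    train: SDMTrainingSet
    model_description: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    _predict_cells: object = None   # callable(env, grid) -> scores

    @property
    def fitted(self) -> bool:
        return self.status == STATUS_FITTED

    def predict_surface(self, env: EnvStack, grid: GridExtent) -> np.ndarray:
        """Per-active-cell predicted recording probability in [0, 1]."""
        if not self.fitted:
            raise UnavailablePredictionError(
                f"{self.method} fit has status {self.status!r}")
        scores = np.clip(self._predict_cells(env, grid), 0.0, 1.0)
        return scores

    def summary(self) -> str:
        lines = [f"{self.method.upper()} species distribution model",
                 "=" * 44,
                 f"status:            {self.status}",
                 f"n events:          {self.train.y.size}",
                 f"n presences:       {self.train.n_presences}",
                 f"predictors:        {', '.join(self.train.predictor_names)}"]
        for k, v in self.model_description.items():
            lines.append(f"{k + ':':<21}{v}")
        for k, v in self.diagnostics.items():
            lines.append(f"{k + ':':<21}{v}")
        return "\n".join(lines)


def _skipped(method: str, train: SDMTrainingSet) -> SDMResults:
    return SDMResults(method=method, status=STATUS_SKIPPED, train=train,
                      diagnostics={"n_presences": train.n_presences})


# ======================================================================
# GLM
# ======================================================================

def _term_column(train_x: np.ndarray, term: str,
                 names: tuple[str, ...]) -> np.ndarray:
    if term.endswith("^2"):
        j = names.index(term[:-2])
        return train_x[:, j] ** 2
    return train_x[:, names.index(term)]


@dataclass(frozen=True)
class _GlmCandidate:
    terms: tuple[str, ...]
    params: np.ndarray      # intercept first, then term coefficients
    aic: float
    penalized: bool


def _fit_glm_candidate(y: np.ndarray, x: np.ndarray,
                       names: tuple[str, ...],
                       terms: tuple[str, ...]) -> _GlmCandidate:
    design = np.column_stack(
        [np.ones(y.size)] + [_term_column(x, t, names) for t in terms])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                maxiter=100)
            params = np.asarray(res.params)
            ok = (np.all(np.isfinite(params))
                  and np.all(np.abs(params) < 1e3)
                  and np.isfinite(res.llf))
            if ok:
                return _GlmCandidate(terms=terms, params=params,
                                     aic=float(res.aic), penalized=False)
        except (np.linalg.LinAlgError, ValueError, PerfectSeparationError):
            pass
    # quasi-separated or singular: small ridge penalty fallback
    if len(terms):
        lr = LogisticRegression(C=100.0, max_iter=1000)
        lr.fit(design[:, 1:], y)
        params = np.concatenate([lr.intercept_, lr.coef_[0]])
        eta = design @ params
    else:
        p1 = np.clip(y.mean(), 1e-9, 1 - 1e-9)
        params = np.array([np.log(p1 / (1 - p1))])
        eta = np.full(y.size, params[0])
    p = np.clip(expit(eta), 1e-9, 1 - 1e-9)
    llf = float(y @ np.log(p) + (1 - y) @ np.log(1 - p))
    return _GlmCandidate(terms=terms, params=params,
                         aic=2.0 * (len(terms) + 1) - 2.0 * llf,
                         penalized=True)


class ChecklistGLM:
    """Stepwise-AIC logistic regression for checklist detection data."""

    def __init__(self, train: SDMTrainingSet):
        self.train = train

    def fit(self) -> SDMResults:
        train = self.train
        if train.n_presences <= MIN_PRESENCES:
            return _skipped("glm", train)
        y, x, names = train.y, train.x, train.predictor_names
        n_ones = int(y.sum())
        n_zeros = y.size - n_ones
        budget = min(min(n_ones, n_zeros) // 10, 2 * len(names))
        cache: dict[tuple[str, ...], _GlmCandidate] = {}

        def fit_terms(terms: tuple[str, ...]) -> _GlmCandidate:
            key = tuple(sorted(terms))
            if key not in cache:
                cache[key] = _fit_glm_candidate(y, x, names, key)
            return cache[key]

        current = fit_terms(())
        while True:
            moves: list[_GlmCandidate] = []
            in_model = set(current.terms)
            if len(current.terms) < budget:
                for n in names:
                    if n not in in_model:
                        moves.append(fit_terms(current.terms + (n,)))
                    elif f"{n}^2" not in in_model:
                        moves.append(fit_terms(current.terms + (f"{n}^2",)))
            for t in current.terms:
                # hierarchy: a linear term is removable only without its square
                if not t.endswith("^2") and f"{t}^2" in in_model:
                    continue
                moves.append(fit_terms(
                    tuple(u for u in current.terms if u != t)))
            if not moves:
                break
            best = min(moves, key=lambda c: c.aic)
            if best.aic < current.aic - 1e-9:
                current = best
            else:
                break

        chosen = current

        def predict_cells(env: EnvStack, grid: GridExtent) -> np.ndarray:
            xc = train.cell_design(env)
            design = np.column_stack(
                [np.ones(xc.shape[0])]
                + [_term_column(xc, t, names) for t in chosen.terms])
            return expit(design @ chosen.params)

        return SDMResults(
            method="glm", status=STATUS_FITTED, train=train,
            model_description={
                "terms": list(chosen.terms),
                "coefficients": {k: float(round(v, 6)) for k, v in
                                 zip(("intercept",) + chosen.terms,
                                     chosen.params)},
                "aic": round(chosen.aic, 3),
                "term_budget": budget,
                "penalized_fallback": chosen.penalized,
            },
            diagnostics={"n_presences": n_ones, "n_absences": n_zeros},
            _predict_cells=predict_cells)


def fit_glm(train: SDMTrainingSet) -> SDMResults:
    return ChecklistGLM(train).fit()


# ======================================================================
# Boosted regression trees
# ======================================================================

def _binomial_deviance(y: np.ndarray, raw: np.ndarray) -> float:
    # raw is the half log-odds decision function used by sklearn GBM
    p = np.clip(expit(raw), 1e-12, 1 - 1e-12)
    return float(-2.0 * (y @ np.log(p) + (1 - y) @ np.log(1 - p)))


def _cv_deviance_curve(x, y, learning_rate, max_leaf_nodes, cv_folds,
                       max_trees, seed, bag_fraction, chunk, stop_margin):
    """Total held-out deviance after each boosting stage, across CV folds.

    Trees are grown in warm-started chunks for all folds in lockstep; the
    search stops once the running CV-deviance minimum is ``stop_margin``
    trees behind the frontier, or at ``max_trees``.  Returns None if a
    fold degenerates to a single training class.
    """
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(x))
    models, raws, tests = [], [], []
    for f, (tr, te) in enumerate(folds):
        if len(np.unique(y[tr])) < 2:
            return None
        m = GradientBoostingClassifier(
            learning_rate=learning_rate, max_leaf_nodes=max_leaf_nodes,
            max_depth=None, subsample=bag_fraction, n_estimators=chunk,
            warm_start=True, random_state=seed + 17 * f)
        models.append(m)
        tests.append((x[te], y[te]))
        raws.append(None)
    curve: list[float] = []
    grown = 0
    while grown < max_trees:
        n_target = min(grown + chunk, max_trees)
        stage_dev = np.zeros(n_target - grown)
        for i, m in enumerate(models):
            tr, _ = folds[i]
            m.set_params(n_estimators=n_target)
            m.fit(x[tr], y[tr])
            xt, yt = tests[i]
            if raws[i] is None:
                raws[i] = m._raw_predict_init(xt).ravel()
            raw = raws[i]
            for t in range(grown, n_target):
                raw = raw + learning_rate * m.estimators_[t, 0].predict(xt)
                stage_dev[t - grown] += _binomial_deviance(yt, raw)
            raws[i] = raw
        curve.extend(stage_dev.tolist())
        grown = n_target
        best = int(np.argmin(curve))
        if best + 1 <= grown - stop_margin:
            break
    return np.asarray(curve)


class BoostedTreesSDM:
    """Gradient-boosted trees with the capped-tree, halving-rate schedule."""

    def __init__(self, train: SDMTrainingSet, seed: int = 0,
                 tree_complexities=(2, 5), learning_rate_start: float = 0.01,
                 learning_rate_floor: float = 1e-5, min_trees: int = 1000,
                 max_trees: int = 30000, cv_folds: int = 10,
                 bag_fraction: float = 0.75, chunk: int = 250,
                 stop_margin: int = 500):
        self.train = train
        self.seed = seed
        self.tree_complexities = tuple(tree_complexities)
        self.learning_rate_start = learning_rate_start
        self.learning_rate_floor = learning_rate_floor
        self.min_trees = min_trees
        self.max_trees = max_trees
        self.cv_folds = cv_folds
        self.bag_fraction = bag_fraction
        self.chunk = chunk
        self.stop_margin = stop_margin

    def fit(self) -> SDMResults:
        train = self.train
        if train.n_presences <= MIN_PRESENCES:
            return _skipped("brt", train)
        x, y = train.x, train.y
        candidates = []
        for tc in self.tree_complexities:
            lr = self.learning_rate_start
            while True:
                curve = _cv_deviance_curve(
                    x, y, lr, max_leaf_nodes=tc + 1, cv_folds=self.cv_folds,
                    max_trees=self.max_trees, seed=self.seed,
                    bag_fraction=self.bag_fraction, chunk=self.chunk,
                    stop_margin=self.stop_margin)
                if curve is None:  # degenerate fold: refold once
                    curve = _cv_deviance_curve(
                        x, y, lr, max_leaf_nodes=tc + 1,
                        cv_folds=self.cv_folds, max_trees=self.max_trees,
                        seed=self.seed + 1, bag_fraction=self.bag_fraction,
                        chunk=self.chunk, stop_margin=self.stop_margin)
                if curve is None:
                    break
                n_opt = int(np.argmin(curve)) + 1
                if n_opt >= self.min_trees:
                    candidates.append((float(curve[n_opt - 1]), tc, lr, n_opt))
                    break
                if lr / 2.0 < self.learning_rate_floor:
                    break
                lr /= 2.0
        if not candidates:
            return SDMResults(
                method="brt", status=STATUS_FAILED, train=train,
                diagnostics={"reason": "no learning-rate schedule reached "
                                       "the minimum tree count"})
        cv_dev, tc, lr, n_opt = min(candidates)
        model = GradientBoostingClassifier(
            learning_rate=lr, max_leaf_nodes=tc + 1, max_depth=None,
            subsample=self.bag_fraction, n_estimators=n_opt,
            random_state=self.seed)
        model.fit(x, y)

        def predict_cells(env: EnvStack, grid: GridExtent) -> np.ndarray:
            return model.predict_proba(train.cell_design(env))[:, 1]

        return SDMResults(
            method="brt", status=STATUS_FITTED, train=train,
            model_description={"tree_complexity": tc, "learning_rate": lr,
                               "n_trees": n_opt,
                               "cv_deviance": round(cv_dev, 3)},
            diagnostics={"n_presences": train.n_presences},
            _predict_cells=predict_cells)


def fit_brt(train: SDMTrainingSet, seed: int = 0, **kwargs) -> SDMResults:
    return BoostedTreesSDM(train, seed=seed, **kwargs).fit()


# ======================================================================
# Inverse distance-weighted interpolation
# ======================================================================

def _idw_predict(train_cells: np.ndarray, y: np.ndarray,
                 query_cells: np.ndarray, power: float, m: int | None,
                 dist: np.ndarray) -> np.ndarray:
    """IDW prediction at query cells from training events at cell centroids.

    Events are aggregated per cell (co-located events share a distance);
    the m nearest *events* are used, taking whole cells in distance order
    and, at the boundary, a partial count of the cell's events at that
    cell's mean response.  A query cell containing training events
    predicts the exact-cell mean response.
    """
    n_cells = dist.shape[0]
    counts = np.bincount(train_cells, minlength=n_cells).astype(float)
    sums = np.bincount(train_cells, weights=y, minlength=n_cells)
    tcells = np.flatnonzero(counts)
    tmean = sums[tcells] / counts[tcells]
    tcount = counts[tcells]
    total_events = int(tcount.sum())
    m_eff = total_events if m is None else min(m, total_events)
    out = np.empty(query_cells.size)
    cache: dict[int, float] = {}
    for qi, q in enumerate(query_cells):
        q = int(q)
        if q in cache:
            out[qi] = cache[q]
            continue
        if counts[q] > 0:
            val = sums[q] / counts[q]
        else:
            d = dist[q, tcells]
            order = np.argsort(d, kind="stable")
            cum = np.cumsum(tcount[order])
            k = int(np.searchsorted(cum, m_eff))
            take = tcount[order[:k + 1]].copy()
            if k < take.size:
                take[k] = m_eff - (cum[k - 1] if k > 0 else 0)
            w = take * d[order[:k + 1]] ** (-power)
            val = float(w @ tmean[order[:k + 1]] / w.sum())
        cache[q] = val
        out[qi] = val
    return out


class InverseDistanceSDM:
    """IDW interpolation of detection outcomes, tuned by internal CV.

    Tuning uses spatially blocked 5-fold CV within the training events
    (events grouped by 100 km block, blocks assigned to folds at random):
    the tuned interpolator must generalise across space, and randomly
    split events leak spatial information between co-located training
    and test rows, which systematically selects over-local
    neighbourhoods.  ``tuning="random"`` restores a plain random split.
    """

    def __init__(self, train: SDMTrainingSet, grid: GridExtent,
                 powers=(1, 2, 3, 4), neighborhoods=(5, 10, 25, None),
                 cv_folds: int = 5, seed: int = 0, tuning: str = "spatial",
                 tuning_block_km: float = 100.0):
        self.train = train
        self.grid = grid
        self.powers = tuple(powers)
        self.neighborhoods = tuple(neighborhoods)
        self.cv_folds = cv_folds
        self.seed = seed
        self.tuning = tuning
        self.tuning_block_km = tuning_block_km

    def _tuning_folds(self, cells: np.ndarray) -> list:
        n = cells.size
        if self.tuning == "spatial":
            grid = self.grid
            ratio = max(1, int(round(self.tuning_block_km / grid.cell_side)))
            nbc = -(-grid.n_cols // ratio)
            block = (grid.rows[cells] // ratio) * nbc + grid.cols[cells] // ratio
            ublocks = np.unique(block)
            if ublocks.size >= 2:
                k = min(self.cv_folds, ublocks.size)
                rng = np.random.default_rng(self.seed)
                group_of = dict(zip(ublocks, rng.permutation(ublocks.size) % k))
                gidx = np.asarray([group_of[b] for b in block])
                return [(np.flatnonzero(gidx != g), np.flatnonzero(gidx == g))
                        for g in range(k)]
            # single-block extent: fall back to a random split
        kf = KFold(n_splits=min(self.cv_folds, n), shuffle=True,
                   random_state=self.seed)
        return list(kf.split(np.arange(n)))

    def fit(self) -> SDMResults:
        train, grid = self.train, self.grid
        if train.n_presences <= MIN_PRESENCES:
            return _skipped("idw", train)
        y, cells = train.y, train.cells
        dist = grid.pairwise_distance
        folds = self._tuning_folds(cells)
        best = None
        for power, m in product(self.powers, self.neighborhoods):
            sse, cnt = 0.0, 0
            for tr, te in folds:
                pred = _idw_predict(cells[tr], y[tr], cells[te], power, m,
                                    dist)
                sse += float(((pred - y[te]) ** 2).sum())
                cnt += te.size
            rmse = np.sqrt(sse / cnt)
            if best is None or rmse < best[0] - 1e-12:
                best = (rmse, power, m)
        cv_rmse, power, m = best

        def predict_cells(env: EnvStack, g: GridExtent) -> np.ndarray:
            return _idw_predict(cells, y, np.arange(g.n_cells), power, m,
                                g.pairwise_distance)

        return SDMResults(
            method="idw", status=STATUS_FITTED, train=train,
            model_description={"power": power,
                               "n_neighbors": "all" if m is None else m,
                               "cv_rmse": round(cv_rmse, 4)},
            diagnostics={"n_presences": train.n_presences},
            _predict_cells=predict_cells)


def fit_idw(train: SDMTrainingSet, grid: GridExtent, **kwargs) -> SDMResults:
    return InverseDistanceSDM(train, grid, **kwargs).fit()
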