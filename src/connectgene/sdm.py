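"""Presence-background ensemble species distribution modeling.

Five base learners — GLM (bidirectional stepwise AIC with squared and
interaction terms), MARS (degree-1 forward/backward pass with GCV penalty
2.0 per knot), BRT (stochastic gradient boosting, bag fraction 0.75, tree
count chosen by 3-fold cross-validation), RF (random forest with the
per-split variable count tuned by out-of-bag error) and MaxEnt (realized as
L1-penalized presence-background logistic regression over linear, quadratic
and product features) — are fitted to presences against uniformly sampled
background points.

Evaluation uses AUC (rank statistic with midrank ties) and TSS at the
threshold maximizing sensitivity + specificity (maxSSS).  Models pass a
k-fold cross-validation gate (mean AUC > 0.75 and mean TSS > 0.4, both
strict) before entering the ensemble.  Variable importance is the drop in
AUC when one covariate is permuted across evaluation points.  The ensemble
is a committee average: each model votes with its own maxSSS-binarized map
and cells with committee value strictly above 0.5 are suitable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .core import PointSet, Raster

__all__ = [
    "MODEL_KINDS",
    "EvalMetrics",
    "SdmFit",
    "EnsembleMap",
    "extract_covariates",
    "sample_background",
    "fit_sdm",
    "evaluate_predictions",
    "split_train_test",
    "cross_validate_select",
    "permutation_importance",
    "importance_table",
    "response_curve",
    "committee_ensemble",
]

log = logging.getLogger(__name__)

MODEL_KINDS = ("GLM", "MARS", "BRT", "RF", "MAXENT")


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

def _names_for(rasters: Sequence[Raster], names: Sequence[str] | None) -> list[str]:
    if names is None:
        return [f"var{i}" for i in range(len(rasters))]
    if len(names) != len(rasters):
        raise ValueError("one name per raster is required")
    return list(names)


def extract_covariates(
    rasters: Sequence[Raster], points: PointSet, names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Covariate values at point locations, one column per raster."""
    cols = {}
    for name, r in zip(_names_for(rasters, names), rasters):
        cols[name] = r.sample(points.x, points.y)
    return pd.DataFrame(cols)


def sample_background(
    rasters: Sequence[Raster], n: int, exclude: PointSet, seed: int
) -> PointSet:
    """Uniform background cells: valid in every raster, not excluded.

    Samples ``n`` distinct cell centers (label 0), never coinciding with the
    cells occupied by ``exclude`` (typically the presences).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    base = rasters[0]
    valid = np.ones(base.shape, dtype=bool)
    for r in rasters:
        if not r.is_aligned(base):
            raise ValueError("rasters are not aligned")
        valid &= r.valid_mask
    if len(exclude):
        er, ec = base.index_of(exclude.x, exclude.y, clip=True)
        valid[er, ec] = False
    rr, cc = np.nonzero(valid)
    if n > len(rr):
        raise ValueError(f"only {len(rr)} valid cells available for {n} background points")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(rr), size=n, replace=False)
    x, y = base.cell_center(rr[pick], cc[pick])
    ids = np.array([f"bg{i}" for i in range(n)], dtype=object)
    return PointSet(ids, x, y, np.zeros(n, dtype=int))


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

@dataclass
class EvalMetrics:
    auc: float
    tss: float
    threshold: float
    sensitivity: float
    specificity: float


def _auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC by the Mann–Whitney rank statistic with midrank ties."""
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _max_sss_threshold(labels: np.ndarray, scores: np.ndarray) -> float:
    """The observed score maximizing sensitivity + specificity (classify >= t).

    Ties in the objective go to the smallest threshold (most sensitive rule).
    """
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    n1 = labels.sum()
    n0 = len(labels) - n1
    # at threshold s_sorted[k]: predicted positive = indices k..end
    tp = n1 - np.concatenate([[0], np.cumsum(y_sorted)[:-1]])
    fp = n0 - np.concatenate([[0], np.cumsum(1 - y_sorted)[:-1]])
    sens = tp / n1
    spec = 1 - fp / n0
    j = sens + spec
    # collapse tied scores: only the first occurrence of each score is a
    # distinct threshold
    first = np.concatenate([[True], np.diff(s_sorted) > 0])
    j[~first] = -np.inf
    return float(s_sorted[int(np.argmax(j))])


def evaluate_predictions(
    labels: np.ndarray, scores: np.ndarray, threshold: float | None = None
) -> EvalMetrics:
    """AUC, maxSSS threshold and TSS of scores against binary labels.

    If ``threshold`` is given it is applied as-is (e.g. a threshold learned
    on training data); otherwise the maxSSS threshold of these scores is
    used.  TSS = sensitivity + specificity - 1 at the threshold, with
    classification rule score >= threshold.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(labels) != len(scores):
        raise ValueError("labels and scores must have equal length")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to evaluate")
    auc = _auc(labels, scores)
    if threshold is None:
        threshold = _max_sss_threshold(labels, scores)
    pred = scores >= threshold
    sens = float(pred[labels == 1].mean())
    spec = float((~pred[labels == 0]).mean())
    return EvalMetrics(auc=auc, tss=sens + spec - 1, threshold=float(threshold),
                       sensitivity=sens, specificity=spec)


def split_train_test(points: PointSet, fraction: float, seed: int) -> tuple[PointSet, PointSet]:
    """Stratified train/test partition of a labelled point set.

    Per class, round(fraction * n_class) points go to the train side.  The
    parts are disjoint and exhaustive; an error is raised if any class would
    be missing from either part.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if points.label is None:
        raise ValueError("points must carry presence/background labels")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in np.unique(points.label):
        idx = np.nonzero(points.label == cls)[0]
        n_train = int(round(fraction * len(idx)))
        if n_train == 0 or n_train == len(idx):
            raise ValueError(f"class {cls} too small to appear in both parts")
        perm = rng.permutation(idx)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return points.subset(np.sort(np.concatenate(train_idx))), points.subset(
        np.sort(np.concatenate(test_idx))
    )


# ---------------------------------------------------------------------------
# base learners
# ---------------------------------------------------------------------------

@dataclass
class SdmFit:
    """A fitted presence-background model: an opaque covariate -> probability map."""

    kind: str
    predict_fn: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    variables: list[str]
    settings: dict = field(default_factory=dict)
    threshold: float | None = None  # maxSSS threshold, set by the pipeline

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        p = np.asarray(self.predict_fn(X), dtype=float)
        return np.clip(p, 0.0, 1.0)

    def predict_raster(self, rasters: Sequence[Raster], names: Sequence[str] | None = None) -> Raster:
        base = rasters[0]
        valid = np.ones(base.shape, dtype=bool)
        for r in rasters:
            valid &= r.valid_mask
        X = np.column_stack([r.values[valid] for r in rasters])
        out = np.full(base.shape, np.nan)
        out[valid] = self.predict(X)
        return base.like(out)


def _standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    return mu, sd


def _fit_glm(X: np.ndarray, y: np.ndarray, names: list[str], settings: dict, seed: int):
    """Bidirectional stepwise AIC logistic GLM over mains, squares and interactions."""
    p = X.shape[1]
    terms: dict[str, np.ndarray] = {}
    for i in range(p):
        terms[names[i]] = X[:, i]
        terms[f"I({names[i]}^2)"] = X[:, i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            terms[f"{names[i]}:{names[j]}"] = X[:, i] * X[:, j]

    def fit(sel: list[str]):
        design = np.column_stack([np.ones(len(y))] + [terms[t] for t in sel])
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=50)
            # AIC from clipped binomial deviance: finite even under the
            # (quasi-)separation that makes the analytic log-likelihood NaN
            mu = np.clip(res.fittedvalues, 1e-12, 1 - 1e-12)
            dev = -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
            aic = dev + 2.0 * (len(sel) + 1)
        return res, aic

    current = list(names)  # start from the main-effects model
    res, best_aic = fit(current)
    max_steps = settings.get("max_steps", 30)
    for _ in range(max_steps):
        moves: list[tuple[float, str, str]] = []
        for t in terms:
            if t not in current:
                moves.append((fit(current + [t])[1], "add", t))
        for t in current:
            moves.append((fit([u for u in current if u != t])[1], "drop", t))
        if not moves:
            break
        aic, action, t = min(moves, key=lambda m: m[0])
        if aic >= best_aic - 1e-9:
            break
        best_aic = aic
        current = current + [t] if action == "add" else [u for u in current if u != t]
        if not current:
            break
    res, _ = fit(current)
    params = res.params

    def predict(Xn: np.ndarray) -> np.ndarray:
        cols = {}
        for i in range(p):
            cols[names[i]] = Xn[:, i]
            cols[f"I({names[i]}^2)"] = Xn[:, i] ** 2
        for i in range(p):
            for j in range(i + 1, p):
                cols[f"{names[i]}:{names[j]}"] = Xn[:, i] * Xn[:, j]
        design = np.column_stack([np.ones(len(Xn))] + [cols[t] for t in current])
        eta = design @ params
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-eta))

    return predict, {"terms": list(current), "aic": float(best_aic)}


def _hinge(x: np.ndarray, knot: float, sign: int) -> np.ndarray:
    return np.maximum(0.0, sign * (x - knot))


def _fit_mars(X: np.ndarray, y: np.ndarray, names: list[str], settings: dict, seed: int):
    """Degree-1 MARS: greedy forward hinge selection, GCV backward prune.

    Basis functions are reflected hinge pairs max(0, x - t), max(0, t - x)
    with knot candidates at per-variable data quantiles.  The generalized
    cross-validation criterion uses Friedman's cost-complexity with a
    penalty of 2.0 effective parameters per knot.  The retained basis is
    refitted as a logistic regression so predictions are probabilities.
    """
    n, p = X.shape
    penalty = settings.get("gcv_penalty", 2.0)
    max_terms = settings.get("max_terms", min(21, 2 * p * 5 + 1))
    n_knots = settings.get("n_knots", 15)

    candidates: list[tuple[int, float]] = []
    for j in range(p):
        qs = np.unique(np.quantile(X[:, j], np.linspace(0.05, 0.95, n_knots)))
        candidates.extend((j, float(t)) for t in qs)

    basis_cols = [np.ones(n)]
    basis_desc: list[tuple[int, float, int] | None] = [None]  # (var, knot, sign)

    def rss_of(cols: list[np.ndarray]) -> float:
        B = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        resid = y - B @ coef
        return float(resid @ resid)

    cur_rss = rss_of(basis_cols)
    while len(basis_cols) + 2 <= max_terms:
        best = None
        for j, t in candidates:
            c1 = _hinge(X[:, j], t, +1)
            c2 = _hinge(X[:, j], t, -1)
            r = rss_of(basis_cols + [c1, c2])
            if best is None or r < best[0]:
                best = (r, j, t, c1, c2)
        if best is None or best[0] >= cur_rss * (1 - 1e-6):
            break
        cur_rss, j, t, c1, c2 = best
        basis_cols += [c1, c2]
        basis_desc += [(j, t, +1), (j, t, -1)]

    def gcv(cols: list[np.ndarray], desc) -> float:
        r = rss_of(cols)
        n_terms = len(cols)
        n_knots_used = len({(d[0], d[1]) for d in desc if d is not None})
        enp = n_terms + penalty * n_knots_used
        if enp >= n:
            return np.inf
        return (r / n) / (1 - enp / n) ** 2

    # backward prune: iteratively drop the term whose removal most improves GCV
    best_cols, best_desc = list(basis_cols), list(basis_desc)
    best_gcv = gcv(best_cols, best_desc)
    cols, desc = list(basis_cols), list(basis_desc)
    while len(cols) > 1:
        trials = []
        for k in range(1, len(cols)):  # never drop the intercept
            tc = cols[:k] + cols[k + 1:]
            td = desc[:k] + desc[k + 1:]
            trials.append((gcv(tc, td), tc, td))
        g, cols, desc = min(trials, key=lambda m: m[0])
        if g < best_gcv:
            best_gcv, best_cols, best_desc = g, cols, desc

    # refit retained basis as a logistic model for probability output
    B = np.column_stack(best_cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, B, family=sm.families.Binomial()).fit(maxiter=50)
    params = res.params
    final_desc = list(best_desc)

    def predict(Xn: np.ndarray) -> np.ndarray:
        cols = [
            np.ones(len(Xn)) if d is None else _hinge(Xn[:, d[0]], d[1], d[2])
            for d in final_desc
        ]
        eta = np.column_stack(cols) @ params
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-eta))

    return predict, {"n_terms": len(final_desc), "gcv": float(best_gcv)}


def _fit_brt(X: np.ndarray, y: np.ndarray, names: list[str], settings: dict, seed: int):
    """Stochastic gradient boosting with bag fraction 0.75.

    The number of trees is chosen by 3-fold cross-validated log-loss over
    the staged predictions, then the model is refitted on all data.
    """
    lr = settings.get("learning_rate", 0.1)
    n_max = settings.get("n_estimators", 200)
    n_folds = settings.get("n_folds", 3)
    depth = settings.get("max_depth", 3)
    kw = dict(learning_rate=lr, n_estimators=n_max, subsample=0.75, max_depth=depth)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    losses = np.zeros(n_max)
    for tr, va in skf.split(X, y):
        gb = GradientBoostingClassifier(random_state=seed, **kw)
        gb.fit(X[tr], y[tr])
        for stage, dec in enumerate(gb.staged_decision_function(X[va])):
            p = 1.0 / (1.0 + np.exp(-dec.ravel()))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            losses[stage] += -np.mean(y[va] * np.log(p) + (1 - y[va]) * np.log(1 - p))
    n_best = int(np.argmin(losses)) + 1
    model = GradientBoostingClassifier(random_state=seed, **{**kw, "n_estimators": n_best})
    model.fit(X, y)

    def predict(Xn: np.ndarray) -> np.ndarray:
        return model.predict_proba(Xn)[:, 1]

    return predict, {"n_trees": n_best, "learning_rate": lr}


def _fit_rf(X: np.ndarray, y: np.ndarray, names: list[str], settings: dict, seed: int):
    """Random forest with mtry (max_features) tuned by out-of-bag error."""
    n_trees = settings.get("n_estimators", 250)
    p = X.shape[1]
    candidates = settings.get("mtry_grid", list(range(1, p + 1)))
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for m in candidates:
            rf = RandomForestClassifier(
                n_estimators=n_trees, max_features=m, oob_score=True,
                random_state=seed, n_jobs=1,
            )
            rf.fit(X, y)
            oob = rf.oob_decision_function_
            ok = ~np.isnan(oob[:, 1])
            err = float(np.mean((oob[ok, 1] >= 0.5).astype(int) != y[ok]))
            if best is None or err < best[0]:
                best = (err, m, rf)
    err, m, model = best

    def predict(Xn: np.ndarray) -> np.ndarray:
        return model.predict_proba(Xn)[:, 1]

    return predict, {"mtry": int(m), "oob_error": err, "n_trees": n_trees}


def _maxent_features(X: np.ndarray) -> np.ndarray:
    p = X.shape[1]
    feats = [X, X**2]
    for i in range(p):
        for j in range(i + 1, p):
            feats.append((X[:, i] * X[:, j])[:, None])
    return np.hstack(feats)


def _fit_maxent(X: np.ndarray, y: np.ndarray, names: list[str], settings: dict, seed: int):
    """Penalized presence-background logistic density estimation.

    The standard equivalence between MaxEnt and infinitely weighted logistic
    regression is exploited: an L1-penalized logistic regression over linear,
    quadratic and product features of the standardized covariates.
    """
    C = settings.get("C", 1.0)
    F = _maxent_features(X)
    model = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", random_state=seed, max_iter=500
    )
    model.fit(F, y)

    def predict(Xn: np.ndarray) -> np.ndarray:
        return model.predict_proba(_maxent_features(Xn))[:, 1]

    return predict, {"C": C, "n_features": F.shape[1]}


_FITTERS = {"GLM": _fit_glm, "MARS": _fit_mars, "BRT": _fit_brt, "RF": _fit_rf, "MAXENT": _fit_maxent}


def fit_sdm(
    kind: str,
    presences: PointSet,
    background: PointSet,
    rasters: Sequence[Raster],
    settings: dict | None = None,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> SdmFit:
    """Fit one base learner to presences vs background points.

    Covariates are standardized internally (the fitted predictor applies the
    same transform).  A covariate that is constant over the training points
    raises an error naming it.
    """
    kind = kind.upper()
    if kind not in _FITTERS:
        raise ValueError(f"unknown model kind {kind!r}")
    if len(presences) < 2 or len(background) < 2:
        raise ValueError("at least 2 presences and 2 background points are required")
    settings = dict(settings or {})
    names = _names_for(rasters, names)
    pts = PointSet.concat([presences, background])
    X_raw = extract_covariates(rasters, pts, names).to_numpy()
    y = np.concatenate([np.ones(len(presences), dtype=int), np.zeros(len(background), dtype=int)])
    if np.any(~np.isfinite(X_raw)):
        raise ValueError("points fall on nodata cells")
    mu, sd = _standardizer(X_raw)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"covariate {names[j]!r} is constant over the training points")
    Xs = (X_raw - mu) / sd
    predict_std, info = _FITTERS[kind](Xs, y, list(names), settings, seed)

    def predict_fn(Xn: np.ndarray) -> np.ndarray:
        return predict_std((np.asarray(Xn, dtype=float) - mu) / sd)

    return SdmFit(kind=kind, predict_fn=predict_fn, variables=list(names),
                  settings={**settings, **info})


# ---------------------------------------------------------------------------
# model selection, importance, response curves, ensemble
# ---------------------------------------------------------------------------

def cross_validate_select(
    kinds: Sequence[str],
    train: PointSet,
    rasters: Sequence[Raster],
    k: int = 10,
    seed: int = 0,
    settings: dict[str, dict] | None = None,
    auc_gate: float = 0.75,
    tss_gate: float = 0.4,
    names: Sequence[str] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """k-fold cross-validation gate over the training points.

    Each kind is refitted on every fold; its maxSSS threshold is taken from
    the fold-train predictions and applied to the held-out fold.  Kinds with
    mean fold AUC strictly above ``auc_gate`` and mean fold TSS strictly
    above ``tss_gate`` are retained.  Returns the retained kinds and the
    per-kind mean metric table (the spec'd single-list return is the first
    element).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if train.label is None:
        raise ValueError("train points must carry labels")
    settings = settings or {}
    idx = np.arange(len(train))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    selected = []
    for kind in kinds:
        aucs, tsss = [], []
        for fold, (tr, te) in enumerate(skf.split(idx, train.label)):
            tr_pts = train.subset(tr)
            te_pts = train.subset(te)
            fit = fit_sdm(
                kind,
                tr_pts.subset(np.nonzero(tr_pts.label == 1)[0]),
                tr_pts.subset(np.nonzero(tr_pts.label == 0)[0]),
                rasters,
                settings.get(kind),
                seed=seed + fold,
                names=names,
            )
            X_tr = extract_covariates(rasters, tr_pts, names).to_numpy()
            thr = _max_sss_threshold(tr_pts.label, fit.predict(X_tr))
            X_te = extract_covariates(rasters, te_pts, names).to_numpy()
            m = evaluate_predictions(te_pts.label, fit.predict(X_te), threshold=thr)
            aucs.append(m.auc)
            tsss.append(m.tss)
        mean_auc, mean_tss = float(np.mean(aucs)), float(np.mean(tsss))
        passed = mean_auc > auc_gate and mean_tss > tss_gate
        rows.append({"kind": kind, "mean_auc": mean_auc, "mean_tss": mean_tss, "selected": passed})
        if passed:
            selected.append(kind)
    if not selected:
        warnings.warn(
            f"no model passed the cross-validation gate (AUC > {auc_gate}, TSS > {tss_gate})"
        )
    return selected, pd.DataFrame(rows)


def permutation_importance(
    fit: SdmFit,
    eval_points: PointSet,
    rasters: Sequence[Raster],
    variable: str,
    n_repeats: int = 10,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> float:
    """ΔAUC importance: AUC drop when one covariate is permuted.

    ΔAUC = AUC(original) - mean over repeats of AUC with ``variable``
    shuffled across the evaluation points; may be slightly negative for
    uninformative covariates.
    """
    if eval_points.label is None:
        raise ValueError("evaluation points must carry labels")
    names = _names_for(rasters, names)
    if variable not in fit.variables or variable not in names:
        raise ValueError(f"unknown variable {variable!r}")
    X = extract_covariates(rasters, eval_points, names).to_numpy()
    base_auc = _auc(eval_points.label, fit.predict(X))
    j = names.index(variable)
    rng = np.random.default_rng(seed)
    perm_aucs = []
    for _ in range(n_repeats):
        Xp = X.copy()
        Xp[:, j] = rng.permutation(Xp[:, j])
        perm_aucs.append(_auc(eval_points.label, fit.predict(Xp)))
    return float(base_auc - np.mean(perm_aucs))


def importance_table(
    fits: Sequence[SdmFit],
    eval_points: PointSet,
    rasters: Sequence[Raster],
    n_repeats: int = 10,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-(model, variable) ΔAUC with per-variable means, ranked descending."""
    names = _names_for(rasters, names)
    data = {}
    for fit in fits:
        data[fit.kind] = [
            permutation_importance(fit, eval_points, rasters, v, n_repeats, seed, names)
            for v in names
        ]
    df = pd.DataFrame(data, index=names)
    df["mean_delta_auc"] = df.mean(axis=1)
    df = df.sort_values("mean_delta_auc", ascending=False)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def response_curve(
    fits: Sequence[SdmFit],
    rasters: Sequence[Raster],
    variable: str,
    n_grid: int = 100,
    points: PointSet | None = None,
    names: Sequence[str] | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Evaluation-strip response curves, one per fitted model.

    The target variable sweeps its observed range over ``n_grid`` values
    while every other covariate is held at its mean over ``points``
    (presences + background).  Returns kind -> (grid, predicted probability).
    """
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    names = _names_for(rasters, names)
    if variable not in names:
        raise ValueError(f"unknown variable {variable!r}")
    if points is None:
        raise ValueError("points (presences + background) are required for the strip means")
    X = extract_covariates(rasters, points, names).to_numpy()
    j = names.index(variable)
    lo, hi = X[:, j].min(), X[:, j].max()
    if lo == hi:
        raise ValueError(f"variable {variable!r} is constant")
    grid = np.linspace(lo, hi, n_grid)
    strip = np.tile(X.mean(axis=0), (n_grid, 1))
    strip[:, j] = grid
    return {fit.kind: (grid, fit.predict(strip)) for fit in fits}


@dataclass
class EnsembleMap:
    """Committee-average habitat map: vote fractions and the suitable mask."""

    committee: Raster  # values in {k / n_models}
    suitable_mask: Raster  # 1 where committee > 0.5
    n_models: int


def committee_ensemble(
    fits: Sequence[SdmFit],
    thresholds: Sequence[float],
    rasters: Sequence[Raster],
    names: Sequence[str] | None = None,
) -> EnsembleMap:
    """Average the maxSSS-binarized maps of the member models.

    Each model votes 1 on cells where its predicted probability is >= its
    own threshold; the committee value is the mean vote and cells strictly
    above 0.5 form the suitable mask.
    """
    if len(fits) != len(thresholds):
        raise ValueError("one threshold per fitted model is required")
    if not fits:
        raise ValueError("at least one fitted model is required")
    base = rasters[0]
    votes = np.zeros(base.shape)
    valid = np.ones(base.shape, dtype=bool)
    for r in rasters:
        valid &= r.valid_mask
    for fit, thr in zip(fits, thresholds):
        pred = fit.predict_raster(rasters, names)
        votes += (pred.values >= thr).astype(float)
    committee = np.where(valid, votes / len(fits), np.nan)
    mask = np.where(valid, (committee > 0.5).astype(float), np.nan)
    return EnsembleMap(base.like(committee), base.like(mask), len(fits))
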