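"""Three-class drinking-event prediction models.

The protocol mirrors the reference analysis: an 80/20 row-level split,
min-max scaling fitted on training data only, SMOTE oversampling of the
two minority classes on the training side only, 10-fold cross-validated
seeded random search over the boosted-tree hyperparameter space, and a
day-of-week majority baseline.  Estimators follow scikit-learn
conventions (``fit``/``predict``/``get_params``, fitted attributes with a
trailing underscore) and compose with sklearn model selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    cohen_kappa_score,
    confusion_matrix,
    precision_recall_fscore_support,
)
from sklearn.model_selection import GroupShuffleSplit, StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from .events import CLASSES, WindowConfig
from .features import FEATURE_NAMES, TIME_ENCODINGS

__all__ = [
    "SplitConfig",
    "SearchSpace",
    "MetricsReport",
    "ModelArtifact",
    "ALGORITHMS",
    "split",
    "prepare_xy",
    "SmoteOversampler",
    "smote_oversample",
    "DayOfWeekBaseline",
    "EventClassifier",
    "evaluate",
    "cross_validated_search",
    "train_algorithms",
    "baseline_day_of_week",
    "run_grid",
    "best_cell",
]

MODEL_COLUMNS = FEATURE_NAMES + TIME_ENCODINGS

ALGORITHMS = ("xgboost", "random_forest", "decision_tree", "svm", "logistic")


@dataclass(frozen=True)
class SplitConfig:
    mode: str = "row"  # 'row' (protocol-faithful) or 'grouped' (by participant)
    test_fraction: float = 0.20
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.mode not in ("row", "grouped"):
            raise ValueError("mode must be 'row' or 'grouped'")


def split(instances: pd.DataFrame, cfg: SplitConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint train/test; grouped mode keeps each participant on one side,
    redrawing (up to 20 seeds) until every class appears on both sides."""
    if cfg.mode == "row":
        tr, te = train_test_split(
            instances,
            test_size=cfg.test_fraction,
            random_state=cfg.seed,
            stratify=instances["label"],
        )
        return tr.reset_index(drop=True), te.reset_index(drop=True)
    groups = instances["participant_id"]
    for attempt in range(20):
        gss = GroupShuffleSplit(
            n_splits=1, test_size=cfg.test_fraction, random_state=cfg.seed + attempt
        )
        itr, ite = next(gss.split(instances, groups=groups))
        tr, te = instances.iloc[itr], instances.iloc[ite]
        if set(tr["label"]) == set(instances["label"]) == set(te["label"]):
            if attempt:
                warnings.warn(f"grouped split redrawn {attempt} time(s) to cover all classes")
            return tr.reset_index(drop=True), te.reset_index(drop=True)
    warnings.warn("grouped split could not place every class on both sides")
    return tr.reset_index(drop=True), te.reset_index(drop=True)


def prepare_xy(instances: pd.DataFrame, columns=None):
    """Instance frame -> (X float matrix, y label strings, column names)."""
    cols = list(columns) if columns is not None else MODEL_COLUMNS
    X = instances[cols].astype(float).to_numpy()
    y = instances["label"].to_numpy()
    return X, y, cols


# ---------------------------------------------------------------------------
# SMOTE


class SmoteOversampler(BaseEstimator):
    """Synthetic minority oversampling: each synthetic point lies on the
    segment between a minority point and one of its k nearest same-class
    neighbors; all classes are raised to the majority count."""

    def __init__(self, k_neighbors: int = 5, random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.random_state = random_state

    def fit_resample(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        classes, counts = np.unique(y, return_counts=True)
        n_max = counts.max()
        xs, ys = [X], [y]
        for cls, cnt in zip(classes, counts):
            need = n_max - cnt
            if need == 0:
                continue
            Xc = X[y == cls]
            k = self.k_neighbors
            if cnt <= k:
                k = max(1, cnt - 1)
                warnings.warn(
                    f"class {cls!r} has only {cnt} members; reducing k to {k}"
                )
            if cnt == 1:  # no neighbor to interpolate with: replicate
                xs.append(np.repeat(Xc, need, axis=0))
                ys.append(np.repeat(cls, need))
                continue
            nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
            _, idx = nn.kneighbors(Xc)
            base = rng.integers(0, cnt, size=need)
            pick = rng.integers(1, k + 1, size=need)  # skip self at column 0
            nbr = idx[base, pick]
            u = rng.random((need, 1))
            xs.append(Xc[base] + u * (Xc[nbr] - Xc[base]))
            ys.append(np.repeat(cls, need))
        return np.vstack(xs), np.concatenate(ys)


def smote_oversample(X, y, k_neighbors: int = 5, random_state: int = 0):
    return SmoteOversampler(k_neighbors, random_state).fit_resample(X, y)


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricsReport:
    accuracy: float
    f1_macro: float
    kappa: float
    per_class: dict  # label -> {'precision': .., 'recall': .., 'f1': ..}
    confusion: np.ndarray
    n: int

    def row(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "f1_macro": self.f1_macro,
            "kappa": self.kappa,
            "n": self.n,
        }
        for cls, d in self.per_class.items():
            for k, v in d.items():
                out[f"{cls}_{k}"] = v
        return out


def evaluate(y_true, y_pred, labels=CLASSES) -> MetricsReport:
    """Accuracy, macro F1, chance-corrected kappa, and per-class P/R/F1.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginal products;
    if p_e = 1 (both sides constant and equal) kappa is defined as 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = list(labels)
    acc = accuracy_score(y_true, y_pred)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    marg = (cm.sum(0) / cm.sum()) @ (cm.sum(1) / cm.sum())
    if np.isclose(marg, 1.0):
        warnings.warn("expected agreement is 1; kappa defined as 0")
        kappa = 0.0
    else:
        kappa = cohen_kappa_score(y_true, y_pred, labels=labels)
    per_class = {
        lab: {"precision": float(p), "recall": float(r), "f1": float(f)}
        for lab, p, r, f in zip(labels, prec, rec, f1)
    }
    return MetricsReport(
        accuracy=float(acc),
        f1_macro=float(np.mean(f1)),
        kappa=float(kappa),
        per_class=per_class,
        confusion=cm,
        n=len(y_true),
    )


# ---------------------------------------------------------------------------
# estimators


class DayOfWeekBaseline(BaseEstimator, ClassifierMixin):
    """Majority-class-by-day-of-week predictor (the reference baseline).

    ``X`` may be an instance frame (uses its ``day_of_week`` column) or a
    1-column array of day-of-week codes.
    """

    def __init__(self, dow_column: str = "day_of_week"):
        self.dow_column = dow_column

    @staticmethod
    def _dow(X, col):
        if isinstance(X, pd.DataFrame):
            return X[col].to_numpy(dtype=int)
        X = np.asarray(X)
        return (X[:, 0] if X.ndim == 2 else X).astype(int)

    def fit(self, X, y):
        dow = self._dow(X, self.dow_column)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.majority_by_dow_ = {}
        for d in np.unique(dow):
            vals, counts = np.unique(y[dow == d], return_counts=True)
            self.majority_by_dow_[int(d)] = vals[np.argmax(counts)]
        vals, counts = np.unique(y, return_counts=True)
        self.global_majority_ = vals[np.argmax(counts)]
        return self

    def predict(self, X):
        check_is_fitted(self, "majority_by_dow_")
        dow = self._dow(X, self.dow_column)
        return np.array(
            [self.majority_by_dow_.get(int(d), self.global_majority_) for d in dow]
        )


def _make_model(algorithm: str, params: dict, seed: int):
    params = dict(params or {})
    if algorithm == "xgboost":
        booster = params.pop("booster", "gbtree")
        kw = dict(
            n_estimators=params.pop("n_estimators", 200),
            booster=booster,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
        if booster in ("gbtree", "dart"):
            # defaults sized for a few hundred instances x ~70 features
            kw.update(
                max_depth=int(params.pop("max_depth", 4)),
                min_child_weight=params.pop("min_child_weight", 4),
                gamma=params.pop("gamma", 0.0),
                grow_policy=params.pop("grow_policy", "depthwise"),
                subsample=params.pop("subsample", 0.9),
                colsample_bytree=params.pop("colsample_bytree", 0.8),
                tree_method="hist",
            )
        kw["learning_rate"] = params.pop("eta", params.pop("learning_rate", 0.1))
        if booster == "dart":
            kw.update(
                sample_type=params.pop("sample_type", "uniform"),
                normalize_type=params.pop("normalize_type", "tree"),
                rate_drop=params.pop("rate_drop", 0.0),
                skip_drop=params.pop("skip_drop", 0.0),
            )
        for k in ("max_depth", "min_child_weight", "gamma", "grow_policy",
                  "sample_type", "normalize_type", "rate_drop", "skip_drop"):
            params.pop(k, None)  # irrelevant for gblinear
        kw.update(params)
        return XGBClassifier(**kw)
    if algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=params.pop("n_estimators", 200), random_state=seed, **params
        )
    if algorithm == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if algorithm == "svm":
        return SVC(probability=True, random_state=seed, **params)
    if algorithm == "logistic":
        return LogisticRegression(max_iter=2000, random_state=seed, **params)
    raise ValueError(f"unknown algorithm: {algorithm!r}")


def correlation_filter_mask(X, threshold: float = 0.95) -> np.ndarray:
    """Greedy redundancy filter: walk the columns in order and drop any
    whose |Pearson r| with an already-kept column exceeds ``threshold``.
    NaNs are handled pairwise; constant columns are kept."""
    df = pd.DataFrame(np.asarray(X, dtype=float))
    corr = df.corr().abs().to_numpy()
    f = corr.shape[0]
    keep = np.zeros(f, dtype=bool)
    for j in range(f):
        kept = np.flatnonzero(keep)
        r = corr[j, kept]
        if kept.size and np.nanmax(r, initial=0.0) > threshold:
            continue
        keep[j] = True
    return keep


class EventClassifier(BaseEstimator, ClassifierMixin):
    """Redundancy filter + scaling + imputation + SMOTE + base learner.

    Feature filtering (dropping near-duplicate columns, |r| > threshold),
    min-max scaling and the median imputer are fitted on the training data
    only (a constant column maps to 0; test values outside the training
    range are not clipped), SMOTE balances the training classes only, and
    the base learner is any of the five benchmarked algorithms.
    """

    def __init__(
        self,
        algorithm: str = "xgboost",
        params: Optional[dict] = None,
        scale: bool = True,
        smote: bool = True,
        smote_k: int = 5,
        corr_threshold: Optional[float] = 0.85,
        random_state: int = 0,
    ):
        self.algorithm = algorithm
        self.params = params
        self.scale = scale
        self.smote = smote
        self.smote_k = smote_k
        self.corr_threshold = corr_threshold
        self.random_state = random_state

    def _transform(self, X):
        X = np.asarray(X, dtype=float)[:, self.feature_mask_]
        if self.scale:
            X = self.scaler_.transform(X)
        return self.imputer_.transform(X)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.isinf(X).any():
            raise ValueError("non-finite (infinite) feature values")
        self.classes_ = np.unique(y)
        if self.corr_threshold is not None:
            self.feature_mask_ = correlation_filter_mask(X, self.corr_threshold)
        else:
            self.feature_mask_ = np.ones(X.shape[1], dtype=bool)
        Xf = X[:, self.feature_mask_]
        self.scaler_ = MinMaxScaler(clip=False).fit(Xf)
        Xs = self.scaler_.transform(Xf) if self.scale else Xf
        self.imputer_ = SimpleImputer(strategy="median", keep_empty_features=True).fit(Xs)
        Xi = self.imputer_.transform(Xs)
        if not np.isfinite(Xi).all():
            raise ValueError("non-finite feature values after imputation")
        yi = y
        if self.smote:
            Xi, yi = smote_oversample(
                Xi, y, k_neighbors=self.smote_k, random_state=self.random_state
            )
        self._code = {c: i for i, c in enumerate(self.classes_)}
        self.model_ = _make_model(self.algorithm, self.params, self.random_state)
        self.model_.fit(Xi, np.array([self._code[c] for c in yi]))
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        code = self.model_.predict(self._transform(X))
        return self.classes_[np.asarray(code, dtype=int)]

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._transform(X))

    def transform_features(self, X):
        """The scaled/imputed matrix the base learner actually sees."""
        check_is_fitted(self, "model_")
        return self._transform(X)


# ---------------------------------------------------------------------------
# hyperparameter search


@dataclass
class SearchSpace:
    """Boosted-tree search ranges (random seeded sampler).

    Dart-specific parameters are drawn, and used, only when the sampled
    booster is ``dart``.
    """

    boosters: tuple = ("gbtree", "gblinear", "dart")
    max_depth: tuple = (3, 9)
    min_child_weight: tuple = (2, 10)
    eta: tuple = (1e-8, 1.0)
    gamma: tuple = (1e-8, 1.0)
    grow_policy: tuple = ("depthwise", "lossguide")
    sample_type: tuple = ("uniform", "weighted")
    normalize_type: tuple = ("tree", "forest")
    rate_drop: tuple = (1e-8, 1.0)
    skip_drop: tuple = (1e-8, 1.0)
    n_trials: int = 100
    #: boosting rounds per candidate; kept moderate so a full cross-validated
    #: search stays affordable on one core
    n_estimators: int = 60

    def sample(self, rng: np.random.Generator) -> dict:
        def loguni(lo, hi):
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

        p = {
            "booster": str(rng.choice(self.boosters)),
            "eta": loguni(*self.eta),
            "n_estimators": self.n_estimators,
        }
        if p["booster"] in ("gbtree", "dart"):
            p.update(
                max_depth=int(rng.integers(self.max_depth[0], self.max_depth[1] + 1)),
                min_child_weight=int(
                    rng.integers(self.min_child_weight[0], self.min_child_weight[1] + 1)
                ),
                gamma=loguni(*self.gamma),
                grow_policy=str(rng.choice(self.grow_policy)),
            )
        if p["booster"] == "dart":
            p.update(
                sample_type=str(rng.choice(self.sample_type)),
                normalize_type=str(rng.choice(self.normalize_type)),
                rate_drop=loguni(*self.rate_drop),
                skip_drop=loguni(*self.skip_drop),
            )
        return p


def cross_validated_search(
    X,
    y,
    space: SearchSpace,
    cv_folds: int = 10,
    seed: int = 0,
    n_trials: Optional[int] = None,
    algorithm: str = "xgboost",
    candidates: Optional[list] = None,
) -> tuple[dict, pd.DataFrame]:
    """Seeded random search maximizing mean cross-validated macro F1.

    Scaling, imputation and SMOTE are refitted inside every fold on that
    fold's training part only.  Returns (best params, trial table).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    n_trials = n_trials if n_trials is not None else space.n_trials
    if candidates is None:
        candidates = [space.sample(rng) for _ in range(n_trials)]
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    records = []
    for i, params in enumerate(candidates):
        scores = []
        for itr, iva in folds:
            clf = EventClassifier(algorithm=algorithm, params=params, random_state=seed)
            clf.fit(X[itr], y[itr])
            scores.append(evaluate(y[iva], clf.predict(X[iva])).f1_macro)
        records.append({"trial": i, "mean_f1": float(np.mean(scores)), **params})
    trials = pd.DataFrame(records)
    best = trials.loc[trials["mean_f1"].idxmax()]
    best_params = candidates[int(best["trial"])]
    return best_params, trials


# ---------------------------------------------------------------------------
# grid protocol


@dataclass
class ModelArtifact:
    day_class: str
    window: WindowConfig
    algorithm: str
    model: object
    metrics: MetricsReport
    columns: list
    seed: int

    @property
    def model_id(self) -> str:
        prefix = "WD" if self.day_class == "weekday" else "WE"
        return f"{prefix}{self.algorithm}-{self.window.tag}"


def train_algorithms(
    train: pd.DataFrame, algorithms=ALGORITHMS, seed: int = 0, smote: bool = True
) -> dict:
    """One fitted EventClassifier per algorithm on a prepared instance frame."""
    X, y, cols = prepare_xy(train)
    out = {}
    for alg in algorithms:
        out[alg] = EventClassifier(algorithm=alg, random_state=seed, smote=smote).fit(X, y)
    return out


def baseline_day_of_week(train: pd.DataFrame, test: pd.DataFrame) -> MetricsReport:
    clf = DayOfWeekBaseline().fit(train, train["label"].to_numpy())
    return evaluate(test["label"].to_numpy(), clf.predict(test))


def _cv_cell_score(X, y, folds: int, seed: int, algorithm: str, params) -> tuple[float, float]:
    """Mean cross-validated (BDE F1, kappa) on the training split — the
    validation-side score used to pick the best grid cell."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    f1s, kappas = [], []
    for itr, iva in skf.split(X, y):
        clf = EventClassifier(algorithm=algorithm, params=params, random_state=seed)
        clf.fit(X[itr], y[itr])
        rep = evaluate(y[iva], clf.predict(X[iva]))
        f1s.append(rep.per_class.get("BDE", {"f1": rep.f1_macro})["f1"])
        kappas.append(rep.kappa)
    return float(np.mean(f1s)), float(np.mean(kappas))


def run_grid(
    instances: dict[WindowConfig, pd.DataFrame],
    split_cfg: SplitConfig = SplitConfig(),
    day_classes=("weekday", "weekend"),
    algorithms=("xgboost",),
    params_by_cell: Optional[dict] = None,
    cv_select: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Evaluate every (window config, day class, algorithm) cell plus the
    day-of-week baseline; returns the result table and fitted artifacts.

    Each cell reports held-out test metrics; with ``cv_select`` the table
    also carries the training-side cross-validated BDE F1 and kappa, which
    :func:`best_cell` prefers for model selection (the held-out split stays
    untouched by selection).
    """
    rows, artifacts = [], {}
    for cfg, inst in instances.items():
        for dc in day_classes:
            sub = inst[inst["day_class"] == dc]
            if sub.empty or sub["label"].value_counts().min() < 10:
                continue
            tr, te = split(sub, split_cfg)
            base = baseline_day_of_week(tr, te)
            rows.append(
                {
                    "day_class": dc,
                    "w_hours": cfg.w_hours,
                    "d_hours": cfg.d_hours,
                    "algorithm": "baseline_dow",
                    "model_id": f"{'WD' if dc == 'weekday' else 'WE'}Baseline-{cfg.tag}",
                    **base.row(),
                }
            )
            X_tr, y_tr, cols = prepare_xy(tr)
            X_te, y_te, _ = prepare_xy(te)
            for alg in algorithms:
                params = (params_by_cell or {}).get((cfg, dc, alg))
                clf = EventClassifier(
                    algorithm=alg, params=params, random_state=split_cfg.seed
                ).fit(X_tr, y_tr)
                rep = evaluate(y_te, clf.predict(X_te))
                art = ModelArtifact(dc, cfg, alg, clf, rep, cols, split_cfg.seed)
                artifacts[(cfg, dc, alg)] = art
                row = {
                    "day_class": dc,
                    "w_hours": cfg.w_hours,
                    "d_hours": cfg.d_hours,
                    "algorithm": alg,
                    "model_id": art.model_id,
                    **rep.row(),
                }
                if cv_select:
                    cv_f1, cv_kappa = _cv_cell_score(
                        X_tr, y_tr, split_cfg.cv_folds, split_cfg.seed, alg, params
                    )
                    row["cv_BDE_f1"] = cv_f1
                    row["cv_kappa"] = cv_kappa
                rows.append(row)
    grid = pd.DataFrame(rows)
    return grid, artifacts


def best_cell(grid: pd.DataFrame, day_class: str) -> pd.Series:
    """Best non-baseline cell for a day class: highest BDE F1 with kappa as
    tie-break, preferring the cross-validated scores when present."""
    sub = grid[(grid["day_class"] == day_class) & (grid["algorithm"] != "baseline_dow")]
    if sub.empty:
        raise ValueError(f"no evaluated cells for {day_class!r}")
    keys = (
        ["cv_BDE_f1", "cv_kappa"]
        if "cv_BDE_f1" in sub.columns and sub["cv_BDE_f1"].notna().all()
        else ["BDE_f1", "kappa"]
    )
    sub = sub.sort_values(keys, ascending=False, kind="mergesort")
    return sub.iloc[0]
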