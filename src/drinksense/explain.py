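"""Explanation layer: Shapley attributions, PDPs, location maps.

Attributions are per class (one-vs-rest output margins).  Boosted-tree
models get exact tree-path Shapley values (local accuracy holds to
floating-point precision: per instance and class, the base value plus the
feature attributions equals the model margin).  Other models fall back to
a seeded permutation-sampling Shapley estimator in probability space.

Partial dependence is reported in probability space on an equal-count
(quantile) grid, centered so 0 is the expected class probability; the
two-way latitude x longitude variant and the coarsely binned
location-probability map support the privacy-versus-accuracy analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import xgboost as xgb

from .modeling import EventClassifier, MetricsReport, evaluate, prepare_xy, split

__all__ = [
    "ShapMatrix",
    "compute_shap",
    "sampling_shap",
    "global_importance",
    "ensemble_importance",
    "dependence_data",
    "pdp_1d",
    "pdp_2d_location",
    "location_probability_map",
    "privacy_accuracy_experiment",
]


@dataclass
class ShapMatrix:
    """Per-class additive attributions for a batch of instances.

    values[i, j, c] is feature j's contribution to class c's output for
    instance i; ``base`` holds the per-class expected output.  Feature
    values are in the model's (scaled) input space, aligned to ``columns``.
    """

    values: np.ndarray  # (n, n_features, n_classes)
    base: np.ndarray  # (n, n_classes)
    feature_values: np.ndarray  # (n, n_features)
    columns: list
    classes: list
    output: str  # 'margin' or 'proba'

    def for_class(self, label) -> np.ndarray:
        return self.values[:, :, list(self.classes).index(label)]


def compute_shap(
    clf: EventClassifier,
    X,
    columns=None,
    n_permutations: int = 2048,
    seed: int = 0,
    background_size: int = 64,
) -> ShapMatrix:
    """Shapley attributions for a fitted :class:`EventClassifier`.

    Tree boosters use xgboost's exact tree-path algorithm on the margin
    output; other algorithms use :func:`sampling_shap` with the given
    permutation budget.
    """
    Xt = clf.transform_features(X)
    if not np.isfinite(Xt).all():
        raise ValueError("non-finite model inputs")
    classes = list(clf.classes_)
    mask = getattr(clf, "feature_mask_", np.ones(Xt.shape[1], dtype=bool))
    n_full = mask.size
    columns = list(columns) if columns is not None else list(range(n_full))
    if clf.algorithm == "xgboost":
        booster = clf.model_.get_booster()
        contrib = booster.predict(xgb.DMatrix(Xt), pred_contribs=True)
        if contrib.ndim == 2:  # binary: (n, f+1)
            contrib = contrib[:, None, :]
        values = np.transpose(contrib[:, :, :-1], (0, 2, 1))
        base = contrib[:, :, -1]
    else:
        values, base = sampling_shap(
            lambda Z: clf.model_.predict_proba(Z),
            Xt,
            n_permutations=n_permutations,
            seed=seed,
            background_size=background_size,
        )
    # expand filtered-space attributions back to the full column set;
    # features removed by the redundancy filter contribute exactly zero
    full_values = np.zeros((values.shape[0], n_full, values.shape[2]), dtype=values.dtype)
    full_values[:, mask, :] = values
    full_feats = np.full((Xt.shape[0], n_full), np.nan)
    full_feats[:, mask] = Xt
    output = "margin" if clf.algorithm == "xgboost" else "proba"
    return ShapMatrix(full_values, base, full_feats, columns, classes, output)


def sampling_shap(
    predict,
    X,
    background: Optional[np.ndarray] = None,
    n_permutations: int = 2048,
    seed: int = 0,
    background_size: int = 64,
):
    """Permutation-sampling Shapley estimate for an arbitrary model.

    For each sampled permutation a background row is drawn; features are
    switched from the background value to the instance value in permutation
    order and the successive output differences are accumulated as marginal
    contributions.  Unbiased in the number of permutations.
    """
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    if background is None:
        idx = rng.choice(len(X), size=min(background_size, len(X)), replace=False)
        background = X[idx]
    n, f = X.shape
    B = len(background)
    out0 = np.atleast_1d(predict(background).mean(axis=0))  # expected output
    n_out = out0.shape[-1]
    values = np.zeros((n, f, n_out))
    for i in range(n):
        x = X[i]
        acc = np.zeros((f, n_out))
        for _ in range(n_permutations):
            order = rng.permutation(f)
            # (f+1) stages x B background rows, features switched to the
            # instance value in permutation order; averaging over the whole
            # background keeps local accuracy exact for additive models
            stages = np.repeat(background[None, :, :], f + 1, axis=0).copy()
            for j, feat in enumerate(order):
                stages[j + 1 :, :, feat] = x[feat]
            preds = predict(stages.reshape((f + 1) * B, f)).reshape(f + 1, B, n_out)
            diffs = np.diff(preds.mean(axis=1), axis=0)
            acc[order] += diffs
        values[i] = acc / n_permutations
    base = np.tile(out0, (n, 1))
    return values, base


def ensemble_importance(
    instances: pd.DataFrame,
    label="BDE",
    n_folds: int = 5,
    algorithm: str = "xgboost",
    params: Optional[dict] = None,
    seed: int = 0,
    k: int = 20,
    columns=None,
) -> pd.DataFrame:
    """Cross-validation-stabilized global importance.

    A single boosted model splits credit arbitrarily among strongly
    correlated features (e.g., radius of gyration vs. location variance,
    which measure the same spread).  Here one model is fitted per
    stratified fold and the per-feature mean |attribution| (over all
    instances) is averaged across the fold models, giving every member of
    a correlated group its expected share.
    """
    from sklearn.model_selection import StratifiedKFold

    X, y, cols = prepare_xy(instances, columns)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    totals = np.zeros(X.shape[1])
    # per-fold seeds and aggressive per-tree column subsampling decorrelate
    # which member of a redundant feature group each model leans on
    fold_params = dict(params or {})
    fold_params.setdefault("colsample_bytree", 0.5)
    for i, (itr, _) in enumerate(skf.split(X, y)):
        clf = EventClassifier(
            algorithm=algorithm, params=dict(fold_params), random_state=seed + i
        )
        clf.fit(X[itr], y[itr])
        sm = compute_shap(clf, X, columns=cols)
        totals += np.abs(sm.for_class(label)).mean(axis=0)
    totals /= n_folds
    order = np.argsort(-totals, kind="mergesort")
    df = pd.DataFrame(
        {"feature": np.asarray(cols, dtype=object)[order], "mean_abs_shap": totals[order]}
    )
    return df.head(k).reset_index(drop=True)


def global_importance(shap: ShapMatrix, label, k: int = 20) -> pd.DataFrame:
    """Features ranked by mean |attribution| for one class; top-k rows."""
    v = np.abs(shap.for_class(label)).mean(axis=0)
    order = np.argsort(-v, kind="mergesort")
    df = pd.DataFrame(
        {"feature": np.asarray(shap.columns, dtype=object)[order], "mean_abs_shap": v[order]}
    )
    return df.head(k).reset_index(drop=True)


def dependence_data(
    shap: ShapMatrix, feature, color_feature, label
) -> pd.DataFrame:
    """Scatter triples (feature value, attribution, color value), one per
    instance — the raw material of a dependence plot."""
    cols = list(shap.columns)
    j = cols.index(feature)
    c = cols.index(color_feature)
    return pd.DataFrame(
        {
            "feature_value": shap.feature_values[:, j],
            "shap_value": shap.for_class(label)[:, j],
            "color_value": shap.feature_values[:, c],
        }
    )


def _quantile_grid(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count grid: the centers of n_bins quantile portions."""
    qs = (np.arange(n_bins) + 0.5) / n_bins
    return np.quantile(x, qs)


def pdp_1d(
    clf,
    instances: pd.DataFrame,
    feature: str,
    label,
    n_bins: int = 9,
    columns=None,
    center: bool = True,
) -> pd.DataFrame:
    """Partial dependence of one class probability on one feature.

    The grid splits the observed feature values into ``n_bins`` equal-count
    portions; at each grid value the feature column is overwritten for every
    reference instance and the class probabilities averaged.  With
    ``center=True`` the curve is shifted so 0 is the expected (mean) class
    probability.
    """
    X, _, cols = prepare_xy(instances, columns)
    j = cols.index(feature)
    xcol = X[:, j]
    xcol = xcol[np.isfinite(xcol)]
    ci = list(clf.classes_).index(label)
    if np.allclose(xcol, xcol[0]):
        warnings.warn(f"feature {feature!r} is constant; single-point curve")
        grid = np.array([xcol[0]])
    else:
        grid = _quantile_grid(xcol, n_bins)
    baseline = clf.predict_proba(X)[:, ci].mean() if center else 0.0
    vals = []
    for g in grid:
        Xg = X.copy()
        Xg[:, j] = g
        vals.append(clf.predict_proba(Xg)[:, ci].mean() - baseline)
    return pd.DataFrame({"grid": grid, "partial_dependence": vals})


def pdp_2d_location(
    clf,
    instances: pd.DataFrame,
    label="BDE",
    lat_feature: str = "lat_mean",
    lon_feature: str = "lon_mean",
    n_bins: int = 9,
    columns=None,
) -> pd.DataFrame:
    """Two-way partial dependence of the BDE probability on mean latitude
    and longitude, on an equal-count grid; cells without observed support
    are flagged extrapolated."""
    X, _, cols = prepare_xy(instances, columns)
    ji = cols.index(lat_feature)
    jj = cols.index(lon_feature)
    ci = list(clf.classes_).index(label)
    lat_obs = X[:, ji][np.isfinite(X[:, ji])]
    lon_obs = X[:, jj][np.isfinite(X[:, jj])]
    lat_grid = np.unique(_quantile_grid(lat_obs, n_bins))
    lon_grid = np.unique(_quantile_grid(lon_obs, n_bins))
    lat_edges = np.concatenate(([-np.inf], (lat_grid[1:] + lat_grid[:-1]) / 2, [np.inf]))
    lon_edges = np.concatenate(([-np.inf], (lon_grid[1:] + lon_grid[:-1]) / 2, [np.inf]))
    support, _, _ = np.histogram2d(X[:, ji], X[:, jj], bins=[lat_edges, lon_edges])
    rows = []
    for a, glat in enumerate(lat_grid):
        Xg = X.copy()
        Xg[:, ji] = glat
        for b, glon in enumerate(lon_grid):
            Xg[:, jj] = glon
            prob = clf.predict_proba(Xg)[:, ci].mean()
            rows.append(
                {
                    "lat": glat,
                    "lon": glon,
                    "bde_probability": float(prob),
                    "support": int(support[a, b]),
                    "extrapolated": support[a, b] == 0,
                }
            )
    return pd.DataFrame(rows)


def location_probability_map(
    clf,
    instances: pd.DataFrame,
    precision: int = 1,
    label="BDE",
    min_support: int = 10,
    columns=None,
) -> pd.DataFrame:
    """Mean predicted BDE probability per coarse spatial bin.

    Coordinates are rounded to ``precision`` decimal places *before*
    binning (1 decimal ~ 11.1 km of latitude); bins supported by fewer than
    ``min_support`` instances are suppressed to avoid singleton disclosure.
    """
    if precision < 0:
        raise ValueError("precision must be >= 0")
    X, _, cols = prepare_xy(instances, columns)
    ci = list(clf.classes_).index(label)
    prob = clf.predict_proba(X)[:, ci]
    lat = np.round(instances["lat_mean"].astype(float).to_numpy(), precision)
    lon = np.round(instances["lon_mean"].astype(float).to_numpy(), precision)
    df = pd.DataFrame({"lat_bin": lat, "lon_bin": lon, "p": prob})
    agg = (
        df.groupby(["lat_bin", "lon_bin"], dropna=True)
        .agg(bde_probability=("p", "mean"), support=("p", "size"))
        .reset_index()
    )
    return agg[agg["support"] >= min_support].reset_index(drop=True)


def privacy_accuracy_experiment(
    instances: pd.DataFrame,
    split_cfg,
    precision: int = 1,
    algorithm: str = "xgboost",
    params: Optional[dict] = None,
    coordinate_features=("lat_mean", "lon_mean"),
) -> dict:
    """Retrain with coordinates rounded to ``precision`` decimals and
    compare test accuracy against the full-precision model."""
    tr, te = split(instances, split_cfg)

    def fit_eval(train, test) -> MetricsReport:
        X_tr, y_tr, _ = prepare_xy(train)
        X_te, y_te, _ = prepare_xy(test)
        clf = EventClassifier(
            algorithm=algorithm, params=params, random_state=split_cfg.seed
        ).fit(X_tr, y_tr)
        return evaluate(y_te, clf.predict(X_te))

    full = fit_eval(tr, te)
    tr_r, te_r = tr.copy(), te.copy()
    for c in coordinate_features:
        tr_r[c] = tr_r[c].astype(float).round(precision)
        te_r[c] = te_r[c].astype(float).round(precision)
    rounded = fit_eval(tr_r, te_r)
    return {
        "full_accuracy": full.accuracy,
        "rounded_accuracy": rounded.accuracy,
        "accuracy_drop": full.accuracy - rounded.accuracy,
        "full_f1_macro": full.f1_macro,
        "rounded_f1_macro": rounded.f1_macro,
    }
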