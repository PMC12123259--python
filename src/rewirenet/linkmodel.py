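"""Boosted-tree interaction classifier: features, fitting, evaluation.

The model predicts the probability that a resource/consumer pair can
interact, from the concatenated traits of both species plus their taxon
groups.  Gradient-boosted trees (LightGBM) with conventional
boosted-regression-tree settings: slow learning rate, shallow trees,
bagging, tree count chosen by early stopping on held-out deviance.
"""

from __future__ import annotations

from dataclasses import dataclass

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    cohen_kappa_score,
    matthews_corrcoef,
    roc_auc_score,
)
from sklearn.model_selection import KFold, StratifiedKFold

from .dataio import TraitTable

#: default training parameters (overridable per call)
DEFAULT_PARAMS = {
    "learning_rate": 0.01,
    "max_depth": 3,
    "num_leaves": 8,
    "n_estimators": 5000,
    "subsample": 0.5,  # bag fraction
    "subsample_freq": 1,
    "min_child_samples": 5,
    "early_stopping_rounds": 100,
    "tree_selection_folds": 5,
}

THRESHOLD_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)


class FittingError(RuntimeError):
    pass


class SchemaMismatchError(ValueError):
    pass


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def _encoders(table: TraitTable, prefix: str) -> dict:
    """Target-independent integer codes for every categorical column."""
    enc = {f"{prefix}_taxon_group": {v: i for i, v in enumerate(sorted(table.data["taxon_group"].unique()))}}
    for t in table.categorical_traits():
        enc[f"{prefix}_{t}"] = {v: i for i, v in enumerate(table.schema[t]["levels"])}
    return enc


def build_features(
    pairs: pd.DataFrame,
    resource: TraitTable,
    consumer: TraitTable,
    encoders: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """One feature row per (resource_id, consumer_id) pair.

    Columns are the resource traits (prefixed ``res_``), consumer traits
    (``con_``) and both taxon groups, in a deterministic order;
    categoricals are replaced by recorded integer codes so that fit-time
    and predict-time encodings are identical.  Returns the feature frame
    and the encoder mapping used.
    """
    if encoders is None:
        encoders = {**_encoders(resource, "res"), **_encoders(consumer, "con")}
    res_cols = ["taxon_group"] + resource.trait_names
    con_cols = ["taxon_group"] + consumer.trait_names
    try:
        rblock = resource.data.loc[pairs["resource_id"], res_cols].reset_index(drop=True)
        cblock = consumer.data.loc[pairs["consumer_id"], con_cols].reset_index(drop=True)
    except KeyError as exc:
        raise SchemaMismatchError(f"pair references unknown species: {exc.args[0]!r}") from exc
    rblock.columns = [f"res_{c}" for c in res_cols]
    cblock.columns = [f"con_{c}" for c in con_cols]
    x = pd.concat([rblock, cblock], axis=1)
    for col, mapping in encoders.items():
        if col not in x.columns:
            raise SchemaMismatchError(f"encoded column {col!r} missing from feature table")
        unknown = set(x[col].unique()) - set(mapping)
        if unknown:
            raise SchemaMismatchError(f"unseen categorical value(s) {sorted(unknown)} in {col!r}")
        x[col] = x[col].map(mapping).astype(int)
    return x.astype(float), encoders


@dataclass
class LinkModel:
    """A fitted boosted-tree interaction classifier plus its provenance."""

    booster: lgb.Booster
    params: dict
    feature_names: list
    encoders: dict
    importance: pd.DataFrame  # feature, gain; descending
    seed: int
    n_trees: int

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        if list(features.columns) != self.feature_names:
            raise SchemaMismatchError(
                "feature schema drift between fit and predict: "
                f"expected {self.feature_names}, got {list(features.columns)}"
            )
        return self.booster.predict(features.to_numpy(), num_iteration=self.n_trees)


def _lgb_params(params: dict, seed: int) -> dict:
    return {
        "objective": "binary",
        "verbosity": -1,
        "learning_rate": params["learning_rate"],
        "max_depth": params["max_depth"],
        "num_leaves": params["num_leaves"],
        "bagging_fraction": params["subsample"],
        "bagging_freq": params["subsample_freq"],
        "min_data_in_leaf": params["min_child_samples"],
        "seed": seed,
        "deterministic": True,
        "force_row_wise": True,
        "num_threads": 1,
    }


def _select_n_trees(xv: np.ndarray, y: np.ndarray, p: dict, seed: int) -> int:
    """Tree count minimising cross-validated binary deviance (early stopped)."""
    nfold = int(min(p["tree_selection_folds"], max(np.bincount(y).min(), 2)))
    cvr = lgb.cv(
        _lgb_params(p, seed),
        lgb.Dataset(xv, y),
        num_boost_round=p["n_estimators"],
        nfold=nfold,
        stratified=True,
        seed=seed,
        callbacks=[lgb.early_stopping(p["early_stopping_rounds"], verbose=False)],
    )
    return max(len(cvr["valid binary_logloss-mean"]), 1)


def fit(
    pairs: pd.DataFrame,
    resource: TraitTable,
    consumer: TraitTable,
    params: dict | None = None,
    seed: int = 0,
) -> LinkModel:
    """Fit the interaction model on labelled pairs.

    The number of trees is selected by early stopping of the
    cross-validated binary deviance (stratified folds), then the model is
    refit on all rows with that tree count.  Reproducible given the seed.
    """
    p = {**DEFAULT_PARAMS, **(params or {})}
    y = pairs["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise FittingError("training data contains a single class")
    x, encoders = build_features(pairs, resource, consumer)
    lp = _lgb_params(p, seed)
    n_trees = _select_n_trees(x.to_numpy(), y, p, seed)
    final = lgb.train(
        lp,
        lgb.Dataset(x.to_numpy(), y, feature_name=list(x.columns)),
        num_boost_round=n_trees,
    )
    imp = pd.DataFrame(
        {"feature": list(x.columns), "gain": final.feature_importance("gain")}
    ).sort_values("gain", ascending=False, ignore_index=True)
    return LinkModel(final, p, list(x.columns), encoders, imp, seed, n_trees)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalMetrics:
    """Discrimination and confusion-based scores for one score vector.

    AUC is the Mann-Whitney rank statistic; PR-AUC uses step (average
    precision) interpolation; accuracy/kappa/MCC come from the confusion
    table at the classification rule ``score > threshold``.
    """

    auc: float
    pr_auc: float
    accuracy: float
    kappa: float
    mcc: float
    tp: int
    fp: int
    fn: int
    tn: int
    threshold: float

    def as_dict(self) -> dict:
        return {
            "auc": self.auc, "pr_auc": self.pr_auc, "accuracy": self.accuracy,
            "kappa": self.kappa, "mcc": self.mcc, "tp": self.tp, "fp": self.fp,
            "fn": self.fn, "tn": self.tn, "threshold": self.threshold,
        }


def evaluate(labels: np.ndarray, scores: np.ndarray, threshold: float = 0.4) -> EvalMetrics:
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC/PR-AUC undefined for a single-class label vector")
    pred = (scores > threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    return EvalMetrics(
        auc=float(roc_auc_score(labels, scores)),
        pr_auc=float(average_precision_score(labels, scores)),
        accuracy=float(accuracy_score(labels, pred)),
        kappa=float(cohen_kappa_score(labels, pred)),
        mcc=float(matthews_corrcoef(labels, pred)),
        tp=tp, fp=fp, fn=fn, tn=tn, threshold=threshold,
    )


@dataclass
class CVResult:
    """Pooled out-of-fold scores and the metrics computed from them."""

    scores: np.ndarray  # out-of-fold score per row, original order
    labels: np.ndarray
    fold: np.ndarray
    metrics: EvalMetrics  # at threshold 0.4
    metrics_05: EvalMetrics  # at threshold 0.5


def cross_validate(
    pairs: pd.DataFrame,
    resource: TraitTable,
    consumer: TraitTable,
    k: int = 10,
    params: dict | None = None,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation; each row scored exactly once
    by a model whose training folds exclude it."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    p = {**DEFAULT_PARAMS, **(params or {})}
    y = pairs["label"].to_numpy()
    if len(y) < k:
        raise ValueError(f"n={len(y)} rows cannot fill k={k} folds")
    x, _ = build_features(pairs, resource, consumer)
    xv = x.to_numpy()
    scores = np.full(len(y), np.nan)
    fold_of = np.full(len(y), -1)
    # stratify folds by label unless a class is rarer than the fold count
    # (e.g. leave-one-out), where stratification is impossible
    if min(np.bincount(y)) >= k:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        skf = KFold(n_splits=k, shuffle=True, random_state=seed)
    lp = _lgb_params(p, seed)
    for f, (tr, te) in enumerate(skf.split(xv, y)):
        n_trees = _select_n_trees(xv[tr], y[tr], p, seed + f)
        refit = lgb.train(
            lp,
            lgb.Dataset(xv[tr], y[tr], feature_name=list(x.columns)),
            num_boost_round=n_trees,
        )
        scores[te] = refit.predict(xv[te])
        fold_of[te] = f
    return CVResult(
        scores=scores,
        labels=y,
        fold=fold_of,
        metrics=evaluate(y, scores, 0.4),
        metrics_05=evaluate(y, scores, 0.5),
    )


def choose_threshold(
    labels: np.ndarray,
    scores: np.ndarray,
    method: str = "fixed",
    fixed: float = 0.4,
) -> float:
    """Pruning threshold for the metanetwork.

    ``fixed`` returns the configured value (default 0.4).  ``max_kappa``
    and ``max_youden`` search the grid {0.01, ..., 0.99} for the value
    maximising Cohen's kappa or Youden's J (sensitivity + specificity - 1),
    ties broken by the smallest threshold.
    """
    if method == "fixed":
        return fixed
    if method not in ("max_kappa", "max_youden"):
        raise ValueError(f"unknown threshold method {method!r}")
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    best_tau, best_val = None, -np.inf
    for tau in THRESHOLD_GRID:
        pred = (scores > tau).astype(int)
        if method == "max_kappa":
            val = cohen_kappa_score(labels, pred)
        else:
            pos, neg = labels == 1, labels == 0
            sens = np.mean(pred[pos]) if pos.any() else 0.0
            spec = np.mean(1 - pred[neg]) if neg.any() else 0.0
            val = sens + spec - 1.0
        if val > best_val + 1e-12:  # strict improvement => smallest tau wins ties
            best_tau, best_val = float(tau), float(val)
    return best_tau
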