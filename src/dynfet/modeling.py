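"""Class-balanced logistic modelling of mutation status from radiomic features.

The modelling chain mirrors common radiomics practice: a stratified 70/30
cohort split; per-feature z-standardisation with training-cohort statistics
only; removal of near-duplicate features (|Pearson r| > 0.99); recursive
feature elimination (RFE) under a class-balanced, L2-regularised logistic
regression, with the feature count chosen by mean out-of-fold AUC over
stratified 10-fold cross-validation; and a final balanced logistic fit

    P(y = 1 | x; theta) = 1 / (1 + exp(-(theta0 + theta^T x))),

with "mutant" called when P > 0.5.  Evaluation reports AUC, accuracy,
sensitivity, specificity, PPV and NPV with 95% percentile confidence
intervals from 1000 stratified bootstrap resamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSplit",
    "StandardizationParams",
    "LogisticModel",
    "EvaluationReport",
    "stratified_split",
    "standardize",
    "apply_standardization",
    "pcc_filter",
    "balanced_class_weights",
    "rfe_rank",
    "select_n_features",
    "fit_final_model",
    "predict_probability",
    "evaluate",
]

#: Regularisation strength (inverse) of every logistic fit in the chain.
LOGISTIC_C = 1.0
_MAX_ITER = 1000


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class CohortSplit:
    train_ids: tuple
    test_ids: tuple
    train_fraction: float
    seed: int


@dataclass
class StandardizationParams:
    """Per-feature mean and population (divisor n) standard deviation."""

    mean: pd.Series
    sd: pd.Series
    dropped: tuple = ()


@dataclass
class LogisticModel:
    selected_features: tuple
    theta: np.ndarray
    intercept: float
    class_weights: dict
    decision_threshold: float = 0.5


@dataclass
class EvaluationReport:
    metrics: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    n_bootstrap: int
    positive_class: str = "mutant"


def stratified_split(
    labels: pd.Series, train_fraction: float = 0.7, seed: int = 0
) -> CohortSplit:
    """Per-class shuffle-and-take split; training size per class is
    ``round(class_size * train_fraction)`` (half-up), remainder to testing."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    labels = pd.Series(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in sorted(labels.unique()):
        ids = np.array(sorted(labels.index[labels == cls]), dtype=object)
        rng.shuffle(ids)
        n_train = _round_half_up(len(ids) * train_fraction)
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    return CohortSplit(tuple(train), tuple(test), train_fraction, seed)


def standardize(
    train_table: pd.DataFrame, test_table: pd.DataFrame | None = None
) -> tuple[StandardizationParams, pd.DataFrame, pd.DataFrame | None]:
    """Z-standardise with training statistics only; constant features are dropped."""
    if len(train_table) < 2:
        raise ValueError("standardisation needs >= 2 training rows")
    mean = train_table.mean()
    sd = train_table.std(ddof=0)
    dropped = tuple(sd.index[sd == 0])
    if dropped:
        logger.warning("dropping %d constant feature(s): %s", len(dropped), dropped[:5])
    keep = [c for c in train_table.columns if c not in dropped]
    params = StandardizationParams(mean[keep], sd[keep], dropped)
    train_z = apply_standardization(train_table, params)
    test_z = apply_standardization(test_table, params) if test_table is not None else None
    return params, train_z, test_z


def apply_standardization(table: pd.DataFrame, params: StandardizationParams) -> pd.DataFrame:
    return (table[params.mean.index] - params.mean) / params.sd


def pcc_filter(train_table: pd.DataFrame, threshold: float = 0.99) -> list[str]:
    """Drop the later of any feature pair with |Pearson r| above the threshold.

    Features are visited in alphabetical order; for each ordered pair
    ``(i, j)`` with ``i`` retained and ``|r| > threshold``, ``j`` is dropped,
    so the survivor set is deterministic and pairwise below the threshold.
    """
    cols = sorted(train_table.columns)
    if len(cols) < 2:
        return cols
    X = train_table[cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    keep: list[str] = []
    keep_idx: list[int] = []
    for j, name in enumerate(cols):
        r = np.abs(corr[keep_idx, j])
        if np.any(np.nan_to_num(r) > threshold):
            continue
        keep.append(name)
        keep_idx.append(j)
    return keep


def balanced_class_weights(labels: pd.Series) -> dict:
    """``w_k = n_total / (n_classes * n_k)`` — the 'balanced' convention."""
    labels = pd.Series(labels)
    counts = labels.value_counts()
    if (counts == 0).any() or len(counts) < 1:
        raise ValueError("every class needs at least one member")
    n, k = len(labels), len(counts)
    return {cls: n / (k * counts[cls]) for cls in sorted(counts.index)}


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> LogisticRegression:
    clf = LogisticRegression(
        class_weight="balanced", C=LOGISTIC_C, solver="lbfgs", max_iter=_MAX_ITER
    )
    clf.fit(X, y)
    return clf


def rfe_rank(X: pd.DataFrame, y: pd.Series) -> list[str]:
    """Recursive feature elimination under balanced logistic regression.

    Repeatedly refits on the surviving features and removes the one with the
    smallest |coefficient| (ties resolved toward the alphabetically first
    name) until a single feature remains.  Returns the full elimination
    order, first-removed to last-surviving, so the best ``n`` features are
    the last ``n`` entries.
    """
    if X.shape[1] < 2:
        return list(X.columns)
    surviving = sorted(X.columns)
    removed: list[str] = []
    y_arr = np.asarray(y)
    iteration = 0
    while len(surviving) > 1:
        iteration += 1
        clf = _fit_logistic(X[surviving].to_numpy(dtype=float), y_arr)
        if int(np.max(clf.n_iter_)) >= _MAX_ITER:
            raise RuntimeError(f"logistic fit did not converge at RFE iteration {iteration}")
        coefs = np.abs(clf.coef_.ravel())
        worst = int(np.argmin(coefs))  # argmin takes the first (alphabetical) tie
        removed.append(surviving.pop(worst))
    return removed + surviving


def select_n_features(
    X: pd.DataFrame, y: pd.Series, folds: int = 10, seed: int = 0
) -> tuple[int, np.ndarray]:
    """Feature count maximising mean out-of-fold AUC along the RFE path.

    For every fold the RFE path is re-ranked on the fold's training part and
    each candidate ``n`` is scored on the held-out part; ties in the mean
    AUC go to the smallest ``n``.
    """
    y_arr = np.asarray(y)
    k = X.shape[1]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = np.zeros((folds, k))
    for f, (tr, te) in enumerate(skf.split(X, y_arr)):
        y_tr, y_te = y_arr[tr], y_arr[te]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            raise ValueError(
                "a CV fold is missing a class; use fewer folds for this cohort"
            )
        order = rfe_rank(X.iloc[tr], pd.Series(y_tr))
        for n in range(1, k + 1):
            feats = order[-n:]
            clf = _fit_logistic(X.iloc[tr][feats].to_numpy(dtype=float), y_tr)
            probs = clf.predict_proba(X.iloc[te][feats].to_numpy(dtype=float))[:, 1]
            aucs[f, n - 1] = roc_auc_score(y_te, probs)
    mean_auc = aucs.mean(axis=0)
    n_selected = int(np.argmax(mean_auc)) + 1  # argmax takes the smallest n on ties
    return n_selected, mean_auc


def fit_final_model(X: pd.DataFrame, y: pd.Series) -> LogisticModel:
    """Balanced logistic fit on the selected (standardised) features."""
    y_arr = np.asarray(y)
    clf = _fit_logistic(X.to_numpy(dtype=float), y_arr)
    if int(np.max(clf.n_iter_)) >= _MAX_ITER:
        raise RuntimeError("final logistic fit did not converge")
    return LogisticModel(
        selected_features=tuple(X.columns),
        theta=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        class_weights=balanced_class_weights(pd.Series(y_arr)),
    )


def predict_probability(model: LogisticModel, x) -> tuple[float, int]:
    """Evaluate the logistic formula on one standardised feature vector.

    Returns ``(probability, hard_label)``; the label is positive (1) only
    when P strictly exceeds the 0.5 threshold.
    """
    x = pd.Series(dict(x)) if not isinstance(x, pd.Series) else x
    missing = [f for f in model.selected_features if f not in x.index]
    if missing:
        raise KeyError(f"missing feature value(s): {missing}")
    z = model.intercept + float(
        np.dot(model.theta, x[list(model.selected_features)].to_numpy(dtype=float))
    )
    p = float(1.0 / (1.0 + np.exp(-z)))
    return p, int(p > model.decision_threshold)


def _confusion_metrics(probs: np.ndarray, labels: np.ndarray, threshold: float) -> dict:
    pred = probs > threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & ~pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))

    def _ratio(a, b):
        return a / b if b > 0 else np.nan

    return {
        "auc": float(roc_auc_score(labels, probs)),
        "accuracy": (tp + tn) / len(labels),
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
    }


def evaluate(
    probs: np.ndarray,
    labels: np.ndarray,
    n_bootstrap: int = 1000,
    seed: int = 0,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Point metrics plus 95% percentile CIs from stratified bootstrap resampling."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("evaluation needs both classes present")
    point = _confusion_metrics(probs, labels, threshold)

    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    samples = {k: [] for k in point}
    for _ in range(n_bootstrap):
        idx = np.concatenate(
            [
                rng.choice(pos_idx, size=len(pos_idx), replace=True),
                rng.choice(neg_idx, size=len(neg_idx), replace=True),
            ]
        )
        m = _confusion_metrics(probs[idx], labels[idx], threshold)
        for k, v in m.items():
            samples[k].append(v)
    ci = {
        k: tuple(np.nanpercentile(np.asarray(v, dtype=float), [2.5, 97.5]))
        for k, v in samples.items()
    }
    return EvaluationReport(point, ci, n_bootstrap)
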