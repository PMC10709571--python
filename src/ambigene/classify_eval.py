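"""Ensemble-classifier evaluation of gene panels.

Measures the predictive power of a ranked gene panel (difficult genes or
ordinary DEGs) for assigning samples to experimental groups.  The protocol:
repeated stratified k-fold cross-validation (5-fold up to 20 samples,
10-fold above); inside every training fold the candidate panel is re-ranked
on training samples only and the top ``n_predictors`` genes are kept; an
ensemble of four base learners (RBF-kernel SVM, random forest, single-
hidden-layer neural network, CART tree), each refit on ``n_boot`` stratified
bootstrap resamples, predicts by averaging class probabilities.  Reported:
per-repeat misclassification percentage and the mean AUC (pairwise
one-vs-one Hand-Till construction for more than two classes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = ["EnsembleConfig", "ClassifierReport", "predictor_counts",
           "ensemble_cv", "auc_score", "log_cpm"]


def predictor_counts(n_samples: int) -> tuple[int, int, int]:
    """Panel sizes tied to the sample count: floor of n/3, n/2 and 2n/3."""
    if n_samples < 6:
        raise ValueError("need at least 6 samples for the predictor-count rule")
    return (n_samples // 3, n_samples // 2, (2 * n_samples) // 3)


def log_cpm(counts: np.ndarray, effective_sizes: np.ndarray) -> np.ndarray:
    """log2 counts-per-million on effective library sizes, pseudocount 1."""
    eff = np.asarray(effective_sizes, dtype=float)
    return np.log2(np.asarray(counts, dtype=float) / eff * 1e6 + 1.0)


@dataclass
class EnsembleConfig:
    """Hyperparameters of the four base learners and the protocol sizes."""

    n_boot: int = 100
    n_repeats: int = 10
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    rf_trees: int = 500
    nn_hidden: int = 5
    nn_max_iter: int = 500
    tree_max_depth: int | None = None
    fold_boundary: int = 20  # <= this many samples -> 5-fold, else 10-fold

    def folds_for(self, n_samples: int) -> int:
        return 5 if n_samples <= self.fold_boundary else 10


@dataclass
class ClassifierReport:
    """Cross-validated performance of one panel at one panel size."""

    n_predictors: int
    n_folds: int
    misclassification_pct: np.ndarray  # one entry per repeat
    auc_per_repeat: np.ndarray
    mean_auc: float
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "repeat": np.arange(1, len(self.misclassification_pct) + 1),
            "misclassification_pct": self.misclassification_pct,
            "auc": self.auc_per_repeat,
        })


def auc_score(probabilities: np.ndarray, labels, classes=None) -> float:
    """ROC AUC from predicted class probabilities.

    Two classes: standard AUC on the probability of the second (sorted)
    class, ties counted 1/2.  More classes: mean of pairwise one-vs-one
    AUCs.  A single observed class yields NaN.
    """
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    classes = np.asarray(classes)
    if len(np.unique(labels)) < 2:
        return float("nan")
    prob = np.asarray(probabilities, dtype=float)
    if len(classes) == 2:
        return float(roc_auc_score(labels == classes[1], prob[:, 1]))
    return float(roc_auc_score(labels, prob, multi_class="ovo",
                               average="macro", labels=classes))


def _base_learners(cfg: EnsembleConfig, rs: int):
    scaled = lambda est: make_pipeline(StandardScaler(), est)
    return [
        scaled(SVC(C=cfg.svm_c, gamma=cfg.svm_gamma, kernel="rbf",
                   probability=True, random_state=rs)),
        RandomForestClassifier(n_estimators=cfg.rf_trees, random_state=rs),
        scaled(MLPClassifier(hidden_layer_sizes=(cfg.nn_hidden,),
                             max_iter=cfg.nn_max_iter, random_state=rs)),
        DecisionTreeClassifier(max_depth=cfg.tree_max_depth, random_state=rs),
    ]


def _stratified_bootstrap(rng: np.random.Generator, y: np.ndarray) -> np.ndarray:
    """Bootstrap indices resampled within class, so no class disappears."""
    idx = []
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        idx.append(rng.choice(members, size=len(members), replace=True))
    return np.concatenate(idx)


def _rank_candidates(expr_train: np.ndarray, y_train: np.ndarray) -> np.ndarray:
    """Training-only re-ranking of candidate genes by one-way F statistic."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, _ = f_classif(expr_train, y_train)
    f = np.nan_to_num(f, nan=0.0)
    return np.argsort(-f, kind="mergesort")


def ensemble_cv(expr: pd.DataFrame | np.ndarray, labels,
                candidate_genes: list[str], n_predictors: int,
                config: EnsembleConfig | None = None, seed: int = 0,
                label: str = "") -> ClassifierReport:
    """Evaluate a ranked candidate panel with the bootstrap ensemble.

    ``expr`` is genes x samples (a DataFrame indexed by gene id, or an array
    whose rows follow ``candidate_genes``); ``labels`` the group of each
    sample.  Candidates are re-ranked inside every training fold before the
    top ``n_predictors`` are used, so selection never sees test labels.
    Deterministic given ``seed``.
    """
    cfg = config or EnsembleConfig()
    if isinstance(expr, pd.DataFrame):
        missing = [g for g in candidate_genes if g not in expr.index]
        if missing:
            raise KeyError(f"candidate gene(s) not in expression matrix: "
                           f"{missing[:5]}")
        X_all = expr.loc[candidate_genes].to_numpy(dtype=float).T
    else:
        X_all = np.asarray(expr, dtype=float).T
    y = np.asarray([str(v) for v in labels])
    n = len(y)
    if X_all.shape[0] != n:
        raise ValueError("labels do not match expression columns")
    classes = np.unique(y)
    counts = pd.Series(y).value_counts()
    k = cfg.folds_for(n)
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 samples")
    k = min(k, int(counts.min()))
    if n_predictors < 1:
        raise ValueError("n_predictors must be >= 1")
    n_predictors = min(n_predictors, X_all.shape[1])

    ss = np.random.SeedSequence(seed)
    repeat_seeds = ss.spawn(cfg.n_repeats)
    misclass = np.empty(cfg.n_repeats)
    aucs = np.empty(cfg.n_repeats)
    class_index = {c: i for i, c in enumerate(classes)}

    for r, child in enumerate(repeat_seeds):
        rng = np.random.default_rng(child)
        fold_state = int(rng.integers(2**31 - 1))
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=fold_state)
        prob = np.zeros((n, len(classes)))
        for train_idx, test_idx in skf.split(X_all, y):
            y_tr = y[train_idx]
            order = _rank_candidates(X_all[train_idx], y_tr)
            sel = order[:n_predictors]
            X_tr = X_all[np.ix_(train_idx, sel)]
            X_te = X_all[np.ix_(test_idx, sel)]
            acc = np.zeros((len(test_idx), len(classes)))
            n_models = 0
            for b in range(cfg.n_boot):
                boot = _stratified_bootstrap(rng, y_tr)
                rs = int(rng.integers(2**31 - 1))
                for est in _base_learners(cfg, rs):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        est.fit(X_tr[boot], y_tr[boot])
                        p = est.predict_proba(X_te)
                    cols = [class_index[c] for c in
                            np.asarray(est.classes_ if not hasattr(est, "steps")
                                       else est.steps[-1][1].classes_)]
                    acc[:, cols] += p
                    n_models += 1
            prob[test_idx] = acc / n_models
        # argmax over lexicographically sorted classes breaks ties to the
        # first class
        pred = classes[np.argmax(prob, axis=1)]
        misclass[r] = 100.0 * np.mean(pred != y)
        aucs[r] = auc_score(prob, y, classes)

    return ClassifierReport(n_predictors, k, misclass, aucs,
                            float(np.nanmean(aucs)), label=label)
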