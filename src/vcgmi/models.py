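"""Classifier grid, stratified 10-fold CV, and out-of-fold stacking.

Nine classifier families (DT, SVM, KNN, DA, ANN, NB, RF, LR, EM) are
enumerated over fixed hyperparameter grids totalling 210 configurations.
Each configuration is evaluated with stratified 10-fold cross-validation;
features are standardized inside each fold using training-fold statistics
only. Class scores are the probability of the MI (positive) class.

Decision-level fusion stacks the base models: their out-of-fold (OOF)
scores — each sample scored only by models that never saw its fold in
training — form the meta-feature matrix on which a logistic-regression
meta-classifier is trained. The stack itself is evaluated fold-wise on the
same plan, refitting the meta-classifier on the other folds' OOF rows, so
no sample's stacked score ever depends on a model trained on it.

Base learners are standard library-backed estimators; a few variants with
no direct scikit-learn equivalent (diagonal Gaussian discriminants, kernel
Naive Bayes, boosting of discriminant learners via weighted resampling)
are implemented here as small scikit-learn-style estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import partial

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.ensemble import (AdaBoostClassifier, GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FAMILIES",
    "ClassifierConfig",
    "FoldPlan",
    "FoldPredictions",
    "StackModel",
    "enumerate_grid",
    "make_folds",
    "fit_predict_config",
    "build_oof_matrix",
    "fit_stacking",
    "predict_stacking",
    "evaluate_stacking",
    "permutation_importance",
    "select_best_per_family",
    "default_base_configs",
]

FAMILIES = ("DT", "SVM", "KNN", "DA", "ANN", "NB", "RF", "LR", "EM")

POSITIVE_LABEL = "MI"


# ---------------------------------------------------------------------------
# Configuration and fold containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierConfig:
    """One grid entry: a family plus one row of that family's grid."""

    family: str
    params: tuple[tuple[str, object], ...]
    supported: bool = True

    @property
    def param_dict(self) -> dict:
        return dict(self.params)

    @property
    def name(self) -> str:
        inner = ",".join(f"{k}={v}" for k, v in self.params)
        return f"{self.family}({inner})"


@dataclass(frozen=True)
class FoldPlan:
    """A stratified k-fold assignment of samples to folds."""

    fold_of: np.ndarray  # sample index -> fold id
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


@dataclass
class FoldPredictions:
    """Out-of-fold scores of one configuration under a fold plan.

    ``scores[i]`` is the MI probability assigned to sample i by the model
    trained on all folds except sample i's own; ``train_index_sets[f]``
    records exactly which samples trained the fold-f model, making the
    no-leakage guarantee checkable.
    """

    config: ClassifierConfig
    scores: np.ndarray
    labels_pred: np.ndarray
    per_fold_accuracy: np.ndarray
    train_index_sets: list[np.ndarray]
    supported: bool = True

    @property
    def accuracy(self) -> float:
        return float(np.nanmean(self.per_fold_accuracy))


@dataclass
class StackModel:
    """Logistic-regression meta-classifier over base-model scores."""

    base_configs: list[ClassifierConfig]
    coef: np.ndarray       # one weight per base model
    intercept: float

    def __post_init__(self) -> None:
        if len(self.coef) != len(self.base_configs):
            raise ValueError("meta dimension must equal the base-model count")


# ---------------------------------------------------------------------------
# Small estimators for variants absent from scikit-learn
# ---------------------------------------------------------------------------

class DiagonalDiscriminant(ClassifierMixin, BaseEstimator):
    """Gaussian discriminant with diagonal covariance.

    ``pooled=True`` shares one per-feature variance across classes
    (diagonal-linear); ``pooled=False`` uses per-class variances
    (diagonal-quadratic, equivalent to Gaussian Naive Bayes with empirical
    priors).
    """

    def __init__(self, pooled: bool = True):
        self.pooled = pooled

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.means_ = np.array([X[y == c].mean(axis=0) for c in self.classes_])
        self.priors_ = np.array([np.mean(y == c) for c in self.classes_])
        if self.pooled:
            resid = np.concatenate(
                [X[y == c] - m for c, m in zip(self.classes_, self.means_)])
            var = resid.var(axis=0)
            self.vars_ = np.tile(var, (len(self.classes_), 1))
        else:
            self.vars_ = np.array([X[y == c].var(axis=0) for c in self.classes_])
        self.vars_ = np.maximum(self.vars_, 1e-12)
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        jll = []
        for m, v, p in zip(self.means_, self.vars_, self.priors_):
            ll = -0.5 * np.sum(np.log(2 * np.pi * v) + (X - m) ** 2 / v, axis=1)
            jll.append(ll + np.log(p))
        return np.column_stack(jll)

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        p = np.exp(jll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def _kernel_density(u: np.ndarray, kind: str) -> np.ndarray:
    if kind == "normal":
        return np.exp(-0.5 * u ** 2) / np.sqrt(2 * np.pi)
    inside = np.abs(u) <= 1
    if kind == "box":
        return 0.5 * inside
    if kind == "epanechnikov":
        return 0.75 * (1 - u ** 2) * inside
    if kind == "triangle":
        return (1 - np.abs(u)) * inside
    raise ValueError(f"unknown kernel type {kind!r}")


class KernelNaiveBayes(ClassifierMixin, BaseEstimator):
    """Naive Bayes with per-feature kernel density class conditionals.

    Each feature's class-conditional density is a 1D KDE over the training
    values with Silverman's bandwidth; ``kernel`` selects the kernel shape
    (normal, box, epanechnikov, triangle). ``priors=None`` uses empirical
    class frequencies; a sequence fixes them (e.g. uniform).
    """

    def __init__(self, kernel: str = "normal", priors=None):
        self.kernel = kernel
        self.priors = priors

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.train_ = [X[y == c] for c in self.classes_]
        self.bandwidths_ = []
        for Xi in self.train_:
            n = len(Xi)
            sd = Xi.std(axis=0)
            iqr = np.subtract(*np.percentile(Xi, [75, 25], axis=0))
            spread = np.minimum(sd, np.where(iqr > 0, iqr / 1.349, np.inf))
            bw = 0.9 * spread * n ** (-0.2)
            self.bandwidths_.append(np.where(bw > 0, bw, 1e-3))
        if self.priors is None:
            self.priors_ = np.array([np.mean(y == c) for c in self.classes_])
        else:
            self.priors_ = np.asarray(self.priors, dtype=float)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        X = np.asarray(X, dtype=float)
        jll = []
        for Xi, bw, p in zip(self.train_, self.bandwidths_, self.priors_):
            # (n_test, n_train, n_feat) broadcast is fine at cohort scale
            u = (X[:, None, :] - Xi[None, :, :]) / bw
            dens = _kernel_density(u, self.kernel).mean(axis=1) / bw
            jll.append(np.log(np.maximum(dens, 1e-300)).sum(axis=1) + np.log(p))
        jll = np.column_stack(jll)
        jll -= jll.max(axis=1, keepdims=True)
        prob = np.exp(jll)
        return prob / prob.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


class CappedKNeighbors(KNeighborsClassifier):
    """KNN whose neighbor count is capped at the training-set size.

    Keeps large-K grid rows runnable on small cohorts or folds instead of
    erroring out.
    """

    def fit(self, X, y):
        self.n_neighbors = min(self.n_neighbors, len(np.asarray(y)))
        return super().fit(X, y)


class DecisionScoreClassifier(ClassifierMixin, BaseEstimator):
    """Expose margin classifiers through a probability-like interface.

    Wraps an estimator with a ``decision_function`` and maps its margin
    through the logistic function. The mapping is monotone, so rankings
    (and hence ROC/AUC) match the raw margins, and it is fully
    deterministic — no internal calibration folds.
    """

    def __init__(self, estimator=None):
        self.estimator = estimator

    def fit(self, X, y, sample_weight=None):
        est = clone(self.estimator)
        if sample_weight is None:
            est.fit(X, y)
        else:
            est.fit(X, y, sample_weight=sample_weight)
        self.estimator_ = est
        self.classes_ = est.classes_
        return self

    def predict_proba(self, X):
        margin = self.estimator_.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-np.clip(margin, -500, 500)))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return self.estimator_.predict(X)


class ResampleWrapper(ClassifierMixin, BaseEstimator):
    """Adds sample_weight support to any classifier by weighted resampling.

    Boosting needs base learners that accept ``sample_weight``; estimators
    without it (e.g. discriminant analysis) are fitted on a bootstrap
    drawn with probability proportional to the weights instead.
    """

    def __init__(self, estimator=None, random_state: int = 0):
        self.estimator = estimator
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X)
        y = np.asarray(y)
        est = clone(self.estimator)
        if sample_weight is None:
            est.fit(X, y)
        else:
            rng = np.random.default_rng(self.random_state)
            p = np.asarray(sample_weight, dtype=float)
            p = p / p.sum()
            for _ in range(10):
                idx = rng.choice(len(y), size=len(y), p=p)
                if len(np.unique(y[idx])) == len(np.unique(y)):
                    break
            est.fit(X[idx], y[idx])
        self.estimator_ = est
        self.classes_ = est.classes_
        return self

    def predict(self, X):
        return self.estimator_.predict(X)

    def predict_proba(self, X):
        return self.estimator_.predict_proba(X)


class UndersampleBoost(ClassifierMixin, BaseEstimator):
    """Boosting on a class-balanced subset (random-undersampling variant).

    The majority class is randomly undersampled to the minority size once,
    then the wrapped boosting ensemble is fitted on the balanced subset.
    """

    def __init__(self, ensemble=None, random_state: int = 0):
        self.ensemble = ensemble
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        rng = np.random.default_rng(self.random_state)
        classes, counts = np.unique(y, return_counts=True)
        n_min = counts.min()
        keep = np.concatenate([
            rng.choice(np.flatnonzero(y == c), size=n_min, replace=False)
            for c in classes])
        keep.sort()
        est = clone(self.ensemble)
        est.fit(X[keep], y[keep])
        self.estimator_ = est
        self.classes_ = est.classes_
        return self

    def predict(self, X):
        return self.estimator_.predict(X)

    def predict_proba(self, X):
        return self.estimator_.predict_proba(X)


# ---------------------------------------------------------------------------
# Grid enumeration
# ---------------------------------------------------------------------------

# Table 9 pattern: which (prior, regularization, solver) rows are supported.
_LR_SUPPORTED = {
    ("uniform", "lasso", "sgd"), ("uniform", "lasso", "sparsa"),
    ("uniform", "ridge", "sgd"), ("uniform", "ridge", "bfgs"),
    ("uniform", "ridge", "lbfgs"),
    ("empirical", "lasso", "sparsa"), ("empirical", "ridge", "bfgs"),
    ("empirical", "ridge", "lbfgs"),
}


def enumerate_grid() -> list[ClassifierConfig]:
    """Enumerate all 210 grid configurations in stable family/row order.

    Per-family cardinalities: DT 32, SVM 25, KNN 36, DA 6, ANN 20, NB 10,
    RF 25, LR 24 (16 of them flagged unsupported), EM 32.
    """
    grid: list[ClassifierConfig] = []

    for criterion in ("gdi", "cross_entropy"):
        for min_leaf in (2, 4, 8, 16):
            for max_splits in (5, 10, 20, 50):
                grid.append(ClassifierConfig("DT", (
                    ("criterion", criterion), ("min_leaf", min_leaf),
                    ("max_splits", max_splits))))

    for kernel in ("poly2", "poly3", "poly4", "linear", "rbf"):
        for scale in (1, 2, 3, 4, 5):
            grid.append(ClassifierConfig("SVM", (
                ("kernel", kernel), ("scale", scale))))

    for k in (5, 10, 15, 20):
        for dist in ("euclidean", "cityblock", "chebyshev"):
            for weight in ("equal", "inverse", "squared_inverse"):
                grid.append(ClassifierConfig("KNN", (
                    ("k", k), ("distance", dist), ("weight", weight))))

    for kind in ("linear", "diag_linear", "pseudo_linear", "quadratic",
                 "diag_quadratic", "pseudo_quadratic"):
        grid.append(ClassifierConfig("DA", (("discriminant", kind),)))

    for layer1 in (5, 10, 20, 50):
        for layer2 in (5, 10, 20, 50):
            grid.append(ClassifierConfig("ANN", (
                ("hidden_layers", 2), ("layer1", layer1), ("layer2", layer2))))
    for layer1 in (5, 10, 20, 50):
        grid.append(ClassifierConfig("ANN", (
            ("hidden_layers", 1), ("layer1", layer1))))

    for prior in ("uniform", "empirical"):
        grid.append(ClassifierConfig("NB", (
            ("prior", prior), ("distribution", "normal"))))
        for kern in ("normal", "box", "epanechnikov", "triangle"):
            grid.append(ClassifierConfig("NB", (
                ("prior", prior), ("distribution", "kernel"),
                ("kernel_type", kern))))

    for n_trees in (100, 200, 300, 400, 500):
        for min_leaf in (1, 2, 3, 4, 5):
            grid.append(ClassifierConfig("RF", (
                ("n_trees", n_trees), ("min_leaf", min_leaf))))

    for prior in ("uniform", "empirical"):
        for reg in ("lasso", "ridge"):
            for solver in ("sgd", "asgd", "dual", "bfgs", "lbfgs", "sparsa"):
                supported = (prior, reg, solver) in _LR_SUPPORTED
                grid.append(ClassifierConfig("LR", (
                    ("prior", prior), ("regularization", reg),
                    ("solver", solver)), supported=supported))

    em_blocks = [
        ("adaboost", "tree"), ("adaboost", "discriminant"),
        ("robust", "tree"), ("robust", "discriminant"),
        ("rus", "tree"), ("rus", "discriminant"),
        ("logitboost", "tree"), ("gentleboost", "tree"),
    ]
    for method, learner in em_blocks:
        for cycles in (50, 100, 150, 200):
            grid.append(ClassifierConfig("EM", (
                ("method", method), ("learner", learner),
                ("cycles", cycles))))

    return grid


# ---------------------------------------------------------------------------
# Estimator construction
# ---------------------------------------------------------------------------

def _squared_inverse_weights(dist: np.ndarray) -> np.ndarray:
    # zero distances get all the weight, mirroring the 'distance' convention
    with np.errstate(divide="ignore"):
        w = 1.0 / dist ** 2
    inf_rows = np.isinf(w).any(axis=1)
    w[inf_rows] = np.isinf(w[inf_rows]).astype(float)
    return w


def _scale_features(X, factor: float):
    return np.asarray(X) / factor


def build_estimator(config: ClassifierConfig, seed: int = 0) -> BaseEstimator:
    """Instantiate the scikit-learn estimator for a supported grid entry."""
    if not config.supported:
        raise ValueError(f"configuration {config.name} is unsupported")
    p = config.param_dict
    fam = config.family

    if fam == "DT":
        crit = "entropy" if p["criterion"] == "cross_entropy" else "gini"
        return DecisionTreeClassifier(
            criterion=crit, min_samples_leaf=p["min_leaf"],
            max_leaf_nodes=p["max_splits"] + 1, random_state=seed)

    if fam == "SVM":
        kern = p["kernel"]
        if kern.startswith("poly"):
            est = SVC(kernel="poly", degree=int(kern[4:]), coef0=1.0, gamma=1.0)
        elif kern == "linear":
            est = SVC(kernel="linear")
        else:
            est = SVC(kernel="rbf", gamma=1.0)
        est = DecisionScoreClassifier(est)
        # kernel scale divides the feature space before the kernel
        from sklearn.pipeline import Pipeline
        from sklearn.preprocessing import FunctionTransformer
        return Pipeline([
            ("scale", FunctionTransformer(
                partial(_scale_features, factor=float(p["scale"])))),
            ("svc", est)])

    if fam == "KNN":
        weight = {"equal": "uniform", "inverse": "distance",
                  "squared_inverse": _squared_inverse_weights}[p["weight"]]
        metric = {"euclidean": "euclidean", "cityblock": "manhattan",
                  "chebyshev": "chebyshev"}[p["distance"]]
        return CappedKNeighbors(n_neighbors=p["k"], metric=metric,
                                weights=weight)

    if fam == "DA":
        kind = p["discriminant"]
        if kind == "linear":
            return LinearDiscriminantAnalysis(solver="svd")
        if kind == "pseudo_linear":
            return LinearDiscriminantAnalysis(solver="lsqr")
        if kind == "diag_linear":
            return DiagonalDiscriminant(pooled=True)
        if kind == "quadratic":
            return QuadraticDiscriminantAnalysis()
        if kind == "diag_quadratic":
            return DiagonalDiscriminant(pooled=False)
        if kind == "pseudo_quadratic":
            return QuadraticDiscriminantAnalysis(reg_param=1e-3)

    if fam == "ANN":
        layers = (p["layer1"], p["layer2"]) if p["hidden_layers"] == 2 \
            else (p["layer1"],)
        return MLPClassifier(hidden_layer_sizes=layers, max_iter=300,
                             random_state=seed)

    if fam == "NB":
        priors = None if p["prior"] == "empirical" else [0.5, 0.5]
        if p["distribution"] == "normal":
            return GaussianNB(priors=priors)
        return KernelNaiveBayes(kernel=p["kernel_type"], priors=priors)

    if fam == "RF":
        return RandomForestClassifier(
            n_estimators=p["n_trees"], min_samples_leaf=p["min_leaf"],
            random_state=seed)

    if fam == "LR":
        weight = "balanced" if p["prior"] == "uniform" else None
        penalty = "l1" if p["regularization"] == "lasso" else "l2"
        if p["solver"] == "sgd":
            return SGDClassifier(loss="log_loss", penalty=penalty,
                                 class_weight=weight, random_state=seed,
                                 max_iter=2000, tol=1e-4)
        if p["solver"] == "sparsa":
            return LogisticRegression(solver="saga",
                                      l1_ratio=1.0 if penalty == "l1" else 0.0,
                                      class_weight=weight, max_iter=5000,
                                      random_state=seed)
        # bfgs / lbfgs quasi-Newton solvers (ridge only per the grid)
        return LogisticRegression(solver="lbfgs", class_weight=weight,
                                  max_iter=5000, random_state=seed)

    if fam == "EM":
        cycles = p["cycles"]
        stump = DecisionTreeClassifier(max_depth=1, random_state=seed)
        disc = ResampleWrapper(LinearDiscriminantAnalysis(), random_state=seed)
        base = stump if p["learner"] == "tree" else disc
        method = p["method"]
        if method == "adaboost":
            return AdaBoostClassifier(estimator=base, n_estimators=cycles,
                                      random_state=seed)
        if method == "robust":
            # outlier-damped boosting approximated by shrunken AdaBoost
            return AdaBoostClassifier(estimator=base, n_estimators=cycles,
                                      learning_rate=0.5, random_state=seed)
        if method == "rus":
            inner = AdaBoostClassifier(estimator=base, n_estimators=cycles,
                                       random_state=seed)
            return UndersampleBoost(ensemble=inner, random_state=seed)
        if method == "logitboost":
            return GradientBoostingClassifier(
                loss="log_loss", n_estimators=cycles, max_depth=1,
                random_state=seed)
        if method == "gentleboost":
            return GradientBoostingClassifier(
                loss="exponential", n_estimators=cycles, max_depth=1,
                random_state=seed)

    raise ValueError(f"unknown configuration {config!r}")


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def make_folds(labels, k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified k-fold plan; deterministic for a fixed seed."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"every class needs at least k={k} members, got {dict(zip(classes, counts))}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_of[test_idx] = fold
    return FoldPlan(fold_of=fold_of, k=k, seed=seed)


def _as_binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    return (labels == POSITIVE_LABEL).astype(int)


def fit_predict_config(config: ClassifierConfig, features, labels,
                       plan: FoldPlan, seed: int = 0) -> FoldPredictions:
    """Out-of-fold scores of one configuration under a fold plan.

    For each fold the estimator is trained on the other k-1 folds (with
    standardization statistics computed on those folds only) and scores
    the held-out fold. Unsupported configurations return an explicit
    unsupported result with NaN scores rather than raising.
    """
    X = np.asarray(features, dtype=float)
    y = _as_binary(labels)
    n = len(y)
    if not config.supported:
        return FoldPredictions(
            config=config, scores=np.full(n, np.nan),
            labels_pred=np.full(n, -1),
            per_fold_accuracy=np.full(plan.k, np.nan),
            train_index_sets=[plan.train_indices(f) for f in range(plan.k)],
            supported=False)

    scores = np.empty(n)
    train_sets = []
    per_fold_acc = np.empty(plan.k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        for f in range(plan.k):
            tr, te = plan.train_indices(f), plan.test_indices(f)
            scaler = StandardScaler().fit(X[tr])
            est = build_estimator(config, seed=seed)
            est.fit(scaler.transform(X[tr]), y[tr])
            proba = est.predict_proba(scaler.transform(X[te]))
            pos = list(est.classes_).index(1)
            scores[te] = proba[:, pos]
            per_fold_acc[f] = np.mean((scores[te] >= 0.5) == y[te])
            train_sets.append(tr)
    return FoldPredictions(
        config=config, scores=scores,
        labels_pred=(scores >= 0.5).astype(int),
        per_fold_accuracy=per_fold_acc,
        train_index_sets=train_sets)


def build_oof_matrix(configs, features, labels, plan: FoldPlan,
                     seed: int = 0) -> tuple[np.ndarray, list[FoldPredictions]]:
    """Sample x model OOF score matrix for a set of supported configs."""
    preds = []
    for cfg in configs:
        if not cfg.supported:
            raise ValueError(f"cannot stack unsupported config {cfg.name}")
        preds.append(fit_predict_config(cfg, features, labels, plan, seed=seed))
    matrix = np.column_stack([p.scores for p in preds])
    return matrix, preds


# ---------------------------------------------------------------------------
# Stacking
# ---------------------------------------------------------------------------

def _meta_estimator(seed: int) -> LogisticRegression:
    return LogisticRegression(max_iter=5000, random_state=seed)


def fit_stacking(oof_matrix: np.ndarray, labels, base_configs=None,
                 seed: int = 0) -> StackModel:
    """Fit the logistic meta-classifier on OOF base scores."""
    oof_matrix = np.asarray(oof_matrix, dtype=float)
    if oof_matrix.ndim != 2 or oof_matrix.shape[1] < 1:
        raise ValueError("oof_matrix must be (n_samples, n_models>=1)")
    y = _as_binary(labels)
    meta = _meta_estimator(seed).fit(oof_matrix, y)
    if base_configs is None:
        base_configs = [ClassifierConfig("META", (("column", j),))
                        for j in range(oof_matrix.shape[1])]
    return StackModel(base_configs=list(base_configs),
                      coef=meta.coef_.ravel().copy(),
                      intercept=float(meta.intercept_[0]))


def predict_stacking(model: StackModel, base_scores: np.ndarray) -> np.ndarray:
    """Stacked MI probability: logistic combination of base scores."""
    z = np.asarray(base_scores, dtype=float) @ model.coef + model.intercept
    return 1.0 / (1.0 + np.exp(-z))


def evaluate_stacking(oof_matrix: np.ndarray, labels, plan: FoldPlan,
                      base_configs=None, seed: int = 0
                      ) -> tuple[FoldPredictions, StackModel]:
    """Fold-wise evaluation of the stack plus the final meta-model.

    For each fold the meta-classifier is refitted on the other folds' OOF
    rows and scores the held-out fold, so stacked scores inherit the
    out-of-fold guarantee. The returned :class:`StackModel` is fitted on
    all OOF rows.
    """
    oof_matrix = np.asarray(oof_matrix, dtype=float)
    y = _as_binary(labels)
    n = len(y)
    scores = np.empty(n)
    per_fold_acc = np.empty(plan.k)
    train_sets = []
    for f in range(plan.k):
        tr, te = plan.train_indices(f), plan.test_indices(f)
        meta = _meta_estimator(seed).fit(oof_matrix[tr], y[tr])
        scores[te] = meta.predict_proba(oof_matrix[te])[:, 1]
        per_fold_acc[f] = np.mean((scores[te] >= 0.5) == y[te])
        train_sets.append(tr)
    stack_cfg = ClassifierConfig("STACK", (("n_base", oof_matrix.shape[1]),))
    preds = FoldPredictions(
        config=stack_cfg, scores=scores,
        labels_pred=(scores >= 0.5).astype(int),
        per_fold_accuracy=per_fold_acc,
        train_index_sets=train_sets)
    model = fit_stacking(oof_matrix, labels, base_configs, seed=seed)
    return preds, model


# ---------------------------------------------------------------------------
# Feature importance and base-model selection
# ---------------------------------------------------------------------------

def permutation_importance(model_scores_fn, features, labels,
                           n_repeats: int = 10, seed: int = 0) -> np.ndarray:
    """Mean increase in classification error from shuffling each feature.

    ``model_scores_fn(X) -> scores`` maps a feature matrix to MI scores;
    error is measured at the 0.5 threshold. Negative values (shuffling
    helps) are legitimate and indicate redundancy or noise.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X = np.asarray(features, dtype=float)
    y = _as_binary(labels)
    rng = np.random.default_rng(seed)
    baseline = np.mean((np.asarray(model_scores_fn(X)) >= 0.5) != y)
    importances = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        errs = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            errs.append(np.mean((np.asarray(model_scores_fn(Xp)) >= 0.5) != y))
        importances[j] = np.mean(errs) - baseline
    return importances


def select_best_per_family(results: list[FoldPredictions],
                           sensitivities: dict[str, float] | None = None
                           ) -> list[ClassifierConfig]:
    """Best supported configuration of each family by CV accuracy.

    Ties are broken by higher sensitivity when provided (keyed by config
    name), then by grid order. Families are returned in canonical order.
    """
    best: dict[str, tuple[float, float, int, ClassifierConfig]] = {}
    for i, res in enumerate(results):
        if not res.supported:
            continue
        sens = (sensitivities or {}).get(res.config.name, 0.0)
        key = (res.accuracy, sens, -i)
        fam = res.config.family
        if fam not in best or key > best[fam][:3]:
            best[fam] = (*key, res.config)
    return [best[f][3] for f in FAMILIES if f in best]


def default_base_configs() -> list[ClassifierConfig]:
    """The nine reference base configurations for stacking (one per family).

    These are the per-family winners of the reference cohort analysis:
    KNN K=10/cityblock/squared-inverse, SVM poly-3/scale-1, DT
    cross-entropy/4/5, DA linear, ANN 10x20, NB empirical/epanechnikov,
    RF 300/1, LR empirical/lasso/sparsa, EM adaboost/tree/200.
    """
    wanted = {
        "DT": dict(criterion="cross_entropy", min_leaf=4, max_splits=5),
        "SVM": dict(kernel="poly3", scale=1),
        "KNN": dict(k=10, distance="cityblock", weight="squared_inverse"),
        "DA": dict(discriminant="linear"),
        "ANN": dict(hidden_layers=2, layer1=10, layer2=20),
        "NB": dict(prior="empirical", distribution="kernel",
                   kernel_type="epanechnikov"),
        "RF": dict(n_trees=300, min_leaf=1),
        "LR": dict(prior="empirical", regularization="lasso", solver="sparsa"),
        "EM": dict(method="adaboost", learner="tree", cycles=200),
    }
    out = []
    for fam in FAMILIES:
        out.append(ClassifierConfig(fam, tuple(wanted[fam].items())))
    return out
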