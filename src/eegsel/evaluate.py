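"""Classifier families, leave-one-subject-out evaluation and metrics.

Four classifier families are supported, mirroring a common clinical-EEG
benchmarking setup:

* RF  — ensemble of 30 bagged decision trees; the tuned parameter is the
  tree depth (1..35).
* SVM — least-squares SVM (Suykens dual: a single linear system) with fixed
  regularization C = 0.2; the tuned parameter is the kernel (linear,
  polynomial of degree 3, or RBF with median-distance bandwidth).
* DA  — linear or quadratic discriminant analysis.
* KNN — nearest-neighbour vote with k in 1..10 and one of ten distances
  (euclidean, seuclidean, cityblock, chebychev, minkowski, mahalanobis,
  cosine, correlation, spearman, hamming — indexed 1..10 in that order).

Evaluation is leave-one-subject-out (LOSO): one fold per subject, the whole
subject held out, so no subject contributes to both training and testing.
Per-fold accuracy is CA = N_correct / N_total x 100%; the headline CA is the
unweighted mean over folds.  Because each LOSO test fold contains a single
class, sensitivity/specificity/precision/F-score are computed from confusion
counts POOLED over all folds (positive class = MCI = label 1).

Features are z-scored per fold with training-set statistics for the
distance- and margin-based learners (SVM, KNN, DA); trees see raw features.
A segment-level k-fold evaluator is provided for contrast: it splits
segments regardless of subject and therefore leaks within-subject structure,
inflating accuracy relative to LOSO.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix

#: KNN distance names in gene-index order (gene value 1 -> euclidean, ...).
KNN_DISTANCES = ("euclidean", "seuclidean", "cityblock", "chebychev",
                 "minkowski", "mahalanobis", "cosine", "correlation",
                 "spearman", "hamming")
SVM_KERNELS = ("linear", "polynomial", "rbf")
DA_TYPES = ("linear", "quadratic")
RF_N_TREES = 30
RF_MAX_DEPTH = 35
KNN_MAX_K = 10


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its (validated) hyperparameters."""

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        fam = self.family.upper()
        object.__setattr__(self, "family", fam)
        p = dict(self.params)
        if fam == "RF":
            depth = int(p.setdefault("tree_depth", 10))
            if not 1 <= depth <= RF_MAX_DEPTH:
                raise ValueError(f"RF tree_depth must be 1..{RF_MAX_DEPTH}")
        elif fam == "SVM":
            kernel = p.setdefault("kernel", "linear")
            if kernel not in SVM_KERNELS:
                raise ValueError(f"SVM kernel must be one of {SVM_KERNELS}")
            p.setdefault("C", 0.2)
        elif fam == "DA":
            disc = p.setdefault("discriminant", "linear")
            if disc not in DA_TYPES:
                raise ValueError(f"DA discriminant must be one of {DA_TYPES}")
        elif fam == "KNN":
            k = int(p.setdefault("k", 3))
            if not 1 <= k <= KNN_MAX_K:
                raise ValueError(f"KNN k must be 1..{KNN_MAX_K}")
            dist = p.setdefault("distance", "euclidean")
            if dist not in KNN_DISTANCES:
                raise ValueError(f"KNN distance must be one of {KNN_DISTANCES}")
        else:
            raise ValueError(f"unknown classifier family {self.family!r}")
        object.__setattr__(self, "params", p)

    @property
    def needs_scaling(self) -> bool:
        return self.family != "RF"


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled confusion counts; positive class = MCI (label 1)."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class EvaluationResult:
    per_fold_accuracy: "tuple[float, ...]"  # percent, one per held-out subject
    CA: float                               # mean of per-fold accuracies, %
    pooled_accuracy: float                  # pooled over all segments, %
    sensitivity: float
    specificity: float
    precision: float
    f_score: float
    counts: ConfusionCounts
    n_folds: int
    flags: "tuple[str, ...]" = ()


class LSSVMClassifier:
    """Least-squares SVM: equality-constrained SVM solved as one linear system.

    Dual system (y in {-1,+1}, Omega_ij = y_i y_j K(x_i, x_j)):

        [ 0    y^T          ] [b]   [0]
        [ y    Omega + I/C  ] [a] = [1]

    decision f(x) = sign( sum_i a_i y_i K(x, x_i) + b ).  Deterministic.
    """

    def __init__(self, kernel: str = "linear", C: float = 0.2, degree: int = 3,
                 gamma: "float | None" = None):
        if kernel not in SVM_KERNELS:
            raise ValueError(f"kernel must be one of {SVM_KERNELS}")
        self.kernel = kernel
        self.C = C
        self.degree = degree
        self.gamma = gamma  # RBF 1/(2 sigma^2); None -> median-distance heuristic

    def _gram(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        if self.kernel == "linear":
            return A @ B.T
        if self.kernel == "polynomial":
            return (1.0 + A @ B.T) ** self.degree
        sq = (np.sum(A ** 2, 1)[:, None] - 2 * A @ B.T + np.sum(B ** 2, 1)[None, :])
        return np.exp(-self._gamma_ * np.maximum(sq, 0.0))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSSVMClassifier":
        X = np.asarray(X, float)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("LS-SVM is binary; need exactly 2 classes in training data")
        ypm = np.where(np.asarray(y) == self.classes_[1], 1.0, -1.0)
        if self.kernel == "rbf":
            if self.gamma is not None:
                self._gamma_ = self.gamma
            else:
                # median-distance heuristic on a capped subsample for O(n^2) safety
                idx = np.linspace(0, len(X) - 1, min(len(X), 500)).astype(int)
                S = X[idx]
                d2 = (np.sum(S ** 2, 1)[:, None] - 2 * S @ S.T + np.sum(S ** 2, 1)[None, :])
                med = np.sqrt(np.maximum(np.median(d2[np.triu_indices(len(S), 1)]), 0))
                self._gamma_ = 1.0 / (2 * med ** 2) if med > 0 else 1.0
        K = self._gram(X, X)
        n = len(X)
        A = np.zeros((n + 1, n + 1))
        A[0, 1:] = ypm
        A[1:, 0] = ypm
        A[1:, 1:] = (ypm[:, None] * ypm[None, :]) * K + np.eye(n) / self.C
        rhs = np.concatenate([[0.0], np.ones(n)])
        sol = np.linalg.solve(A + 1e-12 * np.eye(n + 1), rhs)
        self.b_, self.alpha_ = sol[0], sol[1:]
        self.X_, self.y_pm_ = X, ypm
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        K = self._gram(np.asarray(X, float), self.X_)
        return K @ (self.alpha_ * self.y_pm_) + self.b_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0,
                        self.classes_[1], self.classes_[0])


class _RankTransformKNN:
    """KNN with Spearman distance: correlation distance on per-row ranks."""

    def __init__(self, k: int):
        self.k = k

    @staticmethod
    def _ranks(X: np.ndarray) -> np.ndarray:
        return np.apply_along_axis(rankdata, 1, X)

    def fit(self, X, y):
        self._knn = KNeighborsClassifier(n_neighbors=self.k, metric="correlation",
                                         algorithm="brute")
        self._knn.fit(self._ranks(np.asarray(X, float)), y)
        return self

    def predict(self, X):
        return self._knn.predict(self._ranks(np.asarray(X, float)))


class _GaussianRidgeQDA:
    """Gaussian quadratic discriminant with trace-scaled covariance ridge.

    Handles the rank-deficient regime (class sample count at or below the
    feature count) that sklearn's QDA refuses: each class covariance gets
    delta*I with delta = 1e-6 * trace/p plus an escalation until positive
    definite.  Deterministic.
    """

    def fit(self, X, y):
        X = np.asarray(X, float)
        self.classes_ = np.unique(y)
        self._params = []
        for c in self.classes_:
            Xc = X[np.asarray(y) == c]
            mu = Xc.mean(axis=0)
            C = np.atleast_2d(np.cov(Xc, rowvar=False)) if len(Xc) > 1 \
                else np.zeros((X.shape[1], X.shape[1]))
            delta = 1e-6 * np.trace(C) / C.shape[0] + 1e-12
            while True:
                try:
                    L = np.linalg.cholesky(C + delta * np.eye(C.shape[0]))
                    break
                except np.linalg.LinAlgError:
                    delta *= 100.0
            logdet = 2.0 * np.log(np.diag(L)).sum()
            prior = len(Xc) / len(X)
            self._params.append((mu, L, logdet, np.log(prior)))
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        scores = np.empty((len(X), len(self.classes_)))
        from scipy.linalg import solve_triangular
        for j, (mu, L, logdet, logprior) in enumerate(self._params):
            w = solve_triangular(L, (X - mu).T, lower=True)
            scores[:, j] = -0.5 * (w ** 2).sum(axis=0) - 0.5 * logdet + logprior
        return self.classes_[np.argmax(scores, axis=1)]


class _RegularizedQDA:
    """sklearn QDA when the class covariances are full rank, with a
    deterministic ridge-QDA fallback otherwise."""

    _LADDER = (1e-6, 1e-3)

    def fit(self, X, y):
        for reg in self._LADDER:
            try:
                self._model = QuadraticDiscriminantAnalysis(reg_param=reg).fit(X, y)
                return self
            except np.linalg.LinAlgError:
                continue
        self._model = _GaussianRidgeQDA().fit(X, y)
        return self

    def predict(self, X):
        return self._model.predict(X)


def _ridge_inv_cov(X: np.ndarray) -> np.ndarray:
    """Inverse covariance with trace-scaled ridge against singularity."""
    C = np.cov(X, rowvar=False)
    C = np.atleast_2d(C)
    delta = 1e-6 * np.trace(C) / C.shape[0] + 1e-12
    return np.linalg.inv(C + delta * np.eye(C.shape[0]))


def build_classifier(spec: ClassifierSpec, seed: int = 0, X_train: "np.ndarray | None" = None):
    """Instantiate the estimator for a spec (some KNN metrics need train stats)."""
    fam = spec.family
    if fam == "RF":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(max_depth=spec.params["tree_depth"],
                                             random_state=seed),
            n_estimators=RF_N_TREES, random_state=seed)
    if fam == "SVM":
        return LSSVMClassifier(kernel=spec.params["kernel"], C=spec.params["C"])
    if fam == "DA":
        if spec.params["discriminant"] == "linear":
            return LinearDiscriminantAnalysis()
        return _RegularizedQDA()
    # KNN
    k, dist = spec.params["k"], spec.params["distance"]
    if dist == "spearman":
        return _RankTransformKNN(k)
    kwargs: dict = {"n_neighbors": k}
    if dist == "euclidean":
        kwargs["metric"] = "euclidean"
    elif dist == "cityblock":
        kwargs["metric"] = "manhattan"
    elif dist == "chebychev":
        kwargs["metric"] = "chebyshev"
    elif dist == "minkowski":
        kwargs.update(metric="minkowski", p=3)
    elif dist == "seuclidean":
        V = np.maximum(np.var(X_train, axis=0, ddof=1), 1e-12)
        kwargs.update(metric="seuclidean", metric_params={"V": V}, algorithm="brute")
    elif dist == "mahalanobis":
        kwargs.update(metric="mahalanobis",
                      metric_params={"VI": _ridge_inv_cov(X_train)}, algorithm="brute")
    elif dist in ("cosine", "correlation", "hamming"):
        kwargs.update(metric=dist, algorithm="brute")
    return KNeighborsClassifier(**kwargs)


def loso_split(fm: FeatureMatrix) -> "list[tuple[np.ndarray, np.ndarray]]":
    """One (train_rows, test_rows) pair per subject, disjoint and exhaustive.

    Subjects are held out in first-appearance order.  A training partition
    containing a single class cannot be fit and raises.
    """
    sids = np.asarray(fm.subject_ids)
    labels = np.asarray(fm.labels)
    subjects = list(dict.fromkeys(fm.subject_ids))
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 distinct subjects")
    folds = []
    for subj in subjects:
        test = np.flatnonzero(sids == subj)
        train = np.flatnonzero(sids != subj)
        if len(np.unique(labels[train])) < 2:
            raise ValueError(
                f"training partition for held-out subject {subj!r} has a single class")
        folds.append((train, test))
    return folds


def _standardize(train_X: np.ndarray, test_X: np.ndarray):
    mu = train_X.mean(axis=0)
    sd = train_X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train_X - mu) / sd, (test_X - mu) / sd


def metrics_from_confusion(c: ConfusionCounts):
    """(sensitivity, specificity, precision, f_score); zero denominators -> 0."""
    flags = []

    def _ratio(num, den, name):
        if den == 0:
            flags.append(f"{name}: zero denominator")
            return 0.0
        return 100.0 * num / den

    sens = _ratio(c.TP, c.TP + c.FN, "sensitivity")
    spec = _ratio(c.TN, c.TN + c.FP, "specificity")
    prec = _ratio(c.TP, c.TP + c.FP, "precision")
    if prec + sens == 0:
        flags.append("f_score: zero denominator")
        f = 0.0
    else:
        f = 2.0 * prec * sens / (prec + sens)
    return sens, spec, prec, f, tuple(flags)


def _evaluate_folds(X: np.ndarray, y: np.ndarray, folds, spec: ClassifierSpec,
                    seed: int) -> EvaluationResult:
    per_fold = []
    tp = tn = fp = fn = 0
    for train, test in folds:
        Xtr, Xte = X[train], X[test]
        if spec.needs_scaling:
            Xtr, Xte = _standardize(Xtr, Xte)
        clf = build_classifier(spec, seed=seed, X_train=Xtr)
        clf.fit(Xtr, y[train])
        pred = np.asarray(clf.predict(Xte))
        truth = y[test]
        per_fold.append(100.0 * float(np.mean(pred == truth)))
        tp += int(np.sum((pred == 1) & (truth == 1)))
        tn += int(np.sum((pred == 0) & (truth == 0)))
        fp += int(np.sum((pred == 1) & (truth == 0)))
        fn += int(np.sum((pred == 0) & (truth == 1)))
    counts = ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)
    sens, specif, prec, f, flags = metrics_from_confusion(counts)
    return EvaluationResult(
        per_fold_accuracy=tuple(per_fold), CA=float(np.mean(per_fold)),
        pooled_accuracy=100.0 * (tp + tn) / counts.total,
        sensitivity=sens, specificity=specif, precision=prec, f_score=f,
        counts=counts, n_folds=len(per_fold), flags=flags)


def loso_evaluate(fm: FeatureMatrix, column_mask: "np.ndarray | None" = None,
                  spec: ClassifierSpec = ClassifierSpec("KNN"),
                  seed: int = 0) -> EvaluationResult:
    """Leave-one-subject-out evaluation of one classifier on masked columns."""
    mask = (np.ones(fm.n_features, bool) if column_mask is None
            else np.asarray(column_mask, bool))
    if mask.shape != (fm.n_features,):
        raise ValueError("column_mask length must equal n_features")
    if not mask.any():
        raise ValueError("column_mask selects no features")
    X = fm.values[:, mask]
    y = np.asarray(fm.labels)
    return _evaluate_folds(X, y, loso_split(fm), spec, seed)


def kfold_evaluate(fm: FeatureMatrix, column_mask: "np.ndarray | None" = None,
                   spec: ClassifierSpec = ClassifierSpec("KNN"),
                   n_splits: int = 10, seed: int = 0) -> EvaluationResult:
    """Segment-level stratified k-fold CV — ignores subject identity.

    Segments from one subject land in both training and test folds, so the
    score is optimistically biased; provided as the contrast to LOSO.
    """
    mask = (np.ones(fm.n_features, bool) if column_mask is None
            else np.asarray(column_mask, bool))
    if not mask.any():
        raise ValueError("column_mask selects no features")
    X = fm.values[:, mask]
    y = np.asarray(fm.labels)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    folds = [(tr, te) for tr, te in skf.split(X, y)]
    return _evaluate_folds(X, y, folds, spec, seed)
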