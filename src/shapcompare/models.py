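"""Classifier families, trial design, hyperparameter search and performance metrics.

Four model families are supported for binary activity prediction on binary
fingerprints: random forests (RFC), a single-hidden-layer feed-forward
network (FFNN), and support vector machines with an RBF (SVM_RBF) or
Tanimoto (SVM_TAN) kernel.  Trials are independent stratified 90/10
shuffle-splits; hyperparameters are selected per trial by grid search with
an inner 10-fold stratified shuffle-split scored by F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedShuffleSplit
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .synthetic import ACTIVE

__all__ = [
    "METHODS",
    "DEFAULT_GRIDS",
    "TrialSplit",
    "ModelSpec",
    "PerformanceReport",
    "TrainedModel",
    "split_trials",
    "tanimoto_kernel",
    "tune_and_train",
    "fit_with_params",
    "evaluate",
]

METHODS = ("RFC", "FFNN", "SVM_RBF", "SVM_TAN")

_SVM_C_GRID = [0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1, 10, 100, 10000]
_SVM_GAMMA_GRID = [0.0001, 0.001, 0.01, 0.1, 1, 10, 100]

#: per-family hyperparameter grids searched in each trial
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "RFC": {
        "min_samples_leaf": [1, 2, 5, 10],
        "min_samples_split": [2, 3, 5, 10],
        "n_estimators": [25, 50, 100, 200, 400],
    },
    "SVM_RBF": {"C": list(_SVM_C_GRID), "gamma": list(_SVM_GAMMA_GRID)},
    "SVM_TAN": {"C": list(_SVM_C_GRID)},
    "FFNN": {"learning_rate_init": [0.01, 0.001, 0.0001]},
}

_DEFAULT_OUTPUT_MODE = {
    "RFC": "proba",
    "FFNN": "proba",
    "SVM_RBF": "decision",
    "SVM_TAN": "decision",
}


@dataclass(frozen=True)
class TrialSplit:
    """One stratified 90/10 train/test partition."""

    trial_index: int
    train_ids: np.ndarray
    test_ids: np.ndarray

    def __post_init__(self) -> None:
        if np.intersect1d(self.train_ids, self.test_ids).size:
            raise ValueError("train and test indices overlap")


@dataclass
class ModelSpec:
    """A model family, its hyperparameter grid and explanation-target scalar.

    ``output_mode`` selects which scalar f(x) the attribution methods
    explain: ``proba`` (probability of the active class), ``decision``
    (signed SVM decision value) or ``logit`` (log-odds of activity).
    Probabilities are the default for RFC and FFNN; the signed decision
    value for the SVMs, whose margin lives on a log-odds-like scale.
    """

    method: str
    grid: dict[str, list] = field(default=None)  # type: ignore[assignment]
    output_mode: str = ""

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.grid is None:
            self.grid = {k: list(v) for k, v in DEFAULT_GRIDS[self.method].items()}
        if not self.output_mode:
            self.output_mode = _DEFAULT_OUTPUT_MODE[self.method]
        if self.output_mode not in ("proba", "decision", "logit"):
            raise ValueError(f"unknown output_mode {self.output_mode!r}")
        for name, values in self.grid.items():
            if name in ("C", "gamma", "n_estimators", "learning_rate_init",
                        "min_samples_leaf", "min_samples_split"):
                if any(v <= 0 for v in values):
                    raise ValueError(f"grid values for {name} must be positive")


def split_trials(
    labels: np.ndarray,
    n_trials: int = 10,
    test_fraction: float = 0.1,
    seed: int = 0,
) -> list[TrialSplit]:
    """Independent stratified shuffle-split trials (test sets may overlap
    across trials; this is not K-fold)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 instances of each class")
    sss = StratifiedShuffleSplit(
        n_splits=n_trials, test_size=test_fraction, random_state=seed
    )
    return [
        TrialSplit(trial_index=i, train_ids=tr, test_ids=te)
        for i, (tr, te) in enumerate(sss.split(np.zeros((len(labels), 1)), labels))
    ]


def tanimoto_kernel(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Tanimoto similarity K[i, j] = c / (a + b - c) between binary rows.

    a and b are the on-bit counts of the two rows and c the shared on-bit
    count. The 0/0 case (two all-zero rows) is defined as 1, the
    self-similarity limit, which keeps the kernel matrix positive
    semi-definite on degenerate inputs.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if not (np.isin(X, (0.0, 1.0)).all() and np.isin(Y, (0.0, 1.0)).all()):
        raise ValueError("tanimoto_kernel requires binary matrices")
    c = X @ Y.T
    a = X.sum(axis=1)[:, None]
    b = Y.sum(axis=1)[None, :]
    denom = a + b - c
    K = np.divide(c, denom, out=np.ones_like(c), where=denom > 0)
    return K


def _make_estimator(method: str, seed: int, **params):
    if method == "RFC":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if method == "SVM_RBF":
        return SVC(kernel="rbf", random_state=seed, **params)
    if method == "SVM_TAN":
        return SVC(kernel=tanimoto_kernel, random_state=seed, **params)
    if method == "FFNN":
        # single 256-unit ReLU hidden layer, Adam, batch 16, <=400 epochs,
        # early stop after 20 epochs without >=1e-4 validation-loss change
        return MLPClassifier(
            hidden_layer_sizes=(256,),
            activation="relu",
            solver="adam",
            batch_size=16,
            max_iter=400,
            early_stopping=True,
            validation_fraction=0.1,
            n_iter_no_change=20,
            tol=1e-4,
            random_state=seed,
            **params,
        )
    raise ValueError(f"unknown method {method!r}")


class TrainedModel:
    """Fitted estimator plus the metadata attribution and ROAR need.

    ``output`` returns the explanation-target scalar f(x) for each row under
    the spec's ``output_mode``; ``predict`` returns hard class labels.
    """

    def __init__(self, estimator, spec: ModelSpec, params: dict, seed: int,
                 train_X: np.ndarray, train_y: np.ndarray, trial_index: int = -1):
        self.estimator = estimator
        self.spec = spec
        self.params = dict(params)
        self.seed = seed
        self.train_X = np.asarray(train_X, dtype=np.float64)
        self.train_y = np.asarray(train_y)
        self.trial_index = trial_index

    @property
    def n_features(self) -> int:
        return self.train_X.shape[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=np.float64))

    def output(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        mode = self.spec.output_mode
        if mode == "decision":
            return np.asarray(self.estimator.decision_function(X), dtype=np.float64)
        proba = self.estimator.predict_proba(X)
        idx = int(np.flatnonzero(self.estimator.classes_ == ACTIVE)[0])
        p = np.asarray(proba[:, idx], dtype=np.float64)
        if mode == "proba":
            return p
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return np.log(p / (1 - p))


def tune_and_train(
    X: np.ndarray,
    y: np.ndarray,
    split: TrialSplit,
    spec: ModelSpec,
    seed: int,
) -> TrainedModel:
    """Grid search on the training split, then refit the winner on all of it.

    The inner loop is a 10-fold stratified 90/10 shuffle-split on the
    training data scored by F1; ties between grid points fall to the
    first-in-grid candidate for reproducibility. Single-point grids skip
    the search entirely.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    Xtr, ytr = X[split.train_ids], y[split.train_ids]
    if len(np.unique(ytr)) < 2:
        raise ValueError("training split is degenerate: a class is missing")

    n_candidates = int(np.prod([len(v) for v in spec.grid.values()])) if spec.grid else 1
    if n_candidates <= 1:
        params = {k: v[0] for k, v in spec.grid.items()}
        est = _make_estimator(spec.method, seed, **params).fit(Xtr, ytr)
        return TrainedModel(est, spec, params, seed, Xtr, ytr, split.trial_index)

    inner = StratifiedShuffleSplit(n_splits=10, test_size=0.1, random_state=seed)
    search = GridSearchCV(
        _make_estimator(spec.method, seed),
        param_grid=spec.grid,
        scoring="f1",
        cv=inner,
        refit=True,
        n_jobs=1,
    )
    search.fit(Xtr, ytr)
    return TrainedModel(
        search.best_estimator_, spec, search.best_params_, seed, Xtr, ytr,
        split.trial_index,
    )


def fit_with_params(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    params: dict,
    seed: int,
    trial_index: int = -1,
) -> TrainedModel:
    """Fit one estimator with fixed hyperparameters (no search); used by
    remove-and-retrain, which reuses the full-width selection."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training data: a class is missing")
    est = _make_estimator(spec.method, seed, **params).fit(X, y)
    return TrainedModel(est, spec, params, seed, X, y, trial_index)


@dataclass(frozen=True)
class PerformanceReport:
    """Confusion counts and the five derived classification metrics.

    precision = TP/(TP+FP); recall = TP/(TP+FN); balanced accuracy is the
    mean of recall and specificity; F1 = 2TP/(2TP+FP+FN); MCC is the
    Matthews correlation coefficient. Undefined ratios (zero denominators)
    are reported as 0.
    """

    TP: int
    FP: int
    TN: int
    FN: int
    precision: float
    recall: float
    balanced_accuracy: float
    f1: float
    mcc: float

    @classmethod
    def from_counts(cls, TP: int, FP: int, TN: int, FN: int) -> "PerformanceReport":
        def ratio(num, den):
            return num / den if den else 0.0

        precision = ratio(TP, TP + FP)
        recall = ratio(TP, TP + FN)
        tnr = ratio(TN, TN + FP)
        ba = 0.5 * (recall + tnr)
        f1 = ratio(2 * TP, 2 * TP + FP + FN)
        denom = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
        mcc = (TP * TN - FP * FN) / np.sqrt(denom) if denom else 0.0
        return cls(TP, FP, TN, FN, precision, recall, ba, f1, float(mcc))

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN,
            "precision": self.precision, "recall": self.recall,
            "balanced_accuracy": self.balanced_accuracy,
            "f1": self.f1, "mcc": self.mcc,
        }


def evaluate(model: TrainedModel, X_test: np.ndarray, y_test: np.ndarray) -> PerformanceReport:
    """Confusion counts and metrics on a held-out split (active = positive)."""
    X_test = np.asarray(X_test, dtype=np.float64)
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(X_test)
    TP = int(np.sum((y_test == ACTIVE) & (pred == ACTIVE)))
    FN = int(np.sum((y_test == ACTIVE) & (pred != ACTIVE)))
    TN = int(np.sum((y_test != ACTIVE) & (pred != ACTIVE)))
    FP = int(np.sum((y_test != ACTIVE) & (pred == ACTIVE)))
    return PerformanceReport.from_counts(TP, FP, TN, FN)
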