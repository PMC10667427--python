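"""The four gesture classifiers and the stratified 80/20 split.

NLR: one-vs-all logistic regression on interaction-expanded features
(original entries plus all pairwise products of distinct entries), argmax
of class probabilities (0.5 threshold in the binary case).  SVM: RBF kernel
by default, linear available.  ANN: multilayer perceptron with logistic
activations, 1-5 equal-width hidden layers, depth selected on a seeded
5-fold validation of the training split.  LDA: one-vs-all linear
discriminants, with a shrinkage fallback noted in the model metadata when
class covariances are degenerate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer, StandardScaler
from sklearn.svm import SVC

from .io_formats import FeatureTable

MODEL_KINDS = ("nlr", "svm", "ann", "lda")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0


def stratified_split_indices(labels: Sequence[str], train_fraction: float,
                             seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-class seeded permutation split; |train| = round(f * n) per class."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 rows")
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        train_idx.extend(idx[:n_train].tolist())
        test_idx.extend(idx[n_train:].tolist())
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def split_dataset(table: FeatureTable,
                  spec: SplitSpec = SplitSpec()) -> tuple[FeatureTable, FeatureTable]:
    tr, te = stratified_split_indices(table.labels, spec.train_fraction, spec.seed)
    return table.subset(tr), table.subset(te)


def expand_interactions(X: np.ndarray, degree: int = 2) -> np.ndarray:
    """Original features plus all pairwise products of distinct features."""
    if degree != 2:
        raise NotImplementedError("only pairwise interaction terms are supported")
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    d = X.shape[1]
    iu, ju = np.triu_indices(d, k=1)
    out = np.concatenate([X, X[:, iu] * X[:, ju]], axis=1)
    return out[0] if single else out


@dataclass(frozen=True)
class ModelSpec:
    kind: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}")


@dataclass
class TrainedModel:
    estimator: Pipeline
    kind: str
    feature_kind: str
    classes: tuple[str, ...]
    seed: int
    meta: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return self.estimator.predict(X)

    def to_metadata(self) -> dict:
        return {"kind": self.kind, "feature_kind": self.feature_kind,
                "classes": list(self.classes), "seed": self.seed,
                "meta": self.meta}


def _select_ann_depth(X: np.ndarray, y: np.ndarray, width: int, seed: int,
                      max_depth: int = 5, max_iter: int = 400) -> int:
    """Pick the hidden-layer count by seeded 5-fold validation accuracy."""
    best_depth, best_score = 1, -np.inf
    smallest = int(np.min(np.unique(y, return_counts=True)[1]))
    n_splits = max(2, min(5, smallest))
    if smallest < 2:
        return 1
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for depth in range(1, max_depth + 1):
        scores = []
        for tr, va in cv.split(X, y):
            clf = MLPClassifier(hidden_layer_sizes=(width,) * depth,
                                activation="logistic", max_iter=max_iter,
                                random_state=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                clf.fit(X[tr], y[tr])
            scores.append(clf.score(X[va], y[va]))
        score = float(np.mean(scores))
        if score > best_score + 1e-12:
            best_depth, best_score = depth, score
    return best_depth


def train(table: FeatureTable, spec: ModelSpec) -> TrainedModel:
    """Fit one classifier on a feature table; deterministic given the seed."""
    if len(table) == 0:
        raise ValueError("empty training table")
    y = np.asarray(table.labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("training requires at least 2 classes")
    X = table.X.astype(float)
    hp = dict(spec.hyperparams)
    meta: dict = {}
    steps: list[tuple[str, object]] = []

    if spec.kind == "nlr":
        steps.append(("interactions", FunctionTransformer(expand_interactions)))
        steps.append(("scale", StandardScaler()))
        steps.append(("ovr_logistic", OneVsRestClassifier(
            LogisticRegression(C=hp.get("C", 1.0), max_iter=hp.get("max_iter", 2000)))))
    elif spec.kind == "svm":
        steps.append(("scale", StandardScaler()))
        steps.append(("svc", SVC(kernel=hp.get("kernel", "rbf"),
                                 C=hp.get("C", 1.0), gamma=hp.get("gamma", "scale"))))
    elif spec.kind == "ann":
        steps.append(("scale", StandardScaler()))
        width = hp.get("width", 20)
        depth = hp.get("hidden_layers")
        if depth is None:
            Xs = StandardScaler().fit_transform(X)
            depth = _select_ann_depth(Xs, y, width, spec.seed,
                                      max_iter=hp.get("max_iter", 400))
        if not 1 <= depth <= 5:
            raise ValueError("ANN hidden-layer count must lie in 1..5")
        meta["hidden_layers"] = depth
        steps.append(("mlp", MLPClassifier(
            hidden_layer_sizes=(width,) * depth, activation="logistic",
            max_iter=hp.get("max_iter", 400), random_state=spec.seed)))
    else:  # lda
        steps.append(("ovr_lda", OneVsRestClassifier(LinearDiscriminantAnalysis())))

    pipe = Pipeline(steps)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            pipe.fit(X, y)
        except np.linalg.LinAlgError:
            if spec.kind != "lda":
                raise
            meta["lda_regularized"] = True
            steps[-1] = ("ovr_lda", OneVsRestClassifier(
                LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")))
            pipe = Pipeline(steps)
            pipe.fit(X, y)
    if spec.kind == "lda" and any("collinear" in str(w.message).lower()
                                  for w in caught):
        meta["lda_collinear_variables"] = True

    classes = tuple(sorted(set(y.tolist())))
    return TrainedModel(estimator=pipe, kind=spec.kind,
                        feature_kind=table.kind, classes=classes,
                        seed=spec.seed, meta=meta)


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)
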