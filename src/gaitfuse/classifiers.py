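"""The five candidate base classifiers and their uniform score interface.

=== ==========================================================
 1  BP neural net: 1 hidden layer, 10 units, tanh activation
 2  KNN, k = 1
 3  SVM, linear kernel
 4  SVM, RBF kernel
 5  SVM, polynomial kernel (degree 3)
=== ==========================================================

Every trained model exposes ``score(x) -> real[m]``: a normalized
per-class support row on the probability simplex, which is what all
decision-fusion rules consume. SVM scores are Platt-calibrated pairwise-
coupled probabilities (the standard libsvm construction); the BP net's
softmax output already lives on the simplex; KNN with k = 1 is one-hot
by construction. Feature standardization is fit inside the model
pipeline, so cross-validation never leaks test-fold statistics into
training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass(frozen=True)
class ClassifierSpec:
    id: int
    family: str
    hyperparameters: Mapping[str, Any] = field(default_factory=dict)


DEFAULT_SPECS: dict[int, ClassifierSpec] = {
    1: ClassifierSpec(1, "BP-net", {"hidden_units": 10, "activation": "tanh", "max_epochs": 500}),
    2: ClassifierSpec(2, "KNN", {"k": 1}),
    3: ClassifierSpec(3, "SVM-linear", {"C": 1.0}),
    4: ClassifierSpec(4, "SVM-RBF", {"C": 1.0, "gamma": "scale"}),
    5: ClassifierSpec(5, "SVM-poly", {"C": 1.0, "degree": 3}),
}


def _build_estimator(spec: ClassifierSpec, seed: int):
    hp = dict(spec.hyperparameters)
    if spec.family == "BP-net":
        return MLPClassifier(
            hidden_layer_sizes=(hp.get("hidden_units", 10),),
            activation="tanh",
            max_iter=hp.get("max_epochs", 500),
            random_state=seed,
        )
    if spec.family == "KNN":
        return KNeighborsClassifier(n_neighbors=hp.get("k", 1))
    if spec.family == "SVM-linear":
        return SVC(kernel="linear", C=hp.get("C", 1.0), probability=True, random_state=seed)
    if spec.family == "SVM-RBF":
        return SVC(
            kernel="rbf",
            C=hp.get("C", 1.0),
            gamma=hp.get("gamma", "scale"),
            probability=True,
            random_state=seed,
        )
    if spec.family == "SVM-poly":
        return SVC(
            kernel="poly",
            C=hp.get("C", 1.0),
            degree=hp.get("degree", 3),
            probability=True,
            random_state=seed,
        )
    raise ValueError(f"unknown classifier family: {spec.family!r}")


@dataclass(frozen=True)
class ScoreMatrix:
    """Per-sample classifier support: ``z[i, j]`` is classifier i's
    normalized score for class j. Rows live on the probability simplex.
    """

    z: np.ndarray  # (n_classifiers, n_classes)
    classifier_ids: tuple[int, ...]
    class_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2:
            raise ValueError("score matrix must be 2-D")
        if z.shape != (len(self.classifier_ids), len(self.class_ids)):
            raise ValueError(
                f"shape {z.shape} inconsistent with "
                f"{len(self.classifier_ids)} classifiers x {len(self.class_ids)} classes"
            )
        if np.any(z < -1e-12) or np.any(z > 1 + 1e-12):
            raise ValueError("scores must lie in [0, 1]")
        if np.any(np.abs(z.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each score row must sum to 1")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "classifier_ids", tuple(self.classifier_ids))
        object.__setattr__(self, "class_ids", tuple(self.class_ids))


@dataclass(frozen=True)
class TrainedModel:
    """A fitted base classifier bound to its spec."""

    spec: ClassifierSpec
    pipeline: Pipeline
    class_ids: tuple[int, ...]
    n_features: int

    def score(self, x) -> np.ndarray:
        """Normalized per-class support for one sample."""
        x = np.asarray(x, dtype=float).reshape(1, -1)
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {x.shape[1]}"
            )
        return self.score_batch(x)[0]

    def score_batch(self, X) -> np.ndarray:
        """Score many samples at once; rows on the simplex."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"expected (n, {self.n_features}) input, got shape {X.shape}"
            )
        proba = self.pipeline.predict_proba(X)
        proba = np.clip(proba, 0.0, None)
        return proba / proba.sum(axis=1, keepdims=True)

    def predict(self, x) -> int:
        """Argmax class; ties break toward the lowest class id."""
        return int(self.class_ids[int(np.argmax(self.score(x)))])

    def predict_batch(self, X) -> np.ndarray:
        scores = self.score_batch(X)
        return np.asarray(self.class_ids)[np.argmax(scores, axis=1)]


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model (pickle) with its spec and metadata.

    Retraining from the recorded seed is the canonical way to reproduce
    a model; this artifact is a convenience for deployment-style use.
    """
    import pickle

    with open(path, "wb") as fh:
        pickle.dump(
            {
                "spec": model.spec,
                "pipeline": model.pipeline,
                "class_ids": model.class_ids,
                "n_features": model.n_features,
            },
            fh,
        )


def load_model(path) -> TrainedModel:
    import pickle

    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    return TrainedModel(**payload)


def train(spec: ClassifierSpec | int, X, y, seed: int = 0) -> TrainedModel:
    """Fit one base classifier (z-score standardization included).

    Deterministic given ``seed``; the seed drives BP-net initialization
    and the internal Platt-calibration folds of the SVMs.
    """
    if isinstance(spec, int):
        spec = DEFAULT_SPECS[spec]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    pipe = make_pipeline(StandardScaler(), _build_estimator(spec, seed))
    with warnings.catch_warnings():
        # SVC(probability=True) is the canonical Platt pairwise-coupling
        # construction; scikit-learn 1.9 flags the parameter for future
        # removal but its behaviour here is exactly what we want
        warnings.filterwarnings("ignore", message=".*probability.*", category=FutureWarning)
        pipe.fit(X, y)
    fitted_classes = tuple(int(c) for c in pipe[-1].classes_)
    return TrainedModel(
        spec=spec, pipeline=pipe, class_ids=fitted_classes, n_features=X.shape[1]
    )
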