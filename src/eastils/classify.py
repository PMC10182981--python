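"""Four-class cell classification (tumor / lymphocyte / stromal / other).

The classifier is a deep feedforward network on per-cell feature vectors:
eight hidden layers, trained for at most 100 iterations, with internal
z-score feature standardisation.  It is exposed as a scikit-learn
compatible estimator (:class:`CellClassifier`) so it composes with sklearn
model selection, plus thin cell-list helpers and the slide-level QC rule
(a slide fails QC when more than 10% of its cells are misclassified
against a reference labelling).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .segmentation import CellObject
from .synthetic import CLASSES

__all__ = ["CellClassifier", "QCReport", "train_classifier", "classify_cells", "qc_slide"]


class CellClassifier(BaseEstimator, ClassifierMixin):
    """Feedforward cell-type classifier with fixed class order.

    Parameters
    ----------
    hidden_width : neurons per hidden layer (depth is fixed at 8).
    max_iter : training iteration cap (default 100).
    random_state : seed for weight initialisation and shuffling.

    Predicted probabilities are reported in the canonical class order
    ``("tumor", "lymphocyte", "stromal", "other")``; exact probability ties
    resolve to the earliest class in that order.
    """

    N_HIDDEN_LAYERS = 8

    def __init__(self, hidden_width: int = 64, max_iter: int = 100, random_state: int = 0):
        self.hidden_width = hidden_width
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y, feature_names: list[str] | None = None) -> "CellClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        present = [c for c in CLASSES if c in set(y)]
        unknown = set(y) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")
        if len(present) < 2:
            raise ValueError("training requires at least two classes")
        self.feature_names_ = list(feature_names) if feature_names is not None else [
            f"f{i}" for i in range(X.shape[1])
        ]
        if len(self.feature_names_) != X.shape[1]:
            raise ValueError("feature_names length must match X columns")
        self.scaler_ = StandardScaler().fit(X)
        self.net_ = MLPClassifier(
            hidden_layer_sizes=(self.hidden_width,) * self.N_HIDDEN_LAYERS,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.net_.fit(self.scaler_.transform(X), y)
        self.classes_ = np.array([c for c in CLASSES if c in self.net_.classes_])
        self.training_accuracy_ = float(self.net_.score(self.scaler_.transform(X), y))
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Probabilities in canonical class order (columns follow ``classes_``)."""
        check_is_fitted(self, "net_")
        raw = self.net_.predict_proba(self.scaler_.transform(np.asarray(X, dtype=float)))
        order = [list(self.net_.classes_).index(c) for c in self.classes_]
        return raw[:, order]

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]  # argmax tie -> earliest class

    # -- portable serialization (JSON weights + schema) ---------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "net_")
        return {
            "hidden_width": self.hidden_width,
            "max_iter": self.max_iter,
            "random_state": self.random_state,
            "feature_names": self.feature_names_,
            "classes": self.classes_.tolist(),
            "net_classes": self.net_.classes_.tolist(),
            "scaler_mean": self.scaler_.mean_.tolist(),
            "scaler_scale": self.scaler_.scale_.tolist(),
            "coefs": [w.tolist() for w in self.net_.coefs_],
            "intercepts": [b.tolist() for b in self.net_.intercepts_],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "CellClassifier":
        model = cls(d["hidden_width"], d["max_iter"], d["random_state"])
        model.feature_names_ = list(d["feature_names"])
        model.classes_ = np.array(d["classes"])
        scaler = StandardScaler()
        scaler.mean_ = np.array(d["scaler_mean"])
        scaler.scale_ = np.array(d["scaler_scale"])
        scaler.var_ = scaler.scale_**2
        scaler.n_features_in_ = scaler.mean_.size
        model.scaler_ = scaler
        net = MLPClassifier(hidden_layer_sizes=(model.hidden_width,) * cls.N_HIDDEN_LAYERS)
        net.coefs_ = [np.array(w) for w in d["coefs"]]
        net.intercepts_ = [np.array(b) for b in d["intercepts"]]
        net.classes_ = np.array(d["net_classes"])
        net.n_layers_ = len(net.coefs_) + 1
        net.n_outputs_ = net.coefs_[-1].shape[1]
        net.out_activation_ = "softmax" if net.n_outputs_ > 1 else "logistic"
        net.activation = "relu"
        net.n_features_in_ = net.coefs_[0].shape[0]
        from sklearn.preprocessing import LabelBinarizer

        net._label_binarizer = LabelBinarizer().fit(net.classes_)
        model.net_ = net
        model.training_accuracy_ = float("nan")
        return model

    @classmethod
    def load(cls, path) -> "CellClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class QCReport:
    """Slide-level classification quality control."""

    n_cells: int
    n_misclassified: int
    fraction: float
    passed: bool  # True iff the misclassified fraction is <= 0.10


def _feature_matrix(cells: list[CellObject], feature_names: list[str]) -> np.ndarray:
    rows = []
    for c in cells:
        if c.features is None:
            raise ValueError("cells lack features; run compute_features/smooth_features first")
        missing = [k for k in feature_names if k not in c.features]
        if missing:
            raise ValueError(f"feature schema mismatch; missing {missing[:3]}...")
        rows.append([c.features[k] for k in feature_names])
    return np.asarray(rows, dtype=float)


def train_classifier(
    labeled_cells: list[CellObject],
    labels: list[str],
    hidden_width: int = 64,
    max_iter: int = 100,
    random_state: int = 0,
) -> CellClassifier:
    """Train a :class:`CellClassifier` from featurised cells and reference labels."""
    if len(labeled_cells) != len(labels):
        raise ValueError("one label per cell required")
    feature_names = sorted(labeled_cells[0].features)
    X = _feature_matrix(labeled_cells, feature_names)
    model = CellClassifier(hidden_width, max_iter, random_state)
    model.fit(X, np.asarray(labels), feature_names=feature_names)
    return model


def classify_cells(model: CellClassifier, cells: list[CellObject]) -> list[CellObject]:
    """Assign a class label and probabilities to every cell (in place)."""
    if not cells:
        return cells
    X = _feature_matrix(cells, model.feature_names_)
    proba = model.predict_proba(X)
    labels = model.classes_[np.argmax(proba, axis=1)]
    for cell, lab, p in zip(cells, labels, proba):
        cell.class_label = str(lab)
        cell.class_probabilities = {c: float(v) for c, v in zip(model.classes_, p)}
    return cells


def qc_slide(predicted: list[str], reference: list[str]) -> QCReport:
    """Compare predicted against reference labels; fail if > 10% disagree."""
    if len(predicted) != len(reference):
        raise ValueError("predicted and reference must cover the same cells")
    if len(predicted) == 0:
        raise ValueError("QC undefined for an empty cell set")
    n_bad = sum(p != r for p, r in zip(predicted, reference))
    frac = n_bad / len(predicted)
    return QCReport(len(predicted), n_bad, frac, passed=frac <= 0.10)
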