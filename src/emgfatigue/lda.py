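"""Two-class Fisher linear discriminant for the fatigue feature stream.

Implemented directly (pooled within-class covariance solve) rather than via
a library classifier so that the fitted direction can be checked against a
brute-force generalized-eigenvalue oracle in the tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .fuzzy import FATIGUE, NON_FATIGUE, TRANSITION, LabelSeries

__all__ = ["LDAModel", "fit_lda", "classify", "classify_series",
           "accuracy_over_time", "save_model", "load_model"]


@dataclass(frozen=True)
class LDAModel:
    """Linear decision rule y = w.x + w0.

    ``class_order`` is (negative class, positive class); y > 0 (and the
    y == 0 boundary, safety-first) maps to the positive class.
    """

    weights: np.ndarray
    bias: float
    class_order: tuple = (NON_FATIGUE, TRANSITION)
    training_summary: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float).ravel()
        if not np.all(np.isfinite(w)) or not np.isfinite(self.bias):
            raise ValueError("model weights/bias must be finite")
        object.__setattr__(self, "weights", w)

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]


def fit_lda(features, labels, class_order=(NON_FATIGUE, TRANSITION)) -> LDAModel:
    """Fit the discriminant maximizing between/within class variance ratio.

    ``features`` is (n, d); ``labels`` a matching sequence of class names.
    Rows labelled Fatigue (or carrying NaN) are dropped: the discriminant
    only separates the two pre-fatigue states. w solves
    pooled_cov @ w = mean(pos) - mean(neg); the bias places the boundary at
    the midpoint of the projected class means (equal priors). A singular
    pooled covariance falls back to a ridge-regularized solve whose epsilon
    is recorded in the training summary.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=object).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels must align")
    keep = np.isfinite(X).all(axis=1) & np.isin(y, class_order)
    X, y = X[keep], y[keep]

    neg, pos = class_order
    X0, X1 = X[y == neg], X[y == pos]
    for name, Xc in ((neg, X0), (pos, X1)):
        if Xc.shape[0] < 2:
            raise ValueError(f"need >= 2 windows of class {name!r} to fit")

    m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
    scatter = (X0 - m0).T @ (X0 - m0) + (X1 - m1).T @ (X1 - m1)
    sw = scatter / (X0.shape[0] + X1.shape[0] - 2)

    epsilon = 0.0
    diff = m1 - m0
    try:
        w = np.linalg.solve(sw, diff)
        if not np.all(np.isfinite(w)) or np.linalg.cond(sw) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        epsilon = 1e-6 * max(np.trace(sw) / sw.shape[0], 1e-12)
        w = np.linalg.solve(sw + epsilon * np.eye(sw.shape[0]), diff)
    w0 = float(-0.5 * w @ (m0 + m1))

    summary = {
        "n_per_class": {neg: int(X0.shape[0]), pos: int(X1.shape[0])},
        "class_means": {neg: m0.tolist(), pos: m1.tolist()},
        "pooled_covariance": sw.tolist(),
        "ridge_epsilon": epsilon,
    }
    return LDAModel(w, w0, class_order, summary)


def classify(model: LDAModel, x):
    """Score one feature vector: returns (label, y)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != model.n_features:
        raise ValueError(
            f"feature dimension {x.shape[0]} != model dimension {model.n_features}"
        )
    y = float(model.weights @ x + model.bias)
    label = model.class_order[1] if y >= 0 else model.class_order[0]
    return label, y


def classify_series(model: LDAModel, features, times) -> tuple:
    """Classify a whole feature matrix; NaN rows fall back to the negative
    class (no evidence of transition). Returns (LabelSeries, scores)."""
    X = np.asarray(features, dtype=float)
    labels, scores = [], np.full(X.shape[0], np.nan)
    for k in range(X.shape[0]):
        if np.isfinite(X[k]).all():
            lab, yk = classify(model, X[k])
            scores[k] = yk
        else:
            lab = model.class_order[0]
        labels.append(lab)
    series = LabelSeries(np.asarray(times, dtype=float),
                         np.array(labels, dtype=object), source="classifier")
    return series, scores


def accuracy_over_time(predicted: LabelSeries, truth: LabelSeries,
                       exclude=(FATIGUE,)):
    """Cumulative percent-correct curve of predictions against truth.

    Truth windows in ``exclude`` (Fatigue by default, which the two-class
    discriminant never emits) are skipped. Returns (times, curve) over the
    scored windows.
    """
    if len(predicted) != len(truth) or not np.allclose(predicted.times, truth.times):
        raise ValueError("predicted and truth series are misaligned")
    mask = ~np.isin(truth.labels, list(exclude))
    if not mask.any():
        raise ValueError("no scorable windows after exclusion")
    correct = (predicted.labels[mask] == truth.labels[mask]).astype(float)
    curve = 100.0 * np.cumsum(correct) / np.arange(1, correct.size + 1)
    return predicted.times[mask], curve


def save_model(model: LDAModel, path) -> None:
    """Serialize to a human-readable JSON file."""
    payload = {
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "class_order": list(model.class_order),
        "training_summary": model.training_summary,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_model(path) -> LDAModel:
    with open(path) as fh:
        payload = json.load(fh)
    return LDAModel(
        np.asarray(payload["weights"], dtype=float),
        float(payload["bias"]),
        tuple(payload["class_order"]),
        payload.get("training_summary", {}),
    )
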