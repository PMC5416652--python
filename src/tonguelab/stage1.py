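"""First-stage SVM: deep red versus red/light-red.

A soft-margin SVM (max-margin hyperplane ``min 1/2 ||w||^2`` subject to
``y_i (w.x_i - b) >= 1``) is fitted on the identifier features.  Labels
are +1 for red/light-red and -1 for deep red.  Features are z-score
standardised before fitting (Lab channels have unequal ranges); the
scaler is learned on the training set only and frozen inside the model.

The number of support vectors — training points with nonzero dual
coefficient — is first-class output here: the identifier features exist
precisely to shrink it relative to raw-pixel training, which is what
makes prediction fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .labels import Stage1Label

__all__ = [
    "LABEL_RED_OR_LIGHT_RED",
    "LABEL_DEEP_RED",
    "KERNELS",
    "TrainingSet",
    "SVMModel",
    "EvaluationResult",
    "train_stage1",
    "predict_stage1",
    "count_support_vectors",
    "accuracy",
]

LABEL_RED_OR_LIGHT_RED = +1
LABEL_DEEP_RED = -1

#: kernel name -> SVC kwargs.  "quadratic" is a degree-2 polynomial
#: kernel; "polynomial" defaults to degree 3.  Both use the
#: inhomogeneous form (u.v + 1)^d, the usual convention for these
#: kernels (the homogeneous d=2 form is blind to sign).
KERNELS = {
    "linear": dict(kernel="linear"),
    "rbf": dict(kernel="rbf"),
    "polynomial": dict(kernel="poly", degree=3, coef0=1.0),
    "quadratic": dict(kernel="poly", degree=2, coef0=1.0),
}


@dataclass(frozen=True)
class TrainingSet:
    """Feature matrix with binary labels (+1 red/light-red, -1 deep red)."""

    X: np.ndarray
    y: np.ndarray
    image_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")
        if self.image_ids and len(self.image_ids) != len(self.y):
            raise ValueError("image_ids length differs from y")


@dataclass
class SVMModel:
    kernel: str
    C: float
    seed: int
    pipeline: Pipeline
    support_vector_count: int
    n_features: int


def train_stage1(
    ts: TrainingSet,
    kernel: str = "linear",
    C: float = 1.0,
    seed: int = 0,
    standardize: bool = True,
) -> SVMModel:
    """Fit the first-stage soft-margin SVM on standardised features.

    ``standardize=False`` drops the z-scoring step and fits the
    max-margin problem on the raw features (useful when features are
    already on a common scale).  Raises on single-class input or
    non-finite features; deterministic for a fixed seed.
    """
    if kernel not in KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; choose from {sorted(KERNELS)}")
    X = np.asarray(ts.X, dtype=np.float64)
    y = np.asarray(ts.y)
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain NaN or infinite values")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the training set")

    steps = [("scale", StandardScaler())] if standardize else []
    steps.append(("svc", SVC(C=C, random_state=seed, **KERNELS[kernel])))
    pipe = Pipeline(steps)
    pipe.fit(X, y)
    sv = int(pipe.named_steps["svc"].n_support_.sum())
    return SVMModel(
        kernel=kernel,
        C=C,
        seed=seed,
        pipeline=pipe,
        support_vector_count=sv,
        n_features=X.shape[1],
    )


def predict_stage1(m: SVMModel, features: np.ndarray) -> Stage1Label | list[Stage1Label]:
    """Map the decision-function sign to the two coarse classes.

    Accepts a single feature vector or a 2-D batch; returns one label
    or a list accordingly.
    """
    X = np.asarray(features, dtype=np.float64)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != m.n_features:
        raise ValueError(
            f"feature length {X.shape[1]} != training length {m.n_features}"
        )
    raw = m.pipeline.predict(X)
    labels = [
        Stage1Label.RED_OR_LIGHT_RED if v == LABEL_RED_OR_LIGHT_RED
        else Stage1Label.DEEP_RED
        for v in raw
    ]
    return labels[0] if single else labels


def count_support_vectors(m: SVMModel) -> int:
    """Training points with nonzero dual coefficient in the fitted model."""
    svc = m.pipeline.named_steps["svc"]
    if not hasattr(svc, "n_support_"):
        raise ValueError("model is not fitted")
    return int(svc.n_support_.sum())


@dataclass(frozen=True)
class EvaluationResult:
    """Per-class correct counts and the percentage accuracy rate.

    ``accuracy_pct = 100 * (sum of per-class correct counts) / N`` —
    for the binary stage this is 100 * (n_red/light-red correct +
    n_deep-red correct) / N.  ``confusion`` is a square DataFrame,
    rows = truth, columns = prediction.
    """

    n_correct: dict
    N: int
    accuracy_pct: float
    confusion: pd.DataFrame
    support_vector_count: int | None = None


def accuracy(preds, truth, support_vector_count: int | None = None) -> EvaluationResult:
    """Successful-classification rate with confusion counts.

    Works for any label alphabet (the binary stage-1 labels or the
    three final colours); labels are compared by string value.
    """
    preds = [str(p) for p in preds]
    truth = [str(t) for t in truth]
    if len(preds) != len(truth):
        raise ValueError("prediction and truth lengths differ")
    if len(truth) == 0:
        raise ValueError("cannot score an empty evaluation set")

    classes = sorted(set(truth) | set(preds))
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for p, t in zip(preds, truth):
        conf.loc[t, p] += 1
    n_correct = {c: int(conf.loc[c, c]) for c in sorted(set(truth))}
    total_correct = sum(n_correct.values())
    return EvaluationResult(
        n_correct=n_correct,
        N=len(truth),
        accuracy_pct=100.0 * total_correct / len(truth),
        confusion=conf,
        support_vector_count=support_vector_count,
    )


def save_model(m: SVMModel, path: str | Path) -> None:
    """Serialise a fitted model (joblib container with a version tag)."""
    import joblib

    joblib.dump({"format_version": 1, "model": m}, path)


def load_model(path: str | Path) -> SVMModel:
    import joblib

    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ValueError("unrecognised model file version")
    return payload["model"]
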