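"""Binary SVM wrapper with the fixed kernel configuration used throughout.

The classifier is a degree-4 polynomial-kernel SVM with error/margin
trade-off C = 1.  The kernel is pinned to (x.x' + 1)^4 — i.e. gamma = 1 and
coef0 = 1 — because polynomial-kernel constants differ across libraries and
only the degree and C are part of the method's definition.  There is no
hyperparameter search; changing degree or C is configuration, not fitting.

Every trained model carries a feature-layout fingerprint (window, combo, and
vector length) and refuses to score vectors produced under a different
layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import joblib
import numpy as np
from sklearn.svm import SVC

SERIALIZATION_VERSION = 1


@dataclass(frozen=True)
class SvmSpec:
    """Kernel settings; the defaults are the method's reference configuration."""

    degree: int = 4
    C: float = 1.0
    coef0: float = 1.0
    gamma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.C <= 0:
            raise ValueError("trade-off C must be positive")


class LayoutMismatchError(ValueError):
    """A model was asked to score vectors from a different feature layout."""


class DegenerateTrainingSetError(ValueError):
    """Training data contained a single class."""


def make_layout(window, combo, n_dims: int | None = None) -> str:
    """Canonical fingerprint string for a (window, combo) encoding layout."""
    dims = 4 * window.length + len(combo) if n_dims is None else n_dims
    return f"window={window}|combo={combo}|dims={dims}"


@dataclass
class TrainedModel:
    """Fitted SVM plus the metadata needed to refuse mismatched inputs."""

    svc: SVC
    spec: SvmSpec
    layout: str
    n_pos: int
    n_neg: int

    def _check(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x dims)")
        dims = int(self.layout.rsplit("dims=", 1)[1])
        if X.shape[1] != dims:
            raise LayoutMismatchError(
                f"model layout {self.layout!r} but input has {X.shape[1]} dims"
            )
        return X


def train(
    X: np.ndarray,
    y: np.ndarray,
    spec: SvmSpec = SvmSpec(),
    layout: str | None = None,
) -> TrainedModel:
    """Fit the SVM on labels in {+1, -1}; deterministic given inputs."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and aligned with y")
    classes = set(np.unique(y).tolist())
    if classes != {-1, 1}:
        raise DegenerateTrainingSetError(
            f"degenerate training set: classes present {sorted(classes)}"
        )
    svc = SVC(
        kernel="poly",
        degree=spec.degree,
        C=spec.C,
        coef0=spec.coef0,
        gamma=spec.gamma,
        random_state=spec.seed,
        cache_size=200,
    )
    svc.fit(X, y)
    return TrainedModel(
        svc=svc,
        spec=spec,
        layout=layout if layout is not None else f"dims={X.shape[1]}",
        n_pos=int((y == 1).sum()),
        n_neg=int((y == -1).sum()),
    )


def decision_values(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Signed distances to the separating surface; larger favours class +1."""
    X = model._check(X)
    return model.svc.decision_function(X)


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Hard labels: sign of the decision value, with 0 mapped to -1."""
    scores = decision_values(model, X)
    return np.where(scores > 0, 1, -1)


def save_model(model: TrainedModel, path) -> None:
    joblib.dump(
        {
            "version": SERIALIZATION_VERSION,
            "svc": model.svc,
            "spec": model.spec,
            "layout": model.layout,
            "n_pos": model.n_pos,
            "n_neg": model.n_neg,
        },
        path,
    )


def load_model(path) -> TrainedModel:
    blob: dict[str, Any] = joblib.load(path)
    if blob.get("version") != SERIALIZATION_VERSION:
        raise ValueError(f"unsupported model file version {blob.get('version')!r}")
    return TrainedModel(
        svc=blob["svc"],
        spec=blob["spec"],
        layout=blob["layout"],
        n_pos=blob["n_pos"],
        n_neg=blob["n_neg"],
    )
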