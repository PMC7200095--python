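"""Classifier back-ends, probability thresholding and burst-level majority voting.

Three back-ends are supported on identical feature tables:

* ``svm`` — support vector machine with a radial (RBF) kernel and
  pairwise-coupling probability estimates;
* ``rf`` — random forest with 500 trees; probabilities are tree-vote
  fractions;
* ``ann`` — feed-forward neural network (input, one hidden rectifier layer,
  softmax output — a three-layer network counting input and output).

Window probabilities are turned into a window class by a strict rejection
threshold tau (default 0.7 for the ANN: a window whose best class probability
does not exceed tau is assigned the rejection class "other", absorbing
behaviours absent from training and mixed-behaviour windows). A burst's class
is the absolute majority (> 50 %) over its window classes; without an
absolute majority the burst is rejected as "other" too.

Feature standardization (z-score, fit on the training split only) is applied
for the svm and ann back-ends; the forest is scale-invariant and gets raw
features.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .burst_io import AccBurst, OTHER_LABEL, RunLog
from .errors import DegenerateTrainingError, ProbabilityError, VoteError
from .windowing import WindowPlan, slide
from .features import feature_matrix

BACKENDS = ("svm", "rf", "ann")


def apply_threshold(probs, classes: Sequence[str], tau: float | None = 0.7,
                    other: str = OTHER_LABEL) -> str:
    """Thresholded class assignment for one probability vector.

    Returns the argmax class if its probability strictly exceeds ``tau``,
    else ``other``. ``tau=None`` disables rejection.
    """
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1 or p.size != len(classes):
        raise ProbabilityError(f"probability vector has wrong shape {p.shape}")
    if (p < -1e-9).any() or abs(p.sum() - 1.0) > 1e-6:
        raise ProbabilityError("probabilities must be non-negative and sum to 1")
    i = int(np.argmax(p))
    if tau is not None and not p[i] > tau:
        return other
    return str(classes[i])


def burst_vote(window_classes: Sequence[str], other: str = OTHER_LABEL) -> str:
    """Absolute-majority vote over a burst's window classes.

    All window classifications count equally (including "other"). The burst
    receives the class held by strictly more than half of its windows; with
    no absolute majority the burst is rejected as ``other``.
    """
    if len(window_classes) == 0:
        raise VoteError("no window classes to vote over")
    winner, count = Counter(window_classes).most_common(1)[0]
    if count * 2 > len(window_classes):
        return str(winner)
    return other


@dataclass
class PredictionRecord:
    """Per-burst prediction: window probabilities, window classes, vote."""

    burst_id: str
    burst_start: pd.Timestamp
    window_probs: np.ndarray  # (windows, classes)
    window_classes: list[str]
    burst_class: str
    vote_fraction: float
    animal_id: str = ""
    label: str | None = None  # ground truth when known


class WindowClassifier(ClassifierMixin, BaseEstimator):
    """Sklearn-style classifier over window feature tables with rejection.

    Parameters
    ----------
    kind : {"ann", "svm", "rf"}
        Back-end family.
    tau : float, None or "auto"
        Rejection threshold on the maximum class probability (strict).
        "auto" resolves to 0.7 for the ann back-end and to None (no
        rejection) for svm/rf.
    hidden_units : int
        Minimum hidden-layer width of the ann; the effective width is
        ``max(hidden_units, 2 * n_classes)``.
    max_iter : int
        Training epoch budget of the ann (ignored by svm/rf).
    n_estimators : int
        Trees in the forest (default 500).
    C, gamma : float / str
        Radial-kernel SVM hyperparameters.
    class_weight : dict, "balanced" or None
        Optional reweighting; the default (None) preserves the natural class
        imbalance of the training data.
    random_state : int
        Seed controlling every stochastic element of training.
    """

    def __init__(self, kind: str = "ann", tau: float | str | None = "auto",
                 hidden_units: int = 64, max_iter: int = 200,
                 n_estimators: int = 500, C: float = 1.0, gamma="scale",
                 class_weight=None, random_state: int = 0):
        self.kind = kind
        self.tau = tau
        self.hidden_units = hidden_units
        self.max_iter = max_iter
        self.n_estimators = n_estimators
        self.C = C
        self.gamma = gamma
        self.class_weight = class_weight
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------
    def _make_backend(self, n_classes: int):
        if self.kind == "svm":
            return SVC(kernel="rbf", C=self.C, gamma=self.gamma,
                       probability=True, class_weight=self.class_weight,
                       random_state=self.random_state)
        if self.kind == "rf":
            return RandomForestClassifier(
                n_estimators=self.n_estimators, class_weight=self.class_weight,
                random_state=self.random_state)
        if self.kind == "ann":
            width = max(self.hidden_units, 2 * n_classes)
            return MLPClassifier(hidden_layer_sizes=(width,),
                                 activation="relu", solver="adam",
                                 max_iter=self.max_iter,
                                 random_state=self.random_state)
        raise ValueError(f"unknown back-end {self.kind!r}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        classes = np.unique(y)
        if classes.size < 2:
            raise DegenerateTrainingError(
                f"training data has {classes.size} class(es); need >= 2")
        self.scaler_ = None
        if self.kind in ("svm", "ann"):
            self.scaler_ = StandardScaler().fit(X)
            X = self.scaler_.transform(X)
        self.backend_ = self._make_backend(classes.size).fit(X, y)
        self.classes_ = self.backend_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    # -- prediction --------------------------------------------------------
    @property
    def tau_(self) -> float | None:
        if self.tau == "auto":
            return 0.7 if self.kind == "ann" else None
        return self.tau

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "backend_")
        X = np.asarray(X, dtype=float)
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        return self.backend_.predict_proba(X)

    def predict(self, X) -> np.ndarray:
        """Thresholded window classes (may contain the rejection class)."""
        probs = self.predict_proba(X)
        tau = self.tau_
        idx = probs.argmax(axis=1)
        out = self.classes_[idx].astype(object)
        if tau is not None:
            out[probs.max(axis=1) <= tau] = OTHER_LABEL
        return np.asarray(out)


def train(features, labels, kind: str = "ann", seed: int = 0,
          **hyper) -> WindowClassifier:
    """Fit a :class:`WindowClassifier` on an (X, y) feature table."""
    return WindowClassifier(kind=kind, random_state=seed, **hyper).fit(
        np.asarray(features, dtype=float), labels)


def predict_bursts(
    model: WindowClassifier,
    bursts: Sequence[AccBurst],
    plan: WindowPlan,
    tau: float | str | None = "model",
    log: RunLog | None = None,
) -> list[PredictionRecord]:
    """slide -> featurize -> window probabilities -> threshold -> vote.

    Bursts shorter than the window are skipped with a logged reason. With
    ``tau="model"`` the classifier's own resolved threshold is used.
    """
    log = log if log is not None else RunLog()
    tau_val = model.tau_ if tau == "model" else tau

    usable, stacks, counts = [], [], []
    for b in bursts:
        if b.n < plan.window_size:
            log.log("burst_skipped", burst_id=b.burst_id,
                    reason="shorter than window", n=b.n,
                    window_size=plan.window_size)
            continue
        w, _ = slide(b, plan)
        usable.append(b)
        stacks.append(w)
        counts.append(w.shape[0])
    if not usable:
        return []

    X = feature_matrix(np.concatenate(stacks, axis=0))
    probs = model.predict_proba(X)
    classes = model.classes_

    records = []
    pos = 0
    for b, k in zip(usable, counts):
        p = probs[pos:pos + k]
        pos += k
        wc = [apply_threshold(row, classes, tau_val) for row in p]
        burst_class = burst_vote(wc)
        frac = wc.count(burst_class) / len(wc)
        records.append(PredictionRecord(
            burst_id=b.burst_id, burst_start=b.burst_start, window_probs=p,
            window_classes=wc, burst_class=burst_class, vote_fraction=frac,
            animal_id=b.animal_id, label=b.label))
    return records


class BurstClassifier(BaseEstimator):
    """End-to-end burst-level estimator: window expansion + back-end + vote.

    ``fit`` takes a sequence of labelled bursts; ``predict`` returns one
    behaviour (or "other") per burst via thresholded window classification
    and absolute-majority voting. Composes with sklearn's ``clone`` /
    ``get_params`` machinery.
    """

    def __init__(self, kind: str = "ann", window_size: int = 79, step: int = 1,
                 tau: float | str | None = "auto", hidden_units: int = 64,
                 max_iter: int = 200, n_estimators: int = 500,
                 class_weight=None, random_state: int = 0):
        self.kind = kind
        self.window_size = window_size
        self.step = step
        self.tau = tau
        self.hidden_units = hidden_units
        self.max_iter = max_iter
        self.n_estimators = n_estimators
        self.class_weight = class_weight
        self.random_state = random_state

    def _plan(self) -> WindowPlan:
        return WindowPlan(self.window_size, self.step)

    def fit(self, bursts: Sequence[AccBurst], y=None):
        from .windowing import expand, split_features

        table = expand(list(bursts), self._plan())
        if table["label"].isna().any():
            raise DegenerateTrainingError("all training bursts must be labelled")
        X, labels = split_features(table)
        self.window_clf_ = WindowClassifier(
            kind=self.kind, tau=self.tau, hidden_units=self.hidden_units,
            max_iter=self.max_iter, n_estimators=self.n_estimators,
            class_weight=self.class_weight,
            random_state=self.random_state).fit(X, labels)
        self.classes_ = self.window_clf_.classes_
        return self

    def predict_records(self, bursts, log: RunLog | None = None):
        check_is_fitted(self, "window_clf_")
        return predict_bursts(self.window_clf_, list(bursts), self._plan(),
                              log=log)

    def predict(self, bursts) -> np.ndarray:
        return np.array([r.burst_class for r in self.predict_records(bursts)],
                        dtype=object)
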