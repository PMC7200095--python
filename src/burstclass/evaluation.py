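"""Confusion-matrix metrics, Cohen's kappa and window-size selection.

Metrics are one-vs-rest per behaviour class: recall = TP/(TP+FN),
precision = TP/(TP+FP), accuracy = (TP+TN)/n. Accuracy is computed for
completeness but deliberately excluded from the window-selection score — with
heavily imbalanced classes the dominant class inflates everyone's true
negatives.

Cohen's kappa is (po - pe)/(1 - pe) with po the observed agreement
(trace/n). The default chance term pe is the standard multiclass marginal
product sum_c (row_c/n)(col_c/n); an alternative that builds the first factor
from TP+TN instead of the truth marginal is available as
``chance="printed"`` (the two coincide only in special cases; the standard
form is the one equivalent to the classical two-rater definition).

Window-size selection: sweep window sizes, score each by
mean(mean recall, mean precision, 1 - proportion "other"), smooth the score
curve with a penalized cubic spline (basis dimension 40, smoothing parameter
by generalized cross-validation), take successive difference-quotient slopes
of the fit, and choose the smallest window whose fitted score is within
tolerance of the fitted maximum and whose slope is near zero — the smallest
window wins ties because smaller windows yield more augmented samples.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .burst_io import OTHER_LABEL, AccBurst
from .errors import FitError, UndefinedKappaError
from .models import WindowClassifier
from .windowing import WindowPlan, expand, split_features, stratified_split


# ---------------------------------------------------------------------------
# confusion matrix and per-class metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Truth x predicted count matrix.

    The prediction axis may carry an extra rejection ("other") column that
    has no corresponding truth row.
    """

    truth_classes: tuple[str, ...]
    pred_classes: tuple[str, ...]
    counts: np.ndarray  # (len(truth_classes), len(pred_classes))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.truth_classes),
                            columns=list(self.pred_classes))

    @classmethod
    def from_labels(cls, truth, predicted, classes: Sequence[str] | None = None,
                    other: str = OTHER_LABEL) -> "ConfusionMatrix":
        truth = np.asarray(truth, dtype=object)
        predicted = np.asarray(predicted, dtype=object)
        if truth.shape != predicted.shape:
            raise ValueError("truth and predicted have different lengths")
        if classes is None:
            named = sorted(set(truth) | (set(predicted) - {other}))
        else:
            named = list(classes)
        pred_classes = named + ([other] if other in set(predicted) else [])
        t_index = {c: i for i, c in enumerate(named)}
        p_index = {c: i for i, c in enumerate(pred_classes)}
        counts = np.zeros((len(named), len(pred_classes)), dtype=int)
        for t, p in zip(truth, predicted):
            counts[t_index[t], p_index[p]] += 1
        return cls(tuple(named), tuple(pred_classes), counts)


confusion = ConfusionMatrix.from_labels


@dataclass
class PerformanceReport:
    """Per-class recall/precision/accuracy plus kappa and rejection rate."""

    recall: dict[str, float]
    precision: dict[str, float]
    accuracy: dict[str, float]
    kappa: float
    other_proportion: float
    undefined: set[str] = field(default_factory=set)  # "<metric>:<class>" flags

    @property
    def mean_recall(self) -> float:
        return float(np.mean(list(self.recall.values())))

    @property
    def mean_precision(self) -> float:
        return float(np.mean(list(self.precision.values())))


def per_class_metrics(cm: ConfusionMatrix) -> tuple[dict, dict, dict, set]:
    """One-vs-rest recall/precision/accuracy; undefined ratios map to 0."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    recall, precision, accuracy, undefined = {}, {}, {}, set()
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    p_index = {c: j for j, c in enumerate(cm.pred_classes)}
    for i, c in enumerate(cm.truth_classes):
        j = p_index.get(c)
        tp = int(cm.counts[i, j]) if j is not None else 0
        fn = int(row[i]) - tp
        fp = (int(col[j]) - tp) if j is not None else 0
        tn = n - tp - fn - fp
        if tp + fn > 0:
            recall[c] = tp / (tp + fn)
        else:
            recall[c] = 0.0
            undefined.add(f"recall:{c}")
        if tp + fp > 0:
            precision[c] = tp / (tp + fp)
        else:
            precision[c] = 0.0
            undefined.add(f"precision:{c}")
        accuracy[c] = (tp + tn) / n
    return recall, precision, accuracy, undefined


def cohens_kappa(cm: ConfusionMatrix, chance: str = "standard") -> float:
    """Chance-corrected agreement (po - pe)/(1 - pe) from a count matrix."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    p_index = {c: j for j, c in enumerate(cm.pred_classes)}
    po = 0.0
    pe = 0.0
    for i, c in enumerate(cm.truth_classes):
        j = p_index.get(c)
        tp = int(cm.counts[i, j]) if j is not None else 0
        po += tp / n
        col_c = int(col[j]) if j is not None else 0
        if chance == "standard":
            pe += (int(row[i]) / n) * (col_c / n)
        elif chance == "printed":
            fn = int(row[i]) - tp
            fp = col_c - tp
            tn = n - tp - fn - fp
            pe += ((tp + tn) / n) * ((tp + fp) / n)
        else:
            raise ValueError(f"unknown chance variant {chance!r}")
    if pe >= 1.0:
        raise UndefinedKappaError("expected agreement is 1; kappa undefined")
    return (po - pe) / (1.0 - pe)


def performance_report(truth, predicted, classes: Sequence[str] | None = None,
                       chance: str = "standard") -> PerformanceReport:
    """Full report (metrics + kappa + rejection proportion) from labels."""
    cm = ConfusionMatrix.from_labels(truth, predicted, classes=classes)
    recall, precision, accuracy, undefined = per_class_metrics(cm)
    kappa = cohens_kappa(cm, chance=chance)
    pred = np.asarray(predicted, dtype=object)
    other_prop = float(np.mean(pred == OTHER_LABEL))
    return PerformanceReport(recall=recall, precision=precision,
                             accuracy=accuracy, kappa=kappa,
                             other_proportion=other_prop, undefined=undefined)


def selection_score(report: PerformanceReport) -> float:
    """mean(mean recall, mean precision, 1 - proportion other), in [0, 1]."""
    return float(np.mean([report.mean_recall, report.mean_precision,
                          1.0 - report.other_proportion]))


# ---------------------------------------------------------------------------
# window-size sweep and penalized-spline selection
# ---------------------------------------------------------------------------

@dataclass
class WindowSizeCurve:
    """Raw and smoothed selection scores over candidate window sizes."""

    sizes: np.ndarray
    raw_scores: np.ndarray
    fitted: np.ndarray | None = None
    slopes: np.ndarray | None = None  # defined from the second size onward
    chosen: int | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"size": self.sizes, "raw": self.raw_scores}
        if self.fitted is not None:
            d["fitted"] = self.fitted
            d["slope"] = np.concatenate([[np.nan], self.slopes])
        return pd.DataFrame(d)


def sweep_window_sizes(
    bursts: Sequence[AccBurst],
    sizes: Sequence[int] = range(20, 111),
    train_frac: float = 0.7,
    seed: int = 0,
    clf: WindowClassifier | None = None,
) -> WindowSizeCurve:
    """Train and score a classifier at each candidate window size.

    The burst-level stratified split is made once (same seed) and reused for
    every size; windowing happens after the split. Scoring is at window level
    (each window one item), with the classifier's own rejection threshold.
    """
    template = clf if clf is not None else WindowClassifier(
        kind="ann", random_state=seed)
    train_b, test_b = stratified_split(list(bursts), train_frac, seed)
    raw = []
    for w in sizes:
        plan = WindowPlan(int(w))
        Xtr, ytr = split_features(expand(train_b, plan))
        Xte, yte = split_features(expand(test_b, plan))
        model = WindowClassifier(**template.get_params()).fit(Xtr, ytr)
        pred = model.predict(Xte)
        raw.append(selection_score(performance_report(yte, pred)))
    return WindowSizeCurve(np.asarray(list(sizes), dtype=int),
                           np.asarray(raw, dtype=float))


def _pspline_gcv(x: np.ndarray, y: np.ndarray, basis_dim: int = 40,
                 degree: int = 3) -> np.ndarray:
    """Penalized cubic B-spline fit with GCV-selected smoothing parameter.

    P-spline construction: B-spline basis with ``basis_dim`` coefficients
    (equally spaced interior knots), second-order difference penalty on the
    coefficients; the smoothing parameter minimizes the GCV score
    n * RSS / (n - edf)^2 over a wide log-spaced grid.
    """
    n = len(x)
    df = int(min(basis_dim, n))
    df = max(df, degree + 1)
    x0, x1 = float(x.min()), float(x.max())
    if x1 <= x0:
        raise FitError("degenerate size range")
    n_interior = df - (degree + 1)
    interior = np.linspace(x0, x1, n_interior + 2)[1:-1]
    knots = np.r_[[x0] * (degree + 1), interior, [x1] * (degree + 1)]
    B = BSpline.design_matrix(x, knots, degree).toarray()
    D = np.diff(np.eye(df), n=2, axis=0)
    P = D.T @ D
    BtB = B.T @ B
    Bty = B.T @ y
    best = None
    for lam in np.logspace(-8, 6, 57):
        A = BtB + lam * P + 1e-12 * np.eye(df)
        try:
            coef = np.linalg.solve(A, Bty)
            H_diag_sum = np.trace(np.linalg.solve(A, BtB))
        except np.linalg.LinAlgError:
            continue
        fit = B @ coef
        rss = float(np.sum((y - fit) ** 2))
        edf = float(H_diag_sum)
        denom = max(n - edf, 1e-8)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, fit)
    if best is None:
        raise FitError("spline fit failed")
    return best[1]


def smooth_and_select(curve: WindowSizeCurve, basis_dim: int = 40,
                      slope_tol: float = 1e-3) -> int:
    """Smooth the score curve, compute slopes, pick the window size.

    Candidates are sizes whose fitted score is within ``slope_tol * range``
    of the fitted maximum *and* whose difference-quotient slope has magnitude
    at most ``slope_tol``; the smallest candidate is chosen. If no size
    qualifies (e.g. a strictly rising curve), the size of the fitted maximum
    is chosen (smallest on ties). Fills ``curve.fitted``, ``curve.slopes``
    and ``curve.chosen`` in place and returns the chosen size.
    """
    if len(curve.sizes) < 4:
        raise FitError("need at least 4 points to fit the smoother")
    x = np.asarray(curve.sizes, dtype=float)
    y = np.asarray(curve.raw_scores, dtype=float)
    fitted = _pspline_gcv(x, y, basis_dim=basis_dim)
    slopes = np.diff(fitted) / np.diff(x)
    slope_at = np.concatenate([[slopes[0]], slopes])

    fmax = fitted.max()
    frange = fmax - fitted.min()
    near_max = fitted >= fmax - slope_tol * frange
    flat = np.abs(slope_at) <= slope_tol
    candidates = np.flatnonzero(near_max & flat)
    if candidates.size:
        idx = int(candidates[0])
    else:
        idx = int(np.argmax(fitted))
    curve.fitted = fitted
    curve.slopes = slopes
    curve.chosen = int(curve.sizes[idx])
    return curve.chosen
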