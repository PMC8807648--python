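"""θ-sweep evaluation: ROC curves, AUC, confusion matrices, model comparison.

Sensitivity and specificity are defined on the binary cancer-vs-healthy
step: at threshold θ a sample is called cancerous when its score reaches θ,
so raising θ trades sensitivity for specificity. AUC is the trapezoidal
area under the (1-specificity, sensitivity) curve, equal to the probability
that a random cancer score exceeds a random healthy score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_auc_score

from .constants import CLASSES
from .fusion_model import CANCER, HEALTHY


@dataclass
class RocCurve:
    """(θ, sensitivity, specificity) triples on a uniform θ grid, plus AUC."""

    thetas: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta": self.thetas,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )

    def accuracy(self) -> np.ndarray:
        n = self.n_pos + self.n_neg
        return (self.sensitivity * self.n_pos + self.specificity * self.n_neg) / n


def _binary_truth(labels: Sequence, positive: str) -> np.ndarray:
    y = np.asarray(labels)
    return y == positive


def sweep_theta(
    scores: Sequence[float],
    labels: Sequence,
    grid_step: float = 0.01,
    score_range: tuple[float, float] = (0.0, 2.0),
    positive: str = CANCER,
) -> RocCurve:
    """Sensitivity/specificity at every θ on the grid, with trapezoidal AUC.

    ``labels`` may be cancer/healthy or any labelling where ``positive``
    marks the positive class.
    """
    scores = np.asarray(scores, dtype=float)
    lo, hi = score_range
    if scores.size and (scores.min() < lo - 1e-9 or scores.max() > hi + 1e-9):
        raise ValueError(f"scores outside the declared range [{lo}, {hi}]")
    pos = _binary_truth(labels, positive)
    if pos.size != scores.size:
        raise ValueError("scores and labels differ in length")
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    thetas = np.round(np.arange(lo, hi + grid_step / 2, grid_step), 10)
    called = scores[None, :] >= thetas[:, None]
    sens = called[:, pos].mean(axis=1)
    spec = (~called)[:, ~pos].mean(axis=1)
    auc = float(roc_auc_score(pos.astype(int), scores))
    return RocCurve(thetas, sens, spec, auc, n_pos, n_neg)


def best_theta(
    roc: RocCurve, tie: str = "mid", smooth_window: int = 3, se_mult: float = 1.0
) -> float:
    """The accuracy-maximizing θ on the curve's grid.

    The empirical accuracy curve has a flat, noisy maximum, so the raw
    argmax is unstable. Two standard stabilizers are applied: a short
    moving average (``smooth_window`` grid points, 1 disables) and the
    one-standard-error rule — every θ whose accuracy lies within
    ``se_mult`` binomial standard errors of the maximum counts as a
    maximizer (0 disables). ``tie='mid'`` returns the midpoint of that
    plateau snapped to the grid (the natural estimator of the accuracy
    optimum on a calibrated score); ``tie='upper'`` returns its largest
    member (the screening choice: maximal specificity at no material
    accuracy cost).
    """
    acc = roc.accuracy()
    if smooth_window > 1:
        pad = smooth_window // 2
        padded = np.concatenate([np.full(pad, acc[0]), acc, np.full(pad, acc[-1])])
        acc = np.convolve(padded, np.full(smooth_window, 1.0 / smooth_window), mode="valid")
    best = acc.max()
    margin = 0.0
    if se_mult > 0:
        margin = se_mult * float(np.sqrt(best * (1.0 - best) / (roc.n_pos + roc.n_neg)))
    idx = np.flatnonzero(acc >= best - margin - 1e-12)
    if tie == "upper":
        return float(roc.thetas[idx[-1]])
    if tie == "mid":
        two_mid = idx[0] + idx[-1]
        if two_mid % 2 == 0:
            return float(roc.thetas[two_mid // 2])
        # plateau centre falls between two grid points: round toward the
        # shoulder that falls off more slowly (its edge is nearer the true
        # optimum); on equal shoulders take the lower point
        lo_out = acc[idx[0] - 1] if idx[0] > 0 else -np.inf
        hi_out = acc[idx[-1] + 1] if idx[-1] + 1 < acc.size else -np.inf
        mid = two_mid // 2 + (1 if hi_out > lo_out else 0)
        return float(roc.thetas[mid])
    raise ValueError(f"unknown tie rule {tie!r}")


def auc_pairwise(scores: Sequence[float], labels: Sequence, positive: str = CANCER) -> float:
    """AUC by exhaustive pairwise comparison (ties count half)."""
    scores = np.asarray(scores, dtype=float)
    pos = _binary_truth(labels, positive)
    s_pos, s_neg = scores[pos], scores[~pos]
    wins = (s_pos[:, None] > s_neg[None, :]).sum() + 0.5 * (s_pos[:, None] == s_neg[None, :]).sum()
    return float(wins / (s_pos.size * s_neg.size))


# ---------------------------------------------------------------------------
# confusion


def confusion(
    preds: Sequence, labels: Sequence, classes: Sequence[str] = CLASSES
) -> pd.DataFrame:
    """7x7 count matrix, rows = truth, columns = prediction."""
    preds = np.asarray(preds)
    labels = np.asarray(labels)
    if preds.size != labels.size:
        raise ValueError("prediction and label sequences differ in length")
    unknown = (set(preds) | set(labels)) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the class set: {sorted(unknown)}")
    counts = _sk_confusion(labels, preds, labels=list(classes))
    return pd.DataFrame(counts, index=list(classes), columns=list(classes))


def overall_accuracy(cm: pd.DataFrame) -> float:
    total = cm.to_numpy().sum()
    return float(np.trace(cm.to_numpy()) / total) if total else float("nan")


def per_class_accuracy(cm: pd.DataFrame) -> pd.Series:
    counts = cm.to_numpy()
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.where(totals > 0, np.diag(counts) / totals, np.nan)
    return pd.Series(acc, index=cm.index, name="accuracy")


# ---------------------------------------------------------------------------
# comparison report


def sensitivity_at_specificity(roc: RocCurve, target: float = 0.9) -> float:
    """Sensitivity at the smallest θ whose specificity reaches the target."""
    ok = np.flatnonzero(roc.specificity >= target)
    if ok.size == 0:
        return float("nan")
    return float(roc.sensitivity[ok[0]])


def compare_models(
    rocs: Mapping[str, RocCurve],
    specificity_target: float = 0.9,
) -> pd.DataFrame:
    """Tabulate AUC, matched-specificity sensitivity and deployment θ*.

    θ* is the accuracy-maximizing threshold with ties resolved toward the
    larger θ (favouring specificity in a screening setting). Rows are sorted
    by AUC, best first.
    """
    rows = []
    for name, roc in rocs.items():
        rows.append(
            {
                "model": name,
                "auc": roc.auc,
                f"sens_at_spec_{specificity_target:g}": sensitivity_at_specificity(
                    roc, specificity_target
                ),
                "best_theta": best_theta(roc, tie="upper"),
                "max_accuracy": float(roc.accuracy().max()),
            }
        )
    frame = pd.DataFrame(rows).sort_values("auc", ascending=False, kind="stable")
    return frame.reset_index(drop=True)
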