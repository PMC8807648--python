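"""SVM-RFE feature ranking and per-cancer discriminative-feature reports.

Recursive feature elimination with a linear max-margin classifier: fit on
the surviving features, rank them by squared weight, drop the smallest,
repeat until every feature is ranked. The per-cancer report runs
cancer-vs-healthy RFE per matrix, keeps the top-k m/z bins and attaches
two-sided rank-sum p-values plus the distribution summaries used for violin
plots; a z-scored class-mean matrix feeds heatmap rendering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ranksums
from sklearn.svm import SVC

from .constants import CANCER_CLASSES


@dataclass
class RankedFeatures:
    """Feature indices from most important (eliminated last) to least."""

    ranking: list[int]
    step: int = 1

    def __post_init__(self) -> None:
        if sorted(self.ranking) != list(range(len(self.ranking))):
            raise ValueError("ranking must be a permutation of 0..p-1")

    def top(self, k: int) -> list[int]:
        return self.ranking[:k]


def _standardize(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    Xs = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return Xs


def _encode_labels(y: Sequence) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    return (y == classes[1]).astype(int)


def _rfe_order(
    Xs: np.ndarray,
    y01: np.ndarray,
    C: float,
    schedule: Callable[[int], int],
) -> list[int]:
    """Elimination loop; returns indices ordered most- to least-important.

    Ties in the squared-weight criterion eliminate the lower feature index
    first, so the whole procedure is deterministic.
    """
    remaining = list(range(Xs.shape[1]))
    eliminated: list[int] = []
    while remaining:
        if len(remaining) == 1:
            eliminated.append(remaining.pop())
            break
        # tight tolerance so near-tied weight criteria reflect the optimum,
        # not solver slack
        svc = SVC(kernel="linear", C=C, tol=1e-8)
        svc.fit(Xs[:, remaining], y01)
        crit = np.ravel(svc.coef_) ** 2
        k = max(1, min(schedule(len(remaining)), len(remaining)))
        # ascending criterion, lower original index first on ties
        order = sorted(range(len(remaining)), key=lambda j: (crit[j], remaining[j]))
        for j in sorted(order[:k], key=lambda j: (crit[j], remaining[j])):
            eliminated.append(remaining[j])
        drop = {remaining[j] for j in order[:k]}
        remaining = [f for f in remaining if f not in drop]
    return eliminated[::-1]


def svm_rfe(X: np.ndarray, y: Sequence, step: int = 1, C: float = 1.0) -> RankedFeatures:
    """Rank all features by recursive elimination of the smallest |w|^2.

    Features are standardized (train mean/sd) before each margin fit; the
    elimination ``step`` removes that many features per iteration.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a 2-D samples x features array with p >= 1")
    y01 = _encode_labels(y)
    if np.bincount(y01, minlength=2).min() < 2:
        raise ValueError("need at least 2 samples per class")
    if X.shape[1] == 1:
        return RankedFeatures([0], step=step)
    ranking = _rfe_order(_standardize(X), y01, C, lambda _: step)
    return RankedFeatures(ranking, step=step)


def svm_rfe_adaptive(
    X: np.ndarray, y: Sequence, C: float = 1.0, exact_below: int = 100, fraction: float = 0.2
) -> RankedFeatures:
    """RFE with a geometric coarse phase for wide matrices.

    While more than ``exact_below`` features survive, a ``fraction`` of them
    is dropped per iteration (ordered by the same criterion); below that the
    loop reverts to single-feature elimination. Within-batch order still
    follows the squared-weight criterion, so rankings deep enough for top-k
    selection match the exact loop in practice at a fraction of the fits.
    """
    X = np.asarray(X, dtype=float)
    y01 = _encode_labels(y)

    def schedule(p: int) -> int:
        return max(1, int(p * fraction)) if p > exact_below else 1

    ranking = _rfe_order(_standardize(X), y01, C, schedule)
    return RankedFeatures(ranking, step=1)


def select_top(ranked: RankedFeatures, k: int) -> list[int]:
    if k > len(ranked.ranking):
        raise ValueError(f"k={k} exceeds feature count {len(ranked.ranking)}")
    return ranked.top(k)


# ---------------------------------------------------------------------------
# per-cancer reports


def discriminative_stats(
    features: Mapping[str, pd.DataFrame],
    labels: pd.Series | Sequence,
    k: int = 10,
    C: float = 1.0,
    healthy_label: str = "HC",
) -> pd.DataFrame:
    """Top-k discriminative m/z bins per (cancer, matrix) vs healthy control.

    For each cancer class and each matrix, ranks features by cancer-vs-HC
    SVM-RFE, keeps the top ``k`` and reports per-feature two-sided rank-sum
    p-values, effect direction, and median/quartile summaries of both groups
    (the numbers a violin plot renders). Rows: class x matrix x rank.
    """
    rows = []
    for matrix_tag, X in features.items():
        y = pd.Series(np.asarray(labels), index=X.index) if not isinstance(labels, pd.Series) else labels
        y = y.reindex(X.index)
        hc_mask = (y == healthy_label).to_numpy()
        if hc_mask.sum() < 2:
            raise ValueError("healthy controls missing or too few")
        for cancer in CANCER_CLASSES:
            mask = (y == cancer).to_numpy()
            if mask.sum() < 2:
                warnings.warn(f"class {cancer} absent/too small; row skipped", stacklevel=2)
                continue
            sub = X.to_numpy(dtype=float)[mask | hc_mask]
            sub_y = np.where(mask[mask | hc_mask], cancer, healthy_label)
            ranked = svm_rfe_adaptive(sub, sub_y, C=C)
            cancer_X = X.to_numpy(dtype=float)[mask]
            hc_X = X.to_numpy(dtype=float)[hc_mask]
            for rank, j in enumerate(ranked.top(k)):
                a, b = cancer_X[:, j], hc_X[:, j]
                stat, p = ranksums(a, b)
                rows.append(
                    {
                        "class_label": cancer,
                        "matrix_tag": matrix_tag,
                        "rank": rank,
                        "feature_index": j,
                        "mz": float(X.columns[j]),
                        "direction": "up" if np.median(a) >= np.median(b) else "down",
                        "p_value": max(float(p), np.finfo(float).tiny),
                        "cancer_median": float(np.median(a)),
                        "cancer_q1": float(np.quantile(a, 0.25)),
                        "cancer_q3": float(np.quantile(a, 0.75)),
                        "hc_median": float(np.median(b)),
                        "hc_q1": float(np.quantile(b, 0.25)),
                        "hc_q3": float(np.quantile(b, 0.75)),
                    }
                )
    return pd.DataFrame(rows)


def heatmap_matrix(
    X: pd.DataFrame,
    labels: pd.Series | Sequence,
    k: int = 30,
    C: float = 1.0,
    healthy_label: str = "HC",
) -> pd.DataFrame:
    """Class-mean z-scored intensities over the union of top-k features.

    The union pools each cancer's top-k (vs healthy) ranking; values are
    class means standardized per feature across classes (constant features
    map to zero rows).
    """
    y = pd.Series(np.asarray(labels), index=X.index) if not isinstance(labels, pd.Series) else labels
    y = y.reindex(X.index)
    hc_mask = (y == healthy_label).to_numpy()
    union: list[int] = []
    for cancer in CANCER_CLASSES:
        mask = (y == cancer).to_numpy()
        if mask.sum() < 2:
            continue
        sub = X.to_numpy(dtype=float)[mask | hc_mask]
        sub_y = np.where(mask[mask | hc_mask], cancer, healthy_label)
        for j in svm_rfe_adaptive(sub, sub_y, C=C).top(k):
            if j not in union:
                union.append(j)
    present = [c for c in (healthy_label,) + CANCER_CLASSES if (y == c).any()]
    means = pd.DataFrame(
        {X.columns[j]: [X.to_numpy(dtype=float)[(y == c).to_numpy()][:, j].mean() for c in present] for j in union},
        index=present,
    )
    sd = means.std(axis=0, ddof=0)
    z = (means - means.mean(axis=0)) / sd.replace(0.0, 1.0)
    return z
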