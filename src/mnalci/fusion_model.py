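"""Two-step fused SVM classification.

Step one is binary: one linear SVM per matrix (GNS, SiNW), each with
sigmoid (Platt) probability calibration fitted on out-of-fold decision
values. The MNALCI score of a sample is the sum of the two calibrated
cancer probabilities, in [0, 2]; the sample is called cancerous when the
score reaches the threshold θ (score >= θ).

Step two assigns the tissue of origin: per matrix, six one-vs-rest
calibrated classifiers; the fused class score is the sum of the two
matrices' class probabilities and the prediction is the argmax, ties broken
by the fixed class order (HCC, NSCLC, PAAD, CRC, GC, PTC).

Hyperparameters are selected by five-times-five-fold stratified
cross-validation on the training cohort, then the model is refit on the
whole training cohort at the winning setting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .constants import CANCER_CLASSES, MATRICES

CANCER, HEALTHY = "cancer", "healthy"

#: default hyperparameter grid: C log-spaced over 0.01..100
DEFAULT_C_GRID: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)

#: floor added before the optional log-intensity transform
LOG_EPS: float = 1e-9


def _log_intensity(X: np.ndarray) -> np.ndarray:
    """Log transform for non-negative intensity features.

    Multiplicative (lognormal) intensity variation becomes additive and
    symmetric on this scale, which keeps the calibrated score distributions
    of the two classes mirror-alike — the condition under which the
    accuracy-optimal threshold sits at the calibration midpoint.
    """
    return np.log(np.asarray(X, dtype=float) + LOG_EPS)


class AlignmentError(ValueError):
    """Feature matrices are not aligned on the same sample ids."""


def _check_aligned(X_by_matrix: Mapping[str, pd.DataFrame]) -> pd.Index:
    tags = list(X_by_matrix)
    index = X_by_matrix[tags[0]].index
    for tag in tags[1:]:
        other = X_by_matrix[tag].index
        if len(other) != len(index) or not (other == index).all():
            missing = sorted(set(index.tolist()) ^ set(other.tolist()))
            raise AlignmentError(f"sample ids differ between matrices: {missing[:20]}")
    return index


def _calibrated_linear_svm(C: float, seed: int, log_intensity: bool = False) -> Pipeline:
    """Standardized linear SVM with Platt calibration on out-of-fold scores."""
    from sklearn.preprocessing import FunctionTransformer

    svc = SVC(kernel="linear", C=C)
    calib = CalibratedClassifierCV(
        svc,
        method="sigmoid",
        cv=StratifiedKFold(n_splits=5, shuffle=True, random_state=seed),
        ensemble=False,
    )
    steps = [("scale", StandardScaler()), ("clf", calib)]
    if log_intensity:
        steps.insert(0, ("log", FunctionTransformer(_log_intensity, check_inverse=False)))
    return Pipeline(steps)


def _positive_proba(model, X: np.ndarray, positive) -> np.ndarray:
    clf = model.named_steps["clf"] if isinstance(model, Pipeline) else model
    col = list(clf.classes_).index(positive)
    return model.predict_proba(X)[:, col]


def _linear_params(model) -> tuple[np.ndarray, float]:
    """Weight vector and offset of the underlying fitted SVM."""
    if isinstance(model, LinearSigmoidModel):
        return model.w.copy(), model.b
    svc = model.named_steps["clf"].calibrated_classifiers_[0].estimator
    return np.ravel(svc.coef_).copy(), float(svc.intercept_[0])


@dataclass
class LinearSigmoidModel:
    """Plain-parameter form of a fitted, calibrated linear SVM.

    Reproduces the pipeline's probabilities exactly from (scaler, weights,
    sigmoid) parameters, so models persist as versioned JSON text and
    predictions stay bit-reproducible.
    """

    mean: np.ndarray
    scale: np.ndarray
    w: np.ndarray
    b: float
    sig_a: float
    sig_b: float
    classes: list[str]
    log_intensity: bool = False

    @property
    def classes_(self) -> list[str]:
        return self.classes

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.log_intensity:
            X = _log_intensity(X)
        Xs = (X - self.mean) / self.scale
        return Xs @ self.w + self.b

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        # sigmoid calibration convention: p(classes_[1]) = 1/(1+exp(a*f+b))
        p1 = 1.0 / (1.0 + np.exp(self.sig_a * self.decision_function(X) + self.sig_b))
        return np.column_stack([1.0 - p1, p1])

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "w": self.w.tolist(),
            "b": self.b,
            "sig_a": self.sig_a,
            "sig_b": self.sig_b,
            "classes": list(self.classes),
            "log_intensity": self.log_intensity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearSigmoidModel":
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            w=np.asarray(d["w"], dtype=float),
            b=float(d["b"]),
            sig_a=float(d["sig_a"]),
            sig_b=float(d["sig_b"]),
            classes=list(d["classes"]),
            log_intensity=bool(d.get("log_intensity", False)),
        )

    @classmethod
    def from_pipeline(cls, model: Pipeline) -> "LinearSigmoidModel":
        scaler: StandardScaler = model.named_steps["scale"]
        clf = model.named_steps["clf"]
        calibrated = clf.calibrated_classifiers_[0]
        svc = calibrated.estimator
        sig = calibrated.calibrators[0]
        return cls(
            mean=np.asarray(scaler.mean_, dtype=float),
            scale=np.asarray(scaler.scale_, dtype=float),
            w=np.ravel(svc.coef_).astype(float),
            b=float(svc.intercept_[0]),
            sig_a=float(sig.a_),
            sig_b=float(sig.b_),
            classes=[str(c) for c in clf.classes_],
            log_intensity="log" in model.named_steps,
        )


# ---------------------------------------------------------------------------
# binary fusion


@dataclass
class MnalciScore:
    """Fused score = p_GNS(cancer) + p_SiNW(cancer), in [0, 2]."""

    value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 2.0 + 1e-12):
            raise ValueError(f"MNALCI score {self.value} outside [0, 2]")


@dataclass
class ThresholdPolicy:
    """Decision boundary: cancerous iff score >= theta."""

    theta: float = 1.0
    fusion: bool = True

    def __post_init__(self) -> None:
        hi = 2.0 if self.fusion else 1.0
        if not (0.0 <= self.theta <= hi):
            raise ValueError(f"theta {self.theta} outside [0, {hi}]")


@dataclass
class BinaryFusionModel:
    """Per-matrix calibrated binary SVMs plus the fused decision rule."""

    models: dict[str, Pipeline]
    C: float
    seed: int
    feature_columns: dict[str, list] = field(default_factory=dict)

    def probabilities(self, X_by_matrix: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
        index = _check_aligned(X_by_matrix)
        cols = {}
        for tag, model in self.models.items():
            if tag not in X_by_matrix:
                raise AlignmentError(f"features for matrix {tag} missing (no imputation)")
            cols[tag] = _positive_proba(model, X_by_matrix[tag].to_numpy(dtype=float), CANCER)
        return pd.DataFrame(cols, index=index)

    def scores(self, X_by_matrix: Mapping[str, pd.DataFrame]) -> pd.Series:
        proba = self.probabilities(X_by_matrix)
        return proba.sum(axis=1).rename("mnalci_score")

    def linear_params(self, tag: str) -> tuple[np.ndarray, float]:
        return _linear_params(self.models[tag])

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        record = {
            "format_version": 1,
            "kind": "binary_fusion",
            "C": self.C,
            "seed": self.seed,
            "feature_columns": {t: [float(c) for c in cols] for t, cols in self.feature_columns.items()},
            "models": {
                tag: (m if isinstance(m, LinearSigmoidModel) else LinearSigmoidModel.from_pipeline(m)).to_dict()
                for tag, m in self.models.items()
            },
        }
        Path(path).write_text(json.dumps(record, indent=1))

    @classmethod
    def from_json(cls, path) -> "BinaryFusionModel":
        import json
        from pathlib import Path

        record = json.loads(Path(path).read_text())
        return cls(
            models={tag: LinearSigmoidModel.from_dict(d) for tag, d in record["models"].items()},
            C=record["C"],
            seed=record["seed"],
            feature_columns=record.get("feature_columns", {}),
        )


def fit_binary(
    X_gns: pd.DataFrame,
    X_sinw: pd.DataFrame,
    y: Sequence,
    C: float = 1.0,
    seed: int = 0,
    log_intensity: bool = False,
) -> BinaryFusionModel:
    """Train the two calibrated binary classifiers on aligned matrices.

    ``y`` holds ``cancer``/``healthy`` labels (anything not equal to
    ``healthy`` counts as cancer when exactly two labels are present).
    ``log_intensity`` log-transforms the non-negative intensity features
    before standardization (recommended for spectral bin intensities).
    """
    features = {"GNS": X_gns, "SiNW": X_sinw}
    index = _check_aligned(features)
    y = np.asarray(y)
    if len(y) != len(index):
        raise ValueError("label length does not match sample count")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"binary step needs exactly 2 classes, got {classes.tolist()}")
    y01 = np.where(y == HEALTHY, HEALTHY, CANCER) if HEALTHY in classes else None
    if y01 is None:
        raise ValueError(f"labels must include {HEALTHY!r}")
    models: dict[str, Pipeline] = {}
    for tag in MATRICES:
        model = _calibrated_linear_svm(C, seed, log_intensity=log_intensity)
        model.fit(features[tag].to_numpy(dtype=float), y01)
        models[tag] = model
    return BinaryFusionModel(
        models=models,
        C=C,
        seed=seed,
        feature_columns={tag: list(features[tag].columns) for tag in MATRICES},
    )


def mnalci_score(p_gns: float, p_sinw: float) -> MnalciScore:
    """Fuse the two calibrated cancer probabilities by summation."""
    for name, p in (("GNS", p_gns), ("SiNW", p_sinw)):
        if p is None or not np.isfinite(p):
            raise ValueError(f"{name} probability missing; fusion does not impute")
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} probability {p} outside [0, 1]")
    return MnalciScore(float(p_gns) + float(p_sinw))


def classify_binary(score: MnalciScore | float, policy: ThresholdPolicy) -> str:
    value = score.value if isinstance(score, MnalciScore) else float(score)
    hi = 2.0 if policy.fusion else 1.0
    if not (0.0 <= value <= hi + 1e-12):
        raise ValueError(f"score {value} outside [0, {hi}]")
    return CANCER if value >= policy.theta else HEALTHY


# ---------------------------------------------------------------------------
# multiclass fusion (one-vs-rest, soft voting)


@dataclass
class MulticlassFusionModel:
    """Per matrix: six one-vs-rest calibrated classifiers; fusion by summed
    class probabilities, argmax with fixed-order tie-break."""

    models: dict[str, dict[str, Pipeline]]  # matrix -> class -> pipeline
    C: float
    seed: int
    classes: tuple[str, ...] = CANCER_CLASSES

    def class_probabilities(self, X_by_matrix: Mapping[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
        index = _check_aligned(X_by_matrix)
        out: dict[str, pd.DataFrame] = {}
        for tag, per_class in self.models.items():
            X = X_by_matrix[tag].to_numpy(dtype=float)
            out[tag] = pd.DataFrame(
                {cls: _positive_proba(model, X, cls) for cls, model in per_class.items()},
                index=index,
            )[list(self.classes)]
        return out

    def fused_scores(self, X_by_matrix: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
        per_matrix = self.class_probabilities(X_by_matrix)
        tags = list(per_matrix)
        fused = per_matrix[tags[0]].copy()
        for tag in tags[1:]:
            fused = fused + per_matrix[tag]
        return fused

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        record = {
            "format_version": 1,
            "kind": "multiclass_fusion",
            "C": self.C,
            "seed": self.seed,
            "classes": list(self.classes),
            "models": {
                tag: {
                    cls: (m if isinstance(m, LinearSigmoidModel) else LinearSigmoidModel.from_pipeline(m)).to_dict()
                    for cls, m in per_class.items()
                }
                for tag, per_class in self.models.items()
            },
        }
        Path(path).write_text(json.dumps(record, indent=1))

    @classmethod
    def from_json(cls, path) -> "MulticlassFusionModel":
        import json
        from pathlib import Path

        record = json.loads(Path(path).read_text())
        return cls(
            models={
                tag: {c: LinearSigmoidModel.from_dict(d) for c, d in per_class.items()}
                for tag, per_class in record["models"].items()
            },
            C=record["C"],
            seed=record["seed"],
            classes=tuple(record["classes"]),
        )


def fit_multiclass_ovr(
    X_gns: pd.DataFrame,
    X_sinw: pd.DataFrame,
    y: Sequence,
    C: float = 1.0,
    seed: int = 0,
    classes: tuple[str, ...] = CANCER_CLASSES,
    log_intensity: bool = False,
) -> MulticlassFusionModel:
    """Fit the per-matrix one-vs-rest calibrated classifiers."""
    features = {"GNS": X_gns, "SiNW": X_sinw}
    index = _check_aligned(features)
    y = np.asarray(y)
    if len(y) != len(index):
        raise ValueError("label length does not match sample count")
    for cls in classes:
        if (y == cls).sum() < 2:
            raise ValueError(f"class {cls} missing or has fewer than 2 samples")
    models: dict[str, dict[str, Pipeline]] = {}
    for tag in MATRICES:
        X = features[tag].to_numpy(dtype=float)
        per_class: dict[str, Pipeline] = {}
        for cls in classes:
            y_ovr = np.where(y == cls, cls, "rest")
            model = _calibrated_linear_svm(C, seed, log_intensity=log_intensity)
            model.fit(X, y_ovr)
            per_class[cls] = model
        models[tag] = per_class
    return MulticlassFusionModel(models=models, C=C, seed=seed, classes=tuple(classes))


def fuse_and_predict(
    model: MulticlassFusionModel, X_by_matrix: Mapping[str, pd.DataFrame]
) -> tuple[pd.Series, pd.DataFrame]:
    """Fused class scores and argmax predictions (fixed-order tie-break)."""
    fused = model.fused_scores(X_by_matrix)
    values = fused.to_numpy()
    pred_idx = np.argmax(values, axis=1)  # first maximum wins: fixed class order
    preds = pd.Series([model.classes[i] for i in pred_idx], index=fused.index, name="prediction")
    return preds, fused


def argmax_class(fused_scores: Mapping[str, float], classes: Sequence[str] = CANCER_CLASSES) -> str:
    """Argmax over a single fused score vector, fixed-order tie-break."""
    values = [fused_scores[c] for c in classes]
    return list(classes)[int(np.argmax(values))]


def majority_vote(member_outputs: Sequence[Mapping[str, float]], categories: Sequence[str]) -> str | None:
    """Majority vote: return the category whose summed vote strictly exceeds
    half the total vote mass, otherwise ``None`` (reject)."""
    if not member_outputs:
        raise ValueError("need at least one member classifier")
    totals = {c: sum(float(out.get(c, 0.0)) for out in member_outputs) for c in categories}
    grand = sum(totals.values())
    for c in categories:
        if totals[c] > 0.5 * grand:
            return c
    return None


# ---------------------------------------------------------------------------
# two-step pipeline prediction


def predict_two_step(
    binary_model: BinaryFusionModel,
    multiclass_model: MulticlassFusionModel,
    X_by_matrix: Mapping[str, pd.DataFrame],
    policy: ThresholdPolicy | None = None,
    healthy_label: str = "HC",
) -> pd.Series:
    """Binary gate at θ, then tissue-of-origin argmax for cancer calls."""
    policy = policy or ThresholdPolicy()
    scores = binary_model.scores(X_by_matrix)
    preds, _ = fuse_and_predict(multiclass_model, X_by_matrix)
    out = preds.copy()
    out[scores < policy.theta] = healthy_label
    return out.rename("prediction")


# ---------------------------------------------------------------------------
# cross-validation


def cross_validate_5x5(
    X_gns: pd.DataFrame,
    X_sinw: pd.DataFrame,
    y: Sequence,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    theta: float = 1.0,
    seed: int = 0,
    n_splits: int = 5,
    n_repeats: int = 5,
    log_intensity: bool = False,
) -> tuple[float, float, BinaryFusionModel]:
    """Five-times five-fold stratified CV over the C grid.

    Error per fold is the fused misclassification rate at the given θ; the
    best C (smallest mean error, smaller C on ties) is refit on the whole
    training cohort. Returns (best_C, best_mean_error, refit model).
    """
    C_grid = list(C_grid)
    if not C_grid:
        raise ValueError("hyperparameter grid is empty")
    features = {"GNS": X_gns, "SiNW": X_sinw}
    _check_aligned(features)
    y = np.asarray(y)
    policy = ThresholdPolicy(theta=theta, fusion=True)
    cv = RepeatedStratifiedKFold(n_splits=n_splits, n_repeats=n_repeats, random_state=seed)
    mean_errors: list[float] = []
    for C in C_grid:
        errors = []
        for train_idx, test_idx in cv.split(X_gns, y):
            model = fit_binary(
                X_gns.iloc[train_idx], X_sinw.iloc[train_idx], y[train_idx],
                C=C, seed=seed, log_intensity=log_intensity,
            )
            scores = model.scores({"GNS": X_gns.iloc[test_idx], "SiNW": X_sinw.iloc[test_idx]})
            preds = np.array([classify_binary(s, policy) for s in scores])
            truth = np.where(y[test_idx] == HEALTHY, HEALTHY, CANCER)
            errors.append(float(np.mean(preds != truth)))
        mean_errors.append(float(np.mean(errors)))
    best = int(np.argmin(mean_errors))  # first minimum: smaller C wins ties
    best_model = fit_binary(X_gns, X_sinw, y, C=C_grid[best], seed=seed, log_intensity=log_intensity)
    return C_grid[best], mean_errors[best], best_model
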