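"""Independent small-scale linear SVM + RFE oracle for cross-checking.

Solves the soft-margin dual directly with SLSQP (no sklearn involvement)
and replays the literal eliminate-the-smallest-weight loop. Only intended
for tiny instances (n <= 40, p <= 8).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def dual_svm_weights(X: np.ndarray, y_pm: np.ndarray, C: float = 1.0) -> np.ndarray:
    """Solve max_a sum(a) - 1/2 a'Q a, 0 <= a <= C, sum(a*y) = 0; return w."""
    n = X.shape[0]
    Q = (y_pm[:, None] * X) @ (y_pm[:, None] * X).T
    Q = Q + 1e-10 * np.eye(n)  # numerical ridge

    def neg_obj(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def neg_grad(a):
        return -(np.ones(n) - Q @ a)

    res = minimize(
        neg_obj,
        x0=np.full(n, min(C, 1.0) / 2),
        jac=neg_grad,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y_pm, "jac": lambda a: y_pm}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    alpha = res.x
    return (alpha * y_pm) @ X


def oracle_rfe_ranking(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> list[int]:
    """Literal RFE loop on the dual solver; ties eliminate the lower index."""
    X = np.asarray(X, dtype=float)
    mean, sd = X.mean(axis=0), X.std(axis=0)
    Xs = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    classes = np.unique(y)
    y_pm = np.where(np.asarray(y) == classes[1], 1.0, -1.0)
    remaining = list(range(X.shape[1]))
    eliminated: list[int] = []
    while remaining:
        if len(remaining) == 1:
            eliminated.append(remaining.pop())
            break
        w = dual_svm_weights(Xs[:, remaining], y_pm, C=C)
        crit = w**2
        j = min(range(len(remaining)), key=lambda i: (crit[i], remaining[i]))
        eliminated.append(remaining.pop(j))
    return eliminated[::-1]
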