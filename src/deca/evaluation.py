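"""Deconvolution accuracy metrics.

Lin's concordance correlation coefficient (CCC), mean absolute error
(MAE) and Spearman's rank correlation, reported per sample (over the
k-vector of cell types), per cell type (over samples) and overall
(over all flattened entries).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["MetricReport", "ccc", "mae", "spearman", "evaluate"]


@dataclass
class MetricReport:
    per_celltype: dict = field(default_factory=dict)  # name -> {"ccc":, "mae":}
    per_sample: dict = field(default_factory=dict)
    overall: dict = field(default_factory=dict)  # ccc, mae, spearman


def ccc(X, Y) -> float:
    """Lin's concordance correlation coefficient with population (1/n) moments.

    2 cov(X,Y) / (var X + var Y + (mean X - mean Y)^2); returns 0 when
    the denominator is 0 (both vectors constant and equal means).
    """
    X, Y = np.asarray(X, dtype=float).ravel(), np.asarray(Y, dtype=float).ravel()
    if X.shape != Y.shape:
        raise ValueError(f"length mismatch {X.shape} vs {Y.shape}")
    if len(X) < 2:
        raise ValueError("ccc requires length >= 2")
    mx, my = X.mean(), Y.mean()
    cov = np.mean((X - mx) * (Y - my))
    denom = X.var() + Y.var() + (mx - my) ** 2
    if denom == 0:
        return 0.0
    return float(2.0 * cov / denom)


def mae(X, X_tilde) -> float:
    """Mean absolute error: sum |X_ij - X~_ij| / (n k)."""
    X, X_tilde = np.asarray(X, dtype=float), np.asarray(X_tilde, dtype=float)
    if X.shape != X_tilde.shape:
        raise ValueError(f"shape mismatch {X.shape} vs {X_tilde.shape}")
    return float(np.mean(np.abs(X - X_tilde)))


def spearman(y, y_hat) -> float:
    """Spearman rank correlation (average ranks on ties).

    A constant input vector makes the correlation undefined; 0 is
    returned with a warning rather than NaN.
    """
    y, y_hat = np.asarray(y, dtype=float).ravel(), np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch {y.shape} vs {y_hat.shape}")
    if len(y) < 2:
        raise ValueError("spearman requires length >= 2")
    if np.ptp(y) == 0 or np.ptp(y_hat) == 0:
        warnings.warn("spearman undefined for a constant vector; returning 0", stacklevel=2)
        return 0.0
    r, _ = stats.spearmanr(y, y_hat)
    return float(r)


def evaluate(P_true: np.ndarray, P_hat: np.ndarray,
             celltypes: list[str] | None = None) -> MetricReport:
    """Full metric report for predicted vs true proportion matrices.

    Per-sample CCC/MAE over each k-vector; per-cell-type CCC/MAE over the
    sample axis (reported as missing, not 0, when there is a single
    sample); overall CCC/MAE/Spearman over all flattened entries.
    """
    P_true, P_hat = np.asarray(P_true, float), np.asarray(P_hat, float)
    if P_true.shape != P_hat.shape:
        raise ValueError(f"shape mismatch {P_true.shape} vs {P_hat.shape}")
    n, k = P_true.shape
    names = celltypes if celltypes is not None else [f"type_{i}" for i in range(k)]

    report = MetricReport()
    for i in range(n):
        report.per_sample[i] = {
            "ccc": ccc(P_true[i], P_hat[i]) if k >= 2 else None,
            "mae": mae(P_true[i], P_hat[i]),
        }
    for t, name in enumerate(names):
        if n >= 2:
            report.per_celltype[name] = {
                "ccc": ccc(P_true[:, t], P_hat[:, t]),
                "mae": mae(P_true[:, t], P_hat[:, t]),
            }
        else:
            report.per_celltype[name] = {"ccc": None, "mae": None}
    report.overall = {
        "ccc": ccc(P_true.ravel(), P_hat.ravel()),
        "mae": mae(P_true, P_hat),
        "spearman": spearman(P_true.ravel(), P_hat.ravel()),
    }
    return report
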