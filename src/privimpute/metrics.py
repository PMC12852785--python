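"""Benchmark statistics: coefficient recovery, imputation and prediction
quality, and the cross-implementation discrepancy count.

All metrics operate on decoded (plaintext) arrays -- they evaluate study
results, which are the agreed public output of the protocols.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .chebyshev import sigmoid

__all__ = [
    "RunMetrics",
    "theta_stats",
    "imputation_error",
    "prediction_error",
    "auc",
    "ols_within_variances",
    "logistic_within_variances",
    "pooled_wald_pvalues",
    "summarize_analysis",
    "AnalysisSummary",
    "discrepancy_count",
]

BINARY_THRESHOLD = 0.5


@dataclass
class RunMetrics:
    """Per-run (or aggregate) statistics keyed the way the benchmark tables are."""

    scenario: int | None = None
    n: int | None = None
    method: str = "plaintext"
    seed: int | None = None
    theta_bias: float | None = None
    theta_sd: float | None = None
    theta_rmse: float | None = None
    imputation: dict = field(default_factory=dict)
    final_analysis: dict = field(default_factory=dict)
    discrepancies: int | None = None
    protocol: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "scenario": self.scenario,
            "n": self.n,
            "method": self.method,
            "seed": self.seed,
            "theta_bias": self.theta_bias,
            "theta_sd": self.theta_sd,
            "theta_rmse": self.theta_rmse,
            "discrepancies": self.discrepancies,
        }
        out.update({f"imp_{k}": v for k, v in self.imputation.items()})
        out.update({f"final_{k}": v for k, v in self.final_analysis.items()})
        out.update({f"protocol_{k}": v for k, v in self.protocol.items()})
        return out


def theta_stats(theta_runs: np.ndarray, theta_true: np.ndarray):
    """Bias, standard deviation and root-mean-squared error of fitted weights.

    ``bias = ||E theta - theta_true||_2``, ``sd = sqrt(E ||theta - E theta||_2^2)``
    and ``rmse = sqrt(E ||theta - theta_true||_2^2)``, with the expectation
    taken over repeated runs; ``rmse^2 = bias^2 + sd^2`` holds exactly.
    """
    runs = np.atleast_2d(np.asarray(theta_runs, dtype=float))
    true = np.asarray(theta_true, dtype=float).ravel()
    if runs.shape[1] != true.size:
        raise ValueError("theta_runs and theta_true disagree on dimension")
    mean = runs.mean(axis=0)
    bias = float(np.linalg.norm(mean - true))
    sd = float(np.sqrt(np.mean(np.sum((runs - mean) ** 2, axis=1))))
    rmse = float(np.sqrt(np.mean(np.sum((runs - true) ** 2, axis=1))))
    return bias, sd, rmse


def auc(scores, labels) -> float:
    """Area under the ROC curve as the Mann-Whitney rank statistic (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)  # average ranks implement the tie convention
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def imputation_error(imputed, truth, mask, binary: bool = False):
    """Imputation quality over the originally missing entries only.

    Continuous: mean and standard deviation of the absolute deviation from
    ground truth.  Binary: accuracy of the 0.5-thresholded imputations and
    the AUC of the imputed probabilities.
    """
    imputed = np.asarray(imputed, dtype=float)
    truth = np.asarray(truth, dtype=float)
    missing = np.asarray(mask) == 0
    if not missing.any():
        raise ValueError("mask marks no entry as missing")
    vals, ref = imputed[missing], truth[missing]
    if binary:
        acc = float(np.mean((vals > BINARY_THRESHOLD) == (ref > BINARY_THRESHOLD)))
        return acc, auc(vals, ref)
    err = np.abs(vals - ref)
    return float(err.mean()), float(err.std())


def prediction_error(coef: np.ndarray, X_imputed: np.ndarray, y: np.ndarray,
                     logistic: bool = False):
    """Final-analysis quality of pooled coefficients on the completed dataset.

    Linear: mean/sd of ``|X~ c - y|``.  Logistic: accuracy and AUC of
    ``sigmoid(X~ c)`` against the binary outcome.
    """
    coef = np.asarray(coef, dtype=float).ravel()
    Xb = np.column_stack([np.asarray(X_imputed, dtype=float),
                          np.ones(len(X_imputed))])
    eta = Xb @ coef
    yv = np.asarray(y, dtype=float).ravel()
    if logistic:
        prob = sigmoid(eta)
        acc = float(np.mean((prob > BINARY_THRESHOLD) == (yv == 1)))
        return acc, auc(prob, yv)
    err = np.abs(eta - yv)
    return float(err.mean()), float(err.std())


def ols_within_variances(X_imputed: np.ndarray, y: np.ndarray,
                         coef: np.ndarray | None = None) -> np.ndarray:
    """Sampling variances of OLS coefficients on one completed dataset.

    ``sigma^2 diag((X~' X~)^-1)`` with the residual variance taken at the
    supplied coefficients (or the exact OLS solution when omitted).
    """
    Xb = np.column_stack([np.asarray(X_imputed, dtype=float),
                          np.ones(len(X_imputed))])
    yv = np.asarray(y, dtype=float).ravel()
    G_inv = np.linalg.inv(Xb.T @ Xb)
    if coef is None:
        coef = G_inv @ (Xb.T @ yv)
    resid = yv - Xb @ np.asarray(coef, dtype=float).ravel()
    dof = max(Xb.shape[0] - Xb.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    return sigma2 * np.diag(G_inv)


def pooled_wald_pvalues(coef_rows: np.ndarray, within: np.ndarray):
    """Two-sided normal-approximation Wald p-values from the Rubin total variance."""
    from .mice import rubin_variance

    rows = np.atleast_2d(np.asarray(coef_rows, dtype=float))
    pooled = rows.mean(axis=0)
    total = rubin_variance(rows, within)
    se = np.sqrt(np.maximum(total, 1e-300))
    z = pooled / se
    return pooled, 2.0 * stats.norm.sf(np.abs(z))


def logistic_within_variances(X_imputed: np.ndarray, y: np.ndarray,
                              coef: np.ndarray) -> np.ndarray:
    """Wald variances for logistic coefficients (inverse observed information)."""
    Xb = np.column_stack([np.asarray(X_imputed, dtype=float),
                          np.ones(len(X_imputed))])
    c = np.asarray(coef, dtype=float).ravel()
    p = sigmoid(Xb @ c)
    w = np.clip(p * (1.0 - p), 1e-10, None)
    info = Xb.T @ (Xb * w[:, None])
    return np.diag(np.linalg.inv(info))


def summarize_analysis(coef_rows: np.ndarray, imputed_list, y,
                       logistic: bool = False) -> "AnalysisSummary":
    """Pooled coefficients + Rubin-variance Wald p-values for one MICE analysis."""
    rows = np.atleast_2d(np.asarray(coef_rows, dtype=float))
    within = np.vstack([
        logistic_within_variances(X, y, rows[i]) if logistic
        else ols_within_variances(X, y, rows[i])
        for i, X in enumerate(imputed_list)
    ])
    pooled, pvals = pooled_wald_pvalues(rows, within)
    return AnalysisSummary(pooled, pvals)


@dataclass(frozen=True)
class AnalysisSummary:
    """Pooled coefficients and p-values of one final analysis (bias term last)."""

    coef: np.ndarray
    pvalues: np.ndarray

    def __post_init__(self):
        if len(self.coef) != len(self.pvalues):
            raise ValueError("coefficients and p-values disagree on length")


def discrepancy_count(base: AnalysisSummary, target: AnalysisSummary,
                      alpha: float = 0.05, include_bias: bool = False) -> int:
    """Variables significant in the base analysis that lose significance or
    flip coefficient sign in the target analysis.

    The definition is directional: swapping base and target can change the
    count.  The bias term is excluded by default (it is not a study variable).
    """
    if len(base.coef) != len(target.coef):
        raise ValueError("analyses cover different variable sets")
    n = len(base.coef) if include_bias else len(base.coef) - 1
    count = 0
    for j in range(n):
        if base.pvalues[j] <= alpha and (
            target.pvalues[j] > alpha or base.coef[j] * target.coef[j] < 0
        ):
            count += 1
    return count
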