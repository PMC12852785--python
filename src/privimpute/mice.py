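"""Chained-equations imputation, the multiple-imputation driver, and pooling.

A single chained pass visits the incomplete columns in ascending index
order.  For each such column the column-appropriate regression (linear for
continuous, logistic for binary) is fitted on the rows that are fully
observed under the *current* mask, missing entries are filled with model
predictions -- plus a fresh ``N(0, noise_variance)`` draw for continuous
columns -- and the column's mask is set to one so later columns train on the
freshly imputed values.  The public mask is an accepted protocol leakage
(positions, never values, of missing data).

Binary columns are imputed with the predicted success probability rather
than a hard 0/1 label: thresholding a shared probability would require a
secure comparison, and writing the probability keeps the plaintext and
secure pipelines on the same arithmetic path.  Thresholding happens only in
evaluation (see :mod:`privimpute.metrics`).

``multiple_impute_analyze`` repeats the pass ``k`` times from the original
data (fresh noise draws are the only stochastic difference when the fits are
deterministic), fits the final-analysis model on each completed dataset, and
pools the coefficient vectors by their arithmetic mean -- under sharing the
average is taken on the shares without decryption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regression import RegressionModel, linreg_fit, logreg_fit, predict

__all__ = [
    "ImputationTask",
    "FitSpec",
    "MICEResult",
    "chained_impute",
    "multiple_impute_analyze",
    "rubin_pool",
    "rubin_variance",
    "NoCompleteRowsError",
    "AllMissingColumnError",
]

CONTINUOUS = "continuous"
BINARY = "binary"


class NoCompleteRowsError(ValueError):
    """No fully observed row is available to fit an imputation model."""


class AllMissingColumnError(ValueError):
    """A column has no observed entry at all."""


@dataclass
class ImputationTask:
    """An incomplete dataset: data matrix, public 0/1 mask, outcome, column kinds."""

    data: np.ndarray  # (m, n), missing entries zero-filled
    mask: np.ndarray  # (m, n) ints, 0 = missing; public
    y: np.ndarray  # (m, 1)
    column_kinds: tuple[str, ...]
    noise_variance: float = 0.01

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask)
        self.y = np.asarray(self.y, dtype=float).reshape(-1, 1)
        if self.mask.shape != self.data.shape:
            raise ValueError("mask shape must equal data shape")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")
        if self.y.shape[0] != self.data.shape[0]:
            raise ValueError("outcome length must match the row count")
        if len(self.column_kinds) != self.data.shape[1]:
            raise ValueError("need one column kind per column")
        for kind in self.column_kinds:
            if kind not in (CONTINUOUS, BINARY):
                raise ValueError(f"unknown column kind {kind!r}")
        if np.any(self.data[self.mask == 0] != 0.0):
            raise ValueError("masked entries of the input data must be zero-filled")
        for j, kind in enumerate(self.column_kinds):
            if kind == BINARY:
                obs = self.data[self.mask[:, j] == 1, j]
                if not np.isin(obs, (0.0, 1.0)).all():
                    raise ValueError(f"binary column {j} has non-0/1 observed entries")

    @property
    def shape(self):
        return self.data.shape


@dataclass(frozen=True)
class FitSpec:
    """Hyperparameters for one regression family (None keeps the fit defaults)."""

    kind: str = "linear"
    epochs: int | None = None
    lr: float | None = None
    batch_size: int | None = None

    def fit(self, engine, X, y) -> RegressionModel:
        kwargs = {}
        if self.epochs is not None:
            kwargs["epochs"] = self.epochs
        if self.lr is not None:
            kwargs["lr"] = self.lr
        if self.kind == "linear":
            return linreg_fit(engine, X, y, batch_size=self.batch_size, **kwargs)
        return logreg_fit(engine, X, y, batch_size=self.batch_size, **kwargs)


@dataclass
class ImputationSpec:
    """Per-family fit specs for the chained-equations imputation models."""

    continuous: FitSpec = field(default_factory=lambda: FitSpec("linear"))
    binary: FitSpec = field(default_factory=lambda: FitSpec("logistic"))

    def for_kind(self, kind: str) -> FitSpec:
        return self.continuous if kind == CONTINUOUS else self.binary


@dataclass
class MICEResult:
    """Per-imputation coefficient rows, their pooled mean, and optional extras."""

    coefficients: object  # engine-typed (k, n_features + 1)
    pooled: object  # engine-typed (n_features + 1, 1)
    imputed_datasets: list | None = None
    models: list | None = None


def chained_impute(engine, task: ImputationTask, spec: ImputationSpec | None = None,
                   rng=None, sweeps: int = 1):
    """One multiple-imputation draw: a chained pass over the incomplete columns.

    Returns the completed data matrix as an engine value.  The outcome ``y``
    is deliberately not among the imputation predictors.
    """
    spec = spec or ImputationSpec()
    rng = rng if rng is not None else np.random.default_rng()
    mask = np.asarray(task.mask, dtype=int).copy()
    D = engine.lift(task.data)
    m, n = task.shape
    if mask.all():
        return D
    for j in range(n):
        if mask[:, j].sum() == 0:
            raise AllMissingColumnError(f"column {j} has no observed entries")
    for _ in range(max(1, sweeps)):
        for j in range(n):
            col_mask = mask[:, j]
            if col_mask.all():
                continue
            complete = mask.all(axis=1)
            if not complete.any():
                raise NoCompleteRowsError(
                    f"no fully observed rows available to impute column {j}"
                )
            others = [k for k in range(n) if k != j]
            C = engine.rows(D, complete)
            model = spec.for_kind(task.column_kinds[j]).fit(
                engine, C[:, others], C[:, j : j + 1]
            )
            # prediction input is the masked data product (D . M): entries of
            # still-unimputed later columns enter as zeros, exactly as the
            # chained pass defines them
            masked = engine.mul_mask(D, mask)
            kind = task.column_kinds[j]
            yhat = predict(
                engine,
                model,
                masked[:, others],
                noise_variance=task.noise_variance if kind == CONTINUOUS else 0.0,
                rng=rng,
            )
            col = col_mask.reshape(-1, 1)
            newcol = engine.add(
                engine.mul_mask(D[:, j : j + 1], col),
                engine.mul_mask(yhat, 1 - col),
            )
            engine.set_col(D, j, newcol)
            mask[:, j] = 1
    return D


def multiple_impute_analyze(
    engine,
    task: ImputationTask,
    imputation_spec: ImputationSpec | None = None,
    final_spec: FitSpec | None = None,
    k: int = 5,
    seed: int | None = None,
    keep_imputed: bool = False,
) -> MICEResult:
    """``k`` independent impute-then-fit rounds pooled by Rubin's rules.

    Each round restarts from the original incomplete data with fresh noise
    draws (child generators spawned from ``seed``, so plaintext and secure
    runs given the same seed consume identical draws).
    """
    if k < 1:
        raise ValueError("need at least one imputation")
    imputation_spec = imputation_spec or ImputationSpec()
    final_spec = final_spec or FitSpec("linear")
    child_seeds = np.random.SeedSequence(seed).spawn(k)
    y = engine.lift(task.y)
    rows = []
    imputed = [] if keep_imputed else None
    models = []
    for i in range(k):
        D = chained_impute(
            engine, task, imputation_spec, rng=np.random.default_rng(child_seeds[i])
        )
        model = final_spec.fit(engine, D, y)
        rows.append(model.weights.T)
        models.append(model)
        if keep_imputed:
            imputed.append(D)
    C = rows[0]
    for r in rows[1:]:
        C = engine.concat_rows(C, r)
    return MICEResult(C, rubin_pool(engine, C), imputed, models)


def rubin_pool(engine, C):
    """Column-wise arithmetic mean of the per-imputation coefficient rows.

    Under sharing the mean is computed on the shares (local sums plus a
    public scale), i.e. without decrypting any individual model.
    """
    k = C.shape[0]
    if k == 0:
        raise ValueError("empty coefficient matrix")
    return engine.scale(engine.col_sums(C), 1.0 / k).T


def rubin_variance(C: np.ndarray, within_variances: np.ndarray) -> np.ndarray:
    """Total multiple-imputation variance ``T = W + (1 + 1/k) B`` per coefficient.

    ``W`` is the mean within-imputation sampling variance and ``B`` the
    between-imputation variance of the coefficients; this is the standard
    completion used to attach Wald p-values to the pooled coefficients.
    Plaintext-only (inference happens on decoded results).
    """
    C = np.asarray(C, dtype=float)
    W = np.asarray(within_variances, dtype=float)
    k = C.shape[0]
    if k < 2:
        raise ValueError("between-imputation variance needs k >= 2")
    if W.shape != C.shape:
        raise ValueError("need one within-variance per coefficient per imputation")
    B = C.var(axis=0, ddof=1)
    return W.mean(axis=0) + (1.0 + 1.0 / k) * B
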