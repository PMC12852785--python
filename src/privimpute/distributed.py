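"""Partitioned-dataflow variant: local plaintext blocks, explicit aggregation.

This mirrors the multiparty-homomorphic-encryption style of distributed
computation: every party keeps its horizontal data partition in the clear,
computes whatever it can locally (per-party Gramians, bias columns,
complete-row filtering), and only *aggregated* values -- sums or
concatenations of local contributions -- circulate in protected form.  Two
matrix-product shapes suffice for regression: a vertically partitioned
matrix times a horizontally partitioned one (computed locally, the result is
additively partitioned) and a product with one aggregated operand.

The protected-value backend is a contract (slot count, scale, and an
operation log stand in for ciphertext metadata); the default implementation
is the additive-secret-sharing engine, so a lattice-based backend honoring
the same surface could drop in.  Aggregation counts are recorded: the
logistic loop aggregates the (bias-extended) data matrix and its transpose
exactly once each, never the weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fixedpoint as fx
from .engine import SecureEngine
from .mice import (
    BINARY,
    CONTINUOUS,
    FitSpec,
    ImputationSpec,
    MICEResult,
    NoCompleteRowsError,
    AllMissingColumnError,
    rubin_pool,
)
from .regression import (
    CLOSED_FORM_MAX_COLS,
    RegressionModel,
    destandardize_weights,
)

__all__ = [
    "PartitionedMatrix",
    "ShareBackend",
    "aggregate",
    "partitioned_matmul",
    "mhe_linreg_fit",
    "mhe_logreg_fit",
    "mhe_mice_analyze",
]


class ShareBackend(SecureEngine):
    """Secure-vector backend contract implemented with additive secret sharing.

    ``slot_count`` and ``scale_bits`` are contract metadata (the SIMD width
    and default scale a slot-encoded backend would use); the operation log
    counts aggregations, plaintext-protected and protected-protected
    products, and decryptions, so dataflow properties are testable.
    """

    slot_count = 8192
    scale_bits = 34

    def __init__(self, ctx: fx.DealerContext | None = None, sigmoid_approx=None):
        super().__init__(ctx, sigmoid_approx)
        self.oplog = {
            "aggregations": 0,
            "encryptions": 0,
            "pc_mults": 0,
            "cc_mults": 0,
            "decryptions": 0,
            "rotations": 0,
        }

    def encrypt(self, arr):
        self.oplog["encryptions"] += 1
        return self.lift(arr)

    def decrypt(self, value):
        self.oplog["decryptions"] += 1
        return self.reveal(value)

    def aggregate_sum(self, blocks):
        """Sum additive contributions (plaintext arrays or protected values)."""
        self.oplog["aggregations"] += 1
        total = None
        for blk in blocks:
            val = blk if isinstance(blk, fx.SecretSharedMatrix) else self.lift_public(blk)
            total = val if total is None else self.add(total, val)
        return total

    def aggregate_rows(self, blocks):
        """Concatenate horizontal (row-block) contributions under protection."""
        self.oplog["aggregations"] += 1
        out = None
        for blk in blocks:
            val = blk if isinstance(blk, fx.SecretSharedMatrix) else self.lift(blk)
            out = val if out is None else self.concat_rows(out, val)
        return out

    def aggregate_cols(self, blocks):
        self.oplog["aggregations"] += 1
        out = None
        for blk in blocks:
            val = blk if isinstance(blk, fx.SecretSharedMatrix) else self.lift(blk)
            out = val if out is None else self.concat_cols(out, val)
        return out

    def pc_matmul(self, plain, value):
        """Product of a party-local plaintext matrix with a protected value."""
        self.oplog["pc_mults"] += 1
        enc = np.asarray(fx.fp_encode(np.asarray(plain, dtype=float), self.cfg), dtype=object)
        mod = self.cfg.modulus
        doubled = fx.SecretSharedMatrix([(enc @ s) % mod for s in value.shares], self.cfg)
        return fx.smc_truncate(doubled, self.cfg.frac_bits)

    def matmul(self, a, b):
        self.oplog["cc_mults"] += 1
        return super().matmul(a, b)

    def mul_elem(self, a, b):
        self.oplog["cc_mults"] += 1
        return super().mul_elem(a, b)


@dataclass
class PartitionedMatrix:
    """A matrix split among parties: row blocks, column blocks, additive
    summands, or one backend-protected replicated value."""

    partitioning: str  # horizontal | vertical | additive | aggregated
    blocks: list = field(default_factory=list)
    value: object = None  # protected value when aggregated
    global_shape: tuple = ()

    _KINDS = ("horizontal", "vertical", "additive", "aggregated")

    def __post_init__(self) -> None:
        if self.partitioning not in self._KINDS:
            raise ValueError(f"unknown partitioning {self.partitioning!r}")
        if self.partitioning == "aggregated":
            if self.value is None:
                raise ValueError("aggregated partitioning needs a protected value")
            self.global_shape = tuple(self.value.shape)
            return
        if not self.blocks:
            raise ValueError("need at least one local block")
        shapes = [np.shape(b) for b in self.blocks]
        if self.partitioning == "horizontal":
            cols = {s[1] for s in shapes}
            if len(cols) != 1:
                raise ValueError("row blocks disagree on column count")
            self.global_shape = (sum(s[0] for s in shapes), cols.pop())
        elif self.partitioning == "vertical":
            rows = {s[0] for s in shapes}
            if len(rows) != 1:
                raise ValueError("column blocks disagree on row count")
            self.global_shape = (rows.pop(), sum(s[1] for s in shapes))
        else:  # additive
            if len(set(shapes)) != 1:
                raise ValueError("additive blocks must share one shape")
            self.global_shape = shapes[0]

    @property
    def party_count(self) -> int:
        return len(self.blocks) if self.partitioning != "aggregated" else 1

    def decode(self, backend: ShareBackend | None = None) -> np.ndarray:
        """Reassemble the global matrix (decrypting protected parts)."""
        if self.partitioning == "aggregated":
            return backend.decrypt(self.value)
        if self.partitioning == "horizontal":
            return np.vstack(self.blocks)
        if self.partitioning == "vertical":
            return np.hstack(self.blocks)
        total = None
        for blk in self.blocks:
            arr = backend.decrypt(blk) if isinstance(blk, fx.SecretSharedMatrix) else np.asarray(blk, dtype=float)
            total = arr if total is None else total + arr
        return total


def aggregate(p: PartitionedMatrix, backend: ShareBackend) -> PartitionedMatrix:
    """Turn local contributions into one protected value every party holds."""
    if p.partitioning == "aggregated":
        return p
    if p.partitioning == "additive":
        value = backend.aggregate_sum(p.blocks)
    elif p.partitioning == "horizontal":
        value = backend.aggregate_rows(p.blocks)
    else:
        value = backend.aggregate_cols(p.blocks)
    return PartitionedMatrix("aggregated", value=value)


def partitioned_matmul(a: PartitionedMatrix, b: PartitionedMatrix,
                       backend: ShareBackend | None = None) -> PartitionedMatrix:
    """The two product shapes the regression dataflow needs.

    vertical x horizontal: party-local block products, additively
    partitioned result, zero communication.  additive x aggregated (either
    order): each party multiplies its summand with the protected operand.
    """
    if a.partitioning == "vertical" and b.partitioning == "horizontal":
        if a.party_count != b.party_count:
            raise ValueError("operands distributed over different party counts")
        blocks = [x @ y for x, y in zip(a.blocks, b.blocks)]
        return PartitionedMatrix("additive", blocks=blocks)
    if a.partitioning == "additive" and b.partitioning == "aggregated":
        blocks = [backend.pc_matmul(x, b.value) for x in a.blocks]
        return PartitionedMatrix("additive", blocks=blocks)
    if a.partitioning == "aggregated" and b.partitioning == "additive":
        blocks = [
            backend.pc_matmul(y.T, a.value.T).T for y in b.blocks
        ]
        return PartitionedMatrix("additive", blocks=blocks)
    raise ValueError(
        f"unsupported pairing: {a.partitioning} x {b.partitioning}"
    )


def _append_bias_local(blocks):
    return [np.column_stack([b, np.ones(len(b))]) for b in blocks]


def mhe_linreg_fit(X_blocks, y_blocks, backend: ShareBackend,
                   epochs: int = 500, lr: float = 0.1) -> RegressionModel:
    """Distributed linear regression on horizontal partitions.

    Per-party Gramians ``C_i = X~_i' X~_i`` and moments ``R_i = X~_i' y_i``
    are computed with zero communication; the closed form aggregates and
    inverts, gradient descent re-aggregates the weights every epoch while
    each party updates its additive weight summand locally.
    """
    Xb = _append_bias_local([np.asarray(b, dtype=float) for b in X_blocks])
    ys = [np.asarray(b, dtype=float).reshape(-1, 1) for b in y_blocks]
    m = sum(len(b) for b in Xb)
    p1 = Xb[0].shape[1]
    C_parts = [x.T @ x for x in Xb]
    R_parts = [x.T @ y for x, y in zip(Xb, ys)]
    if p1 < CLOSED_FORM_MAX_COLS:
        if m < p1:
            raise ValueError(f"closed form needs at least {p1} pooled rows, got {m}")
        C = backend.scale(backend.aggregate_sum(C_parts), 1.0 / m)
        R = backend.scale(backend.aggregate_sum(R_parts), 1.0 / m)
        w = backend.matmul(backend.inverse_small(C), R)
        return RegressionModel("linear", w, epochs, lr)
    parts = [backend.zeros((p1, 1)) for _ in Xb]
    for _ in range(epochs):
        w = backend.aggregate_sum(parts)
        new_parts = []
        for Ci, Ri, part in zip(C_parts, R_parts, parts):
            grad = backend.add_plain(
                backend.neg(backend.pc_matmul(Ci / m, w)), Ri / m
            )
            new_parts.append(backend.add(part, backend.scale(grad, lr)))
        parts = new_parts
    return RegressionModel("linear", backend.aggregate_sum(parts), epochs, lr)


def _global_moments(X_blocks):
    m = sum(len(b) for b in X_blocks)
    s1 = sum(b.sum(axis=0) for b in X_blocks)
    s2 = sum((b**2).sum(axis=0) for b in X_blocks)
    mu = s1 / m
    sd = np.sqrt(np.maximum(s2 / m - mu**2, 0.0))
    sd[sd < 1e-12] = 1.0
    return mu, sd


def mhe_logreg_fit(X_blocks, y_blocks, backend: ShareBackend,
                   epochs: int = 200, lr: float = 1.0,
                   standardize: bool = True) -> RegressionModel:
    """Distributed logistic regression on horizontal partitions.

    The bias-extended data matrix and its transpose are aggregated once,
    before the loop, so the per-epoch work touches only protected
    intermediates (aggregating the weights every epoch would cost one
    aggregation per epoch instead of two in total).
    """
    Xs = [np.asarray(b, dtype=float) for b in X_blocks]
    ys = [np.asarray(b, dtype=float).reshape(-1, 1) for b in y_blocks]
    m = sum(len(b) for b in Xs)
    p = Xs[0].shape[1]
    if standardize:
        mu, sd = _global_moments(Xs)  # revealed aggregate statistics
        Xs = [(b - mu) / sd for b in Xs]
    else:
        mu, sd = np.zeros(p), np.ones(p)
    Xb = _append_bias_local(Xs)
    X_enc = backend.aggregate_rows(Xb)
    Xt_enc = backend.aggregate_cols([b.T for b in Xb])
    y_full = np.vstack(ys)  # each party subtracts its own rows; assembled here
    w = backend.zeros((p + 1, 1))
    for _ in range(epochs):
        A = backend.sigmoid(backend.matmul(X_enc, w))
        g = backend.matmul(Xt_enc, backend.add_plain(A, -y_full))
        w = backend.sub(w, backend.scale(g, lr / m))
    weights = destandardize_weights(backend, w, mu, sd)
    return RegressionModel("logistic", weights, epochs, lr)


def _fit_distributed(kind, spec: FitSpec, X_blocks, y_blocks, backend):
    kwargs = {}
    if spec.epochs is not None:
        kwargs["epochs"] = spec.epochs
    if spec.lr is not None:
        kwargs["lr"] = spec.lr
    if kind == "linear":
        return mhe_linreg_fit(X_blocks, y_blocks, backend, **kwargs)
    return mhe_logreg_fit(X_blocks, y_blocks, backend, **kwargs)


def mhe_mice_analyze(
    X_blocks,
    y_blocks,
    M_blocks,
    column_kinds,
    backend: ShareBackend | None = None,
    imputation_spec: ImputationSpec | None = None,
    final_spec: FitSpec | None = None,
    k: int = 5,
    seed: int | None = None,
    noise_variance: float = 0.01,
    keep_imputed: bool = False,
) -> MICEResult:
    """Multiple imputation and final analysis on horizontally partitioned data.

    Masks stay local: every party filters its own complete rows and receives
    back (only) the imputed entries of its own partition, which it stores in
    the clear like the rest of its data.  The pooled result equals the
    plaintext pooled-data analysis up to backend tolerance.
    """
    backend = backend or ShareBackend()
    imputation_spec = imputation_spec or ImputationSpec()
    final_spec = final_spec or FitSpec("linear")
    X_blocks = [np.asarray(b, dtype=float) for b in X_blocks]
    y_blocks = [np.asarray(b, dtype=float).reshape(-1, 1) for b in y_blocks]
    M_blocks = [np.asarray(b, dtype=int) for b in M_blocks]
    n = X_blocks[0].shape[1]
    child_seeds = np.random.SeedSequence(seed).spawn(k)
    rows = []
    imputed = [] if keep_imputed else None
    for i in range(k):
        rng = np.random.default_rng(child_seeds[i])
        D = [b.copy() for b in X_blocks]
        masks = [b.copy() for b in M_blocks]
        for j in range(n):
            if sum(int(mk[:, j].sum()) for mk in masks) == 0:
                raise AllMissingColumnError(f"column {j} has no observed entries")
        for j in range(n):
            if all(mk[:, j].all() for mk in masks):
                continue
            others = [c for c in range(n) if c != j]
            fit_X, fit_y = [], []
            for Di, mk in zip(D, masks):
                complete = mk.all(axis=1)  # local filtering at each party
                fit_X.append(Di[complete][:, others])
                fit_y.append(Di[complete][:, j : j + 1])
            if sum(len(b) for b in fit_X) == 0:
                raise NoCompleteRowsError(
                    f"no fully observed rows available to impute column {j}"
                )
            kind = "linear" if column_kinds[j] == CONTINUOUS else "logistic"
            model = _fit_distributed(
                kind, imputation_spec.for_kind(column_kinds[j]), fit_X, fit_y, backend
            )
            sizes = [len(b) for b in D]
            eps_full = (
                rng.normal(0.0, np.sqrt(noise_variance), (sum(sizes), 1))
                if column_kinds[j] == CONTINUOUS and noise_variance > 0
                else None
            )
            offset = 0
            for Di, mk in zip(D, masks):
                Xp = np.column_stack([(Di * mk)[:, others], np.ones(len(Di))])
                eta = backend.pc_matmul(Xp, model.weights)
                if column_kinds[j] == BINARY:
                    eta = backend.sigmoid(eta)
                elif eps_full is not None:
                    eta = backend.add_plain(eta, eps_full[offset : offset + len(Di)])
                yhat = backend.decrypt(eta)  # imputed entries return to their owner
                hole = mk[:, j] == 0
                Di[hole, j] = yhat.ravel()[hole]
                mk[:, j] = 1
                offset += len(Di)
        model = _fit_distributed(final_spec.kind, final_spec, D, y_blocks, backend)
        rows.append(model.weights.T)
        if keep_imputed:
            imputed.append([b.copy() for b in D])
    C = rows[0]
    for r in rows[1:]:
        C = backend.concat_rows(C, r)
    return MICEResult(C, rubin_pool(backend, C), imputed)
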