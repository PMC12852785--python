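"""Linear and logistic regression over a plaintext or secret-shared engine.

Both model kinds follow the same training recipe in both arithmetic worlds:

* linear — precompute the Gramian ``C = X~' X~`` and moment vector
  ``R = X~' y`` (``X~`` is the data with a trailing bias column), then either
  solve the normal equations in closed form when ``X~`` has fewer than four
  columns, or run (mini-)batched gradient descent
  ``w <- w + (R - C w) * eta`` on the mean-squared loss;
* logistic — full- or mini-batch gradient descent with the sigmoid replaced
  by its Chebyshev approximant, on features standardized by revealed
  aggregate moments so that ``X~ w`` stays inside the approximation interval
  (weights are mapped back to the raw scale afterwards).

The closed-form path inverts the (at most 3x3) normalized Gramian; under
sharing this uses the adjugate plus a Newton-Raphson reciprocal of the
determinant whose public initial guess comes from a revealed trace bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import fixedpoint as fx
from .fixedpoint import DealerContext, SecretSharedMatrix

__all__ = [
    "RegressionModel",
    "append_bias",
    "linreg_fit",
    "logreg_fit",
    "predict",
    "secure_inverse_small",
    "DivergenceError",
]

#: column-count threshold below which linear regression uses the closed form
CLOSED_FORM_MAX_COLS = 4

#: weight-norm bound of the gradient-descent divergence detector
DIVERGENCE_NORM = 1e6


class DivergenceError(FloatingPointError):
    """Gradient descent left the representable region."""


@dataclass
class RegressionModel:
    """Fitted coefficients (bias last) plus the hyperparameters used."""

    kind: str  # "linear" | "logistic"
    weights: object = None  # (n_features + 1, 1), engine-typed
    epochs: int = 500
    lr: float = 0.1
    batch_size: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "logistic"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")
        if self.lr <= 0:
            raise ValueError("step size must be positive")


def append_bias(engine, X):
    """Append a column of ones as the last column (not idempotent by design)."""
    return engine.concat_cols(X, engine.ones((X.shape[0], 1)))


def _batches(m: int, batch_size: int | None):
    if batch_size is None or batch_size >= m:
        yield slice(0, m)
    else:
        for start in range(0, m, batch_size):
            yield slice(start, min(start + batch_size, m))


def linreg_fit(
    engine,
    X,
    y,
    epochs: int = 500,
    lr: float = 0.1,
    batch_size: int | None = None,
) -> RegressionModel:
    """Fit ``y ~ X`` by normal equations (columns < 4) or gradient descent.

    The gradient step uses row-count-normalized moments (the mean-squared
    loss gradient), so the stable step-size range does not depend on the
    sample size.
    """
    Xb = append_bias(engine, X)
    m, p1 = Xb.shape
    if p1 < CLOSED_FORM_MAX_COLS:
        if m < p1:
            raise ValueError(f"closed form needs at least {p1} rows, got {m}")
        C = engine.scale(engine.matmul(Xb.T, Xb), 1.0 / m)
        R = engine.scale(engine.matmul(Xb.T, y), 1.0 / m)
        w = engine.matmul(engine.inverse_small(C), R)
        return RegressionModel("linear", w, epochs, lr, batch_size)

    w = engine.zeros((p1, 1))
    if batch_size is None:
        C = engine.scale(engine.matmul(Xb.T, Xb), 1.0 / m)
        R = engine.scale(engine.matmul(Xb.T, y), 1.0 / m)
        for _ in range(epochs):
            w = engine.add(w, engine.scale(engine.sub(R, engine.matmul(C, w)), lr))
            if engine.norm_exceeds(w, DIVERGENCE_NORM):
                raise DivergenceError("linear gradient descent diverged")
    else:
        for _ in range(epochs):
            for rows in _batches(m, batch_size):
                Xr, yr = Xb[rows], y[rows]
                mb = Xr.shape[0]
                Cb = engine.scale(engine.matmul(Xr.T, Xr), 1.0 / mb)
                Rb = engine.scale(engine.matmul(Xr.T, yr), 1.0 / mb)
                w = engine.add(w, engine.scale(engine.sub(Rb, engine.matmul(Cb, w)), lr))
            if engine.norm_exceeds(w, DIVERGENCE_NORM):
                raise DivergenceError("linear gradient descent diverged")
    return RegressionModel("linear", w, epochs, lr, batch_size)


def logreg_fit(
    engine,
    X,
    y,
    epochs: int = 200,
    lr: float = 1.0,
    batch_size: int | None = None,
    standardize: bool = True,
) -> RegressionModel:
    """Fit a logistic model by gradient descent with the polynomial sigmoid.

    Standardization moments are aggregate statistics revealed by the secure
    engine (an accepted, documented leakage); the returned weights are on the
    raw feature scale.
    """
    m, p = X.shape
    if standardize:
        mu, var = engine.column_moments(X)
        sd = np.sqrt(np.maximum(var, 0.0))
        sd[sd < 1e-12] = 1.0
        Xs = engine.mul_plain(engine.add_plain(X, -mu.reshape(1, -1)), (1.0 / sd).reshape(1, -1))
    else:
        mu, sd = np.zeros(p), np.ones(p)
        Xs = X
    Xb = append_bias(engine, Xs)
    w = engine.zeros((p + 1, 1))
    for _ in range(epochs):
        for rows in _batches(m, batch_size):
            Xr, yr = Xb[rows], y[rows]
            A = engine.sigmoid(engine.matmul(Xr, w))
            g = engine.matmul(Xr.T, engine.sub(A, yr))
            w = engine.sub(w, engine.scale(g, lr / Xr.shape[0]))
        if engine.norm_exceeds(w, DIVERGENCE_NORM):
            raise DivergenceError("logistic gradient descent diverged")
    weights = destandardize_weights(engine, w, mu, sd)
    return RegressionModel("logistic", weights, epochs, lr, batch_size)


def destandardize_weights(engine, w, mu, sd):
    """Map weights fitted on ``(x - mu) / sd`` back to the raw feature scale."""
    p = len(mu)
    w_feat = engine.mul_plain(w[:p], (1.0 / sd).reshape(-1, 1))
    shift = engine.sum_all(engine.mul_plain(w_feat, mu.reshape(-1, 1)))
    intercept = engine.sub(w[p:], shift)
    return engine.concat_rows(w_feat, intercept)


def predict(engine, model: RegressionModel, X, noise_variance: float = 0.0, rng=None):
    """Model predictions on new rows.

    Linear models return ``X~ w`` plus, when ``noise_variance > 0``, a fresh
    normal draw per entry (drawn in plaintext by the coordinating party and
    added to its share).  Logistic models return probabilities; thresholding
    for binary imputation-quality metrics happens at evaluation time.
    """
    if model.weights is None:
        raise ValueError("model is not fitted")
    Xb = append_bias(engine, X)
    eta = engine.matmul(Xb, model.weights)
    if model.kind == "linear":
        if noise_variance > 0.0:
            rng = rng or np.random.default_rng()
            eps = rng.normal(0.0, np.sqrt(noise_variance), (Xb.shape[0], 1))
            eta = engine.add_plain(eta, eps)
        return eta
    return engine.sigmoid(eta)


# ---------------------------------------------------------------------------
# secure closed-form inversion (dimension <= 3)
# ---------------------------------------------------------------------------

_SUBSETS = {0: (1, 2), 1: (0, 2), 2: (0, 1)}


def _gather(ssm: SecretSharedMatrix, pairs) -> SecretSharedMatrix:
    blocks = [
        np.array([[s[i, j]] for (i, j) in pairs], dtype=object) for s in ssm.shares
    ]
    return SecretSharedMatrix(blocks, ssm.cfg)


def _mul_elem(a, b, ctx):
    (t,) = fx.dealer_issue_triples(ctx, a.shape, b.shape, elementwise=True)
    return fx.smc_mul(a, b, t, ctx)


def secure_inverse_small(
    c: SecretSharedMatrix,
    ctx: DealerContext,
    newton_iters: int = 20,
    trace_precision_bits: int = 16,
) -> SecretSharedMatrix:
    """Invert a shared symmetric positive-definite matrix of dimension <= 3.

    The adjugate is polynomial in the entries and computed with elementwise
    Beaver products.  The determinant reciprocal comes from Newton-Raphson
    ``r <- r (2 - d r)`` seeded with the public value ``2 / B`` where
    ``B = 2 (tr/d)^d`` upper-bounds the determinant (AM-GM); only the trace,
    rounded up to ``trace_precision_bits`` fractional bits, is revealed.
    """
    d, d2 = c.shape
    if d != d2:
        raise ValueError("matrix must be square")
    if d > 3:
        raise ValueError("secure closed-form inversion is limited to 3x3")
    cfg = c.cfg
    mod = cfg.modulus

    tr_shares = SecretSharedMatrix(
        [np.array([[int(np.trace(s)) % mod]], dtype=object) for s in c.shares], cfg
    )
    tr = float(fx.fp_decode(fx.open_shares(tr_shares, ctx), cfg)[0, 0])
    grid = 1 << trace_precision_bits
    tr = np.ceil(tr * grid) / grid  # round up: keeps the AM-GM bound valid
    if tr <= 0:
        raise ValueError("non-positive revealed trace bound")
    trace_bound = 2.0 * (tr / d) ** d
    r0 = 2.0 / trace_bound

    if d == 1:
        adj = fx.share_public(fx.fp_encode(np.ones((1, 1)), cfg), ctx)
        det = c
    elif d == 2:
        u = _gather(c, [(0, 0), (0, 1)])
        v = _gather(c, [(1, 1), (1, 0)])
        prod = _mul_elem(u, v, ctx)
        det = fx.smc_sub(prod[0:1], prod[1:2])
        blocks = []
        for s in c.shares:
            blocks.append(
                np.array(
                    [[s[1, 1], (-s[0, 1]) % mod], [(-s[1, 0]) % mod, s[0, 0]]],
                    dtype=object,
                )
            )
        adj = SecretSharedMatrix(blocks, cfg)
    else:
        left, right, signs, spots = [], [], [], []
        for i in range(3):
            r1, r2 = _SUBSETS[i]
            for j in range(3):
                c1, c2 = _SUBSETS[j]
                left.extend([(r1, c1), (r1, c2)])
                right.extend([(r2, c2), (r2, c1)])
                signs.append(1 if (i + j) % 2 == 0 else -1)
                spots.append((j, i))  # adjugate is the transposed cofactor matrix
        prods = _mul_elem(_gather(c, left), _gather(c, right), ctx)
        minors = fx.smc_sub(prods[0::2], prods[1::2])  # (9, 1)
        blocks = [np.zeros((3, 3), dtype=object) for _ in range(c.party_count)]
        for k, (aj, ai) in enumerate(spots):
            for p_idx in range(c.party_count):
                blocks[p_idx][aj, ai] = (signs[k] * minors.shares[p_idx][k, 0]) % mod
        adj = SecretSharedMatrix(blocks, cfg)
        row = _gather(c, [(0, k) for k in range(3)])
        col = _gather(adj, [(k, 0) for k in range(3)])
        terms = _mul_elem(row, col, ctx)
        det = SecretSharedMatrix(
            [np.array([[int(s.sum()) % mod]], dtype=object) for s in terms.shares], cfg
        )

    # Newton-Raphson reciprocal of the shared determinant
    x = fx.smc_scale_public(det, r0)
    t = fx.smc_add_public(fx.smc_neg(x), 2.0)
    r = fx.smc_scale_public(t, r0)
    for _ in range(newton_iters - 1):
        x = _mul_elem(det, r, ctx)
        t = fx.smc_add_public(fx.smc_neg(x), 2.0)
        r = _mul_elem(r, t, ctx)

    r_mat = SecretSharedMatrix(
        [np.broadcast_to(s, (d, d)).copy() for s in r.shares], cfg
    )
    return _mul_elem(adj, r_mat, ctx)
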