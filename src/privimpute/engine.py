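"""Plaintext / secure arithmetic engines with a common surface.

The imputation and regression code is written once against this interface.
``PlainEngine`` executes it in float64 and is the reference pipeline;
``SecureEngine`` executes the identical sequence of operations on additive
secret shares, so any divergence between the two is attributable to the
cryptographic layer (fixed-point quantization, probabilistic truncation,
polynomial sigmoid) rather than to algorithmic differences.

By default both engines use the same Chebyshev sigmoid, keeping the plaintext
reference the oracle for the share arithmetic alone; the exact logistic
function is available via ``PlainEngine(exact_sigmoid=True)``.
"""

from __future__ import annotations

import numpy as np

from . import chebyshev as _cheb
from . import fixedpoint as fx

__all__ = ["PlainEngine", "SecureEngine"]


class PlainEngine:
    """Reference engine: numpy float64, no sharing."""

    kind = "plaintext"

    def __init__(self, sigmoid_approx=None, exact_sigmoid: bool = False):
        self.sigmoid_approx = sigmoid_approx or _cheb.default_sigmoid_approx()
        self.exact_sigmoid = exact_sigmoid

    def lift(self, arr):
        return np.array(arr, dtype=float)

    lift_public = lift

    def reveal(self, x):
        return np.asarray(x, dtype=float)

    def matmul(self, a, b):
        return a @ b

    def mul_elem(self, a, b):
        return a * b

    def add(self, a, b):
        return a + b

    def sub(self, a, b):
        return a - b

    def neg(self, a):
        return -a

    def scale(self, a, c):
        return a * float(c)

    def add_plain(self, a, v):
        return a + np.asarray(v, dtype=float)

    def mul_plain(self, a, v):
        return a * np.asarray(v, dtype=float)

    mul_mask = mul_plain

    def sigmoid(self, a):
        if self.exact_sigmoid:
            return _cheb.sigmoid(a)
        return _cheb.eval_plain(self.sigmoid_approx, a)

    def inverse_small(self, c):
        if c.shape[0] > 3:
            raise ValueError("closed-form inversion is limited to 3x3 systems")
        try:
            return np.linalg.inv(c)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(f"singular Gramian: {err}") from err

    def column_moments(self, x):
        arr = np.asarray(x, dtype=float)
        return arr.mean(axis=0), arr.var(axis=0)

    def concat_cols(self, a, b):
        return np.concatenate([a, b], axis=1)

    def concat_rows(self, a, b):
        return np.concatenate([a, b], axis=0)

    def sum_all(self, a):
        return np.sum(a, keepdims=True).reshape(1, 1)

    def col_sums(self, a):
        return np.sum(a, axis=0, keepdims=True)

    def zeros(self, shape):
        return np.zeros(shape)

    def ones(self, shape):
        return np.ones(shape)

    def set_col(self, a, j, col):
        a[:, j : j + 1] = col

    def rows(self, a, idx):
        return a[idx]

    def norm_exceeds(self, w, bound: float) -> bool:
        return bool(np.linalg.norm(np.asarray(w, dtype=float)) > bound)


class SecureEngine:
    """Secret-sharing engine: values are :class:`~privimpute.fixedpoint.SecretSharedMatrix`."""

    kind = "secure"

    def __init__(self, ctx: fx.DealerContext | None = None, sigmoid_approx=None):
        self.ctx = ctx or fx.DealerContext()
        self.cfg = self.ctx.cfg
        self.sigmoid_approx = sigmoid_approx or _cheb.default_sigmoid_approx()

    def lift(self, arr):
        return fx.share(fx.fp_encode(np.atleast_2d(np.asarray(arr, dtype=float)), self.cfg), self.ctx)

    def lift_public(self, arr):
        # public constants are also shared with fresh randomness: the
        # probabilistic-truncation wrap argument needs uniform shares
        return fx.share(
            fx.fp_encode(np.atleast_2d(np.asarray(arr, dtype=float)), self.cfg), self.ctx
        )

    def reveal(self, x):
        return fx.fp_decode(fx.open_shares(x, self.ctx), self.cfg)

    def matmul(self, a, b):
        (triple,) = fx.dealer_issue_triples(self.ctx, a.shape, b.shape)
        return fx.smc_mul(a, b, triple, self.ctx)

    def mul_elem(self, a, b):
        (triple,) = fx.dealer_issue_triples(self.ctx, a.shape, b.shape, elementwise=True)
        return fx.smc_mul(a, b, triple, self.ctx)

    def add(self, a, b):
        return fx.smc_add(a, b)

    def sub(self, a, b):
        return fx.smc_sub(a, b)

    def neg(self, a):
        return fx.smc_neg(a)

    def scale(self, a, c):
        return fx.smc_scale_public(a, c)

    def add_plain(self, a, v):
        return fx.smc_add_public(a, v)

    def mul_plain(self, a, v):
        """Elementwise product with a public real array (encode + truncate)."""
        enc = np.broadcast_to(
            np.asarray(fx.fp_encode(np.asarray(v, dtype=float), self.cfg), dtype=object),
            a.shape,
        )
        mod = self.cfg.modulus
        doubled = fx.SecretSharedMatrix([(s * enc) % mod for s in a.shares], self.cfg)
        return fx.smc_truncate(doubled, self.cfg.frac_bits)

    def mul_mask(self, a, mask):
        """Exact elementwise product with a public 0/1 integer mask (no truncation)."""
        m = np.broadcast_to(np.asarray(mask, dtype=object), a.shape)
        mod = self.cfg.modulus
        return fx.SecretSharedMatrix([(s * m) % mod for s in a.shares], self.cfg)

    def sigmoid(self, a):
        return _cheb.eval_secure(self.sigmoid_approx, a, self.ctx)

    def inverse_small(self, c):
        from .regression import secure_inverse_small

        return secure_inverse_small(c, self.ctx)

    def column_moments(self, x):
        """Column means/variances revealed as public aggregate statistics."""
        m = x.shape[0]
        ones_row = np.ones((1, m), dtype=object)
        mod = self.cfg.modulus
        sums = fx.SecretSharedMatrix([(ones_row @ s) % mod for s in x.shares], self.cfg)
        sq = self.mul_elem(x, x)
        sumsq = fx.SecretSharedMatrix([(ones_row @ s) % mod for s in sq.shares], self.cfg)
        mu = fx.fp_decode(fx.open_shares(sums, self.ctx), self.cfg)[0] / m
        ex2 = fx.fp_decode(fx.open_shares(sumsq, self.ctx), self.cfg)[0] / m
        return mu, np.maximum(ex2 - mu**2, 0.0)

    def concat_cols(self, a, b):
        return fx.SecretSharedMatrix(
            [np.concatenate([x, y], axis=1) for x, y in zip(a.shares, b.shares)], self.cfg
        )

    def concat_rows(self, a, b):
        return fx.SecretSharedMatrix(
            [np.concatenate([x, y], axis=0) for x, y in zip(a.shares, b.shares)], self.cfg
        )

    def sum_all(self, a):
        mod = self.cfg.modulus
        return fx.SecretSharedMatrix(
            [np.array([[int(s.sum()) % mod]], dtype=object) for s in a.shares], self.cfg
        )

    def col_sums(self, a):
        mod = self.cfg.modulus
        return fx.SecretSharedMatrix(
            [s.sum(axis=0, keepdims=True) % mod for s in a.shares], self.cfg
        )

    def zeros(self, shape):
        # shared with fresh randomness (see lift_public)
        return fx.share(np.zeros(shape, dtype=object), self.ctx)

    def ones(self, shape):
        return self.lift_public(np.ones(shape))

    def set_col(self, a, j, col):
        for mine, theirs in zip(a.shares, col.shares):
            mine[:, j : j + 1] = theirs

    def rows(self, a, idx):
        return a[idx]

    def norm_exceeds(self, w, bound: float) -> bool:
        # a norm check would reveal the shared weights; divergence is caught
        # at decode time instead
        return False
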