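"""Chebyshev interpolation of the logistic sigmoid (and natural log).

Secure protocols can only add and multiply, so nonlinear scalar functions
are replaced by polynomial interpolants fitted at Chebyshev nodes.  The
default sigmoid approximant is degree 11 on [-8, 8], the smallest degree
whose uniform error is below 1e-2 (about 6e-3), at a modest multiplication
depth; a log approximant on
[0.01, 1] is provided for cross-entropy reporting.

Secure evaluation runs the Clenshaw recurrence on secret shares after an
affine change of variable onto [-1, 1].  There is no secure comparison, so
inputs cannot be clipped under sharing: outside the fitted interval the
polynomial is unbounded and callers must range-control their inputs
(plaintext evaluation does clip, which is the documented contract
difference between the two paths).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.polynomial import chebyshev as _cheb

from .fixedpoint import (
    DealerContext,
    SecretSharedMatrix,
    dealer_issue_triples,
    smc_add,
    smc_add_public,
    smc_mul,
    smc_scale_public,
    smc_sub,
)

__all__ = ["ChebyshevApprox", "fit_chebyshev", "eval_plain", "eval_secure", "sigmoid"]


def sigmoid(x):
    """Numerically stable logistic function 1 / (1 + exp(-x))."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


_TARGETS = {"sigmoid": sigmoid, "log": np.log}


@dataclass(frozen=True)
class ChebyshevApprox:
    """Chebyshev-basis coefficients approximating ``target`` on ``interval``."""

    target: str
    interval: tuple[float, float]
    degree: int
    coefficients: tuple[float, ...]  # Chebyshev basis on the mapped [-1, 1]
    basis: str = "chebyshev"

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.degree + 1:
            raise ValueError("degree must equal len(coefficients) - 1")
        lo, hi = self.interval
        if not lo < hi:
            raise ValueError("interval must be non-degenerate")


def fit_chebyshev(target, interval, degree: int) -> ChebyshevApprox:
    """Interpolate ``target`` at the ``degree + 1`` Chebyshev nodes of ``interval``.

    ``target`` is one of ``"sigmoid"``/``"log"`` or any callable finite on the
    interval.  The fit is deterministic (no least squares, exact interpolation
    at the nodes), so a degree-``d`` polynomial is reproduced exactly.
    """
    lo, hi = float(interval[0]), float(interval[1])
    if isinstance(target, str):
        name = target
        func = _TARGETS[target]
    else:
        name, func = getattr(target, "__name__", "custom"), target
    if name == "log" and lo <= 0:
        raise ValueError("log requires a strictly positive interval")
    poly = _cheb.Chebyshev.interpolate(func, degree, domain=[lo, hi])
    return ChebyshevApprox(name, (lo, hi), degree, tuple(float(c) for c in poly.coef))


@lru_cache(maxsize=None)
def default_sigmoid_approx(degree: int = 11, lo: float = -8.0, hi: float = 8.0) -> ChebyshevApprox:
    return fit_chebyshev("sigmoid", (lo, hi), degree)


@lru_cache(maxsize=None)
def default_log_approx(degree: int = 9, lo: float = 0.01, hi: float = 1.0) -> ChebyshevApprox:
    return fit_chebyshev("log", (lo, hi), degree)


def eval_plain(approx: ChebyshevApprox, x):
    """Clenshaw evaluation; inputs outside the interval clip to its endpoints."""
    lo, hi = approx.interval
    t = np.clip(np.asarray(x, dtype=float), lo, hi)
    u = (2.0 * t - (lo + hi)) / (hi - lo)
    val = _cheb.chebval(u, np.asarray(approx.coefficients))
    return val if np.asarray(x).ndim else float(val)


def eval_secure(
    approx: ChebyshevApprox,
    s: SecretSharedMatrix,
    ctx: DealerContext,
    triples: list | None = None,
) -> SecretSharedMatrix:
    """Clenshaw recurrence on secret shares.

    Consumes ``approx.degree`` elementwise Beaver triples of the input's
    shape (drawn from the dealer unless supplied).  No clipping is possible
    on shares; see the module docstring.
    """
    lo, hi = approx.interval
    coef = approx.coefficients
    deg = approx.degree
    if triples is None:
        triples = dealer_issue_triples(ctx, s.shape, count=deg, elementwise=True)
    if len(triples) < deg:
        raise ValueError(f"need {deg} elementwise triples, got {len(triples)}")
    # affine map onto [-1, 1]: u = (2x - (lo + hi)) / (hi - lo)
    u = smc_add_public(smc_scale_public(s, 2.0 / (hi - lo)), -(lo + hi) / (hi - lo))
    two_u = smc_scale_public(u, 2)
    it = iter(triples)
    b1 = b2 = None  # b_{k+1}, b_{k+2}; None encodes an exact zero
    for k in range(deg, 0, -1):
        if b1 is None:
            b = smc_add_public(smc_scale_public(s, 0), coef[k])  # shared constant
        else:
            b = smc_add_public(smc_mul(two_u, b1, next(it), ctx), coef[k])
            if b2 is not None:
                b = smc_sub(b, b2)
        b1, b2 = b, b1
    out = smc_add_public(smc_mul(u, b1, next(it), ctx), coef[0])
    if b2 is not None:
        out = smc_sub(out, b2)
    return out
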