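"""Fixed-point arithmetic over Z_{2^k} with additive secret sharing.

Real numbers are encoded as scaled integers (``round(x * 2^frac_bits)``)
embedded two's-complement-style in the ring ``Z_{2^total_bits}``.  A secret is
split into additive shares, one per computing party; a trusted dealer hands
out Beaver triples that enable secure multiplication.  All parties are
honest-but-curious: they follow the protocol but may inspect every message
they receive, so the only values ever opened are Beaver-masked differences.

Parties are simulated in-process: a :class:`SecretSharedMatrix` holds one
share array per party, and every protocol step manipulates only the share it
conceptually owns.  Steps that would require network traffic in a real
deployment go through :func:`open_shares`, which is accounted for (and can be
forbidden) via the :class:`DealerContext` protocol log.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FixedPointConfig",
    "SecretSharedMatrix",
    "BeaverTriple",
    "DealerContext",
    "ProtocolLog",
    "CommunicationForbidden",
    "TripleReuseError",
    "fp_encode",
    "fp_decode",
    "share",
    "reconstruct",
    "open_shares",
    "smc_add",
    "smc_sub",
    "smc_neg",
    "smc_scale_public",
    "smc_add_public",
    "smc_mul",
    "smc_truncate",
    "dealer_issue_triples",
]


class CommunicationForbidden(RuntimeError):
    """Raised when a protocol step needs network traffic under a no-traffic stub."""


class TripleReuseError(RuntimeError):
    """Raised when a Beaver triple is consumed twice."""


@dataclass(frozen=True)
class FixedPointConfig:
    """Ring and fixed-point layout.

    Defaults: 192-bit ring with 32 fractional bits, 64 bits for a whole
    fixed-point value and 64 bits of padding as the statistical-security
    margin of probabilistic truncation.
    """

    total_bits: int = 192
    frac_bits: int = 32
    value_bits: int = 64
    padding_bits: int = 64

    def __post_init__(self) -> None:
        if not self.frac_bits < self.value_bits:
            raise ValueError("frac_bits must be smaller than value_bits")
        if self.value_bits + self.padding_bits > self.total_bits:
            raise ValueError("value_bits + padding_bits must fit in total_bits")

    @property
    def modulus(self) -> int:
        return 1 << self.total_bits

    @property
    def scale(self) -> int:
        return 1 << self.frac_bits

    @property
    def max_magnitude(self) -> float:
        """Largest representable magnitude, ``2^(value_bits - frac_bits - 1)``."""
        return float(1 << (self.value_bits - self.frac_bits - 1))


DEFAULT_CONFIG = FixedPointConfig()

_to_ring = np.frompyfunc(int, 1, 1)


def fp_encode(x, cfg: FixedPointConfig = DEFAULT_CONFIG):
    """Encode reals as ring elements, negatives as ``modulus - |q|``.

    Raises ``OverflowError`` if any magnitude exceeds the representable range.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(np.abs(arr) >= cfg.max_magnitude):
        raise OverflowError(
            f"magnitude {np.max(np.abs(arr))} exceeds fixed-point range "
            f"(< {cfg.max_magnitude})"
        )
    q = np.rint(arr * cfg.scale)
    enc = _to_ring(np.atleast_1d(q).astype(object)) % cfg.modulus
    return enc.reshape(arr.shape) if arr.ndim else enc[0]


def fp_decode(e, cfg: FixedPointConfig = DEFAULT_CONFIG, frac_bits: int | None = None):
    """Decode ring elements back to floats; elements above modulus/2 are negative."""
    scale = 1 << (cfg.frac_bits if frac_bits is None else frac_bits)
    arr = np.atleast_1d(np.asarray(e, dtype=object))
    half = cfg.modulus >> 1
    signed = np.where(arr > half, arr - cfg.modulus, arr)
    out = np.asarray(signed / scale, dtype=float)
    ndim = np.asarray(e).ndim
    return out.reshape(np.asarray(e).shape) if ndim else float(out[0])


@dataclass
class ProtocolLog:
    """Counts of protocol events, for cost accounting and no-traffic stubs."""

    messages: int = 0
    opens: int = 0
    triples_issued: dict = field(default_factory=dict)

    def record_open(self, party_count: int) -> None:
        self.opens += 1
        # every party broadcasts its share of the opened value
        self.messages += party_count * (party_count - 1)

    def record_triples(self, key, count: int) -> None:
        self.triples_issued[key] = self.triples_issued.get(key, 0) + count


@dataclass
class DealerContext:
    """Trusted dealer plus per-party randomness.

    The dealer draws correlated randomness (shares, Beaver triples) but never
    touches a data share.  A run is reproducible from ``(seed, party_count)``.
    """

    seed: int = 0
    party_count: int = 2
    cfg: FixedPointConfig = field(default_factory=FixedPointConfig)
    forbid_communication: bool = False
    log: ProtocolLog = field(default_factory=ProtocolLog)

    def __post_init__(self) -> None:
        if self.party_count < 2:
            raise ValueError("need at least two computing parties")
        self._rng = random.Random(f"dealer:{self.seed}")

    def random_ring_matrix(self, shape) -> np.ndarray:
        bits = self.cfg.total_bits
        rng = self._rng
        flat = [rng.getrandbits(bits) for _ in range(int(np.prod(shape)))]
        return np.array(flat, dtype=object).reshape(shape)


class SecretSharedMatrix:
    """Additive shares of a fixed-point-encoded matrix, one block per party."""

    __slots__ = ("shares", "cfg")

    def __init__(self, shares: list[np.ndarray], cfg: FixedPointConfig):
        shapes = {s.shape for s in shares}
        if len(shapes) != 1:
            raise ValueError(f"party shares differ in shape: {shapes}")
        self.shares = shares
        self.cfg = cfg

    @property
    def shape(self):
        return self.shares[0].shape

    @property
    def party_count(self) -> int:
        return len(self.shares)

    # public (mask-driven) structural ops are local and communication-free
    def __getitem__(self, idx) -> "SecretSharedMatrix":
        return SecretSharedMatrix([np.asarray(s[idx]) for s in self.shares], self.cfg)

    @property
    def T(self) -> "SecretSharedMatrix":
        return SecretSharedMatrix([s.T for s in self.shares], self.cfg)

    def reshape(self, *shape) -> "SecretSharedMatrix":
        return SecretSharedMatrix([s.reshape(*shape) for s in self.shares], self.cfg)

    def copy(self) -> "SecretSharedMatrix":
        return SecretSharedMatrix([s.copy() for s in self.shares], self.cfg)

    def set_rows_cols(self, idx, value: "SecretSharedMatrix") -> None:
        for mine, theirs in zip(self.shares, value.shares):
            mine[idx] = theirs


def share(encoded, ctx: DealerContext) -> SecretSharedMatrix:
    """Split an encoded matrix into ``party_count`` additive shares.

    The first ``P-1`` shares are uniform over the ring; the last is the
    modular difference, so single shares carry no information about the secret.
    """
    enc = np.asarray(encoded, dtype=object)
    mod = ctx.cfg.modulus
    blocks = [ctx.random_ring_matrix(enc.shape) for _ in range(ctx.party_count - 1)]
    last = (enc - sum(blocks)) % mod
    blocks.append(last)
    return SecretSharedMatrix(blocks, ctx.cfg)


def share_public(encoded, ctx: DealerContext) -> SecretSharedMatrix:
    """Deterministic sharing of a public constant (party 0 holds it in full)."""
    enc = np.asarray(encoded, dtype=object) % ctx.cfg.modulus
    zeros = np.zeros(enc.shape, dtype=object)
    return SecretSharedMatrix(
        [enc.copy()] + [zeros.copy() for _ in range(ctx.party_count - 1)], ctx.cfg
    )


def reconstruct(s: SecretSharedMatrix) -> np.ndarray:
    """Element-wise modular sum of all party shares (exact at ring level)."""
    total = s.shares[0]
    for blk in s.shares[1:]:
        if blk.shape != total.shape:
            raise ValueError("share shape mismatch")
        total = total + blk
    return total % s.cfg.modulus


def open_shares(s: SecretSharedMatrix, ctx: DealerContext) -> np.ndarray:
    """Reveal a shared value to all parties (a communication round)."""
    if ctx.forbid_communication:
        raise CommunicationForbidden("open() attempted under a no-traffic stub")
    ctx.log.record_open(s.party_count)
    return reconstruct(s)


def _check_conformable(s: SecretSharedMatrix, t: SecretSharedMatrix) -> None:
    if s.shape != t.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {t.shape}")


def smc_add(s: SecretSharedMatrix, t: SecretSharedMatrix) -> SecretSharedMatrix:
    _check_conformable(s, t)
    mod = s.cfg.modulus
    return SecretSharedMatrix([(a + b) % mod for a, b in zip(s.shares, t.shares)], s.cfg)


def smc_sub(s: SecretSharedMatrix, t: SecretSharedMatrix) -> SecretSharedMatrix:
    _check_conformable(s, t)
    mod = s.cfg.modulus
    return SecretSharedMatrix([(a - b) % mod for a, b in zip(s.shares, t.shares)], s.cfg)


def smc_neg(s: SecretSharedMatrix) -> SecretSharedMatrix:
    mod = s.cfg.modulus
    return SecretSharedMatrix([(-a) % mod for a in s.shares], s.cfg)


def smc_add_public(s: SecretSharedMatrix, x) -> SecretSharedMatrix:
    """Add a public constant; applied by the designated first party only."""
    enc = np.asarray(fp_encode(x, s.cfg), dtype=object)
    enc = np.broadcast_to(enc, s.shape)
    mod = s.cfg.modulus
    blocks = [(s.shares[0] + enc) % mod] + [b.copy() for b in s.shares[1:]]
    return SecretSharedMatrix(blocks, s.cfg)


def smc_scale_public(s: SecretSharedMatrix, scalar) -> SecretSharedMatrix:
    """Multiply by a public scalar, locally at every party.

    Integer scalars are exact; real scalars go through fixed-point encoding
    followed by probabilistic truncation to restore the scale.
    """
    mod = s.cfg.modulus
    if isinstance(scalar, (int, np.integer)):
        c = int(scalar) % mod
        return SecretSharedMatrix([(b * c) % mod for b in s.shares], s.cfg)
    c = int(fp_encode(float(scalar), s.cfg))
    doubled = SecretSharedMatrix([(b * c) % mod for b in s.shares], s.cfg)
    return smc_truncate(doubled, s.cfg.frac_bits)


def smc_truncate(s: SecretSharedMatrix, bits: int) -> SecretSharedMatrix:
    """Probabilistic truncation: divide the shared value by ``2^bits``.

    Two-party local protocol: the first party shifts its share down, the
    second applies the complement trick.  The decoded result is within one
    unit-in-the-last-place of the exact division, except with probability
    about ``2^-padding_bits`` (a share-wrap event for in-range secrets).
    """
    if s.party_count != 2:
        raise NotImplementedError(
            "probabilistic truncation is a two-computing-party protocol; "
            f"got {s.party_count} parties"
        )
    if bits == 0:
        return s.copy()
    mod = s.cfg.modulus
    first = s.shares[0] >> bits
    second = (mod - ((mod - s.shares[1]) >> bits)) % mod
    return SecretSharedMatrix([first, second], s.cfg)


@dataclass
class BeaverTriple:
    """Shares of ``(a, b, c)`` with ``c = a x b`` exactly in the ring."""

    a: SecretSharedMatrix
    b: SecretSharedMatrix
    c: SecretSharedMatrix
    elementwise: bool = False
    _used: bool = field(default=False, repr=False)

    def consume(self) -> None:
        if self._used:
            raise TripleReuseError("Beaver triple reused; triples are single-use")
        self._used = True


def dealer_issue_triples(
    ctx: DealerContext,
    shape_a,
    shape_b=None,
    count: int = 1,
    elementwise: bool = False,
) -> list[BeaverTriple]:
    """Dealer-side batch generation of Beaver triples.

    Matrix triples (``c = a @ b``) cover one whole matrix product each, which
    keeps the number of opened values (and rounds) at two per product and
    makes triple caching straightforward.
    """
    shape_a = tuple(shape_a)
    shape_b = shape_a if shape_b is None else tuple(shape_b)
    if elementwise:
        if shape_a != shape_b:
            raise ValueError("elementwise triples need identical shapes")
    elif shape_a[-1] != shape_b[0]:
        raise ValueError(f"inner dimensions differ: {shape_a} x {shape_b}")
    mod = ctx.cfg.modulus
    out = []
    for _ in range(count):
        a = ctx.random_ring_matrix(shape_a)
        b = ctx.random_ring_matrix(shape_b)
        c = (a * b) % mod if elementwise else (a @ b) % mod
        out.append(
            BeaverTriple(share(a, ctx), share(b, ctx), share(c, ctx), elementwise)
        )
    ctx.log.record_triples((shape_a, shape_b, elementwise), count)
    return out


def smc_mul(
    s: SecretSharedMatrix,
    t: SecretSharedMatrix,
    triple: BeaverTriple,
    ctx: DealerContext,
    truncate: bool = True,
) -> SecretSharedMatrix:
    """Beaver multiplication (matrix or elementwise per the triple's kind).

    Opens ``s - a`` and ``t - b`` (uniformly masked, hence safe), combines
    ``c + E.b + a.F + E.F``, then re-truncates by ``frac_bits`` so the
    fixed-point scale of the product matches its operands.
    """
    triple.consume()
    if triple.a.shape != s.shape or triple.b.shape != t.shape:
        raise ValueError("triple shape does not match operands")
    mod = s.cfg.modulus
    E = open_shares(smc_sub(s, triple.a), ctx)
    F = open_shares(smc_sub(t, triple.b), ctx)
    blocks = []
    for i in range(s.party_count):
        if triple.elementwise:
            z = triple.c.shares[i] + E * triple.b.shares[i] + triple.a.shares[i] * F
            if i == 0:
                z = z + E * F
        else:
            z = triple.c.shares[i] + E @ triple.b.shares[i] + triple.a.shares[i] @ F
            if i == 0:
                z = z + E @ F
        blocks.append(z % mod)
    prod = SecretSharedMatrix(blocks, s.cfg)
    return smc_truncate(prod, s.cfg.frac_bits) if truncate else prod
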