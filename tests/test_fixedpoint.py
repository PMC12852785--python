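"""Ring encoding, sharing, Beaver multiplication and truncation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from privimpute import fixedpoint as fx

CFG = fx.FixedPointConfig()


class TestEncoding:
    def test_zero_and_unit_scaling(self):
        assert fx.fp_encode(0.0, CFG) == 0
        assert fx.fp_encode(1.0, CFG) == 1 << 32
        assert fx.fp_decode(1 << 32, CFG) == 1.0
        assert fx.fp_decode(CFG.modulus - (1 << 32), CFG) == -1.0

    def test_pi_round_trip(self):
        assert abs(fx.fp_decode(fx.fp_encode(np.pi, CFG), CFG) - np.pi) <= 2**-32

    @given(st.floats(min_value=-100, max_value=100, allow_nan=False))
    def test_round_trip_property(self, x):
        assert abs(fx.fp_decode(fx.fp_encode(x, CFG), CFG) - x) <= 2**-32

    def test_round_trip_bulk(self, rng):
        x = rng.uniform(-100, 100, (100, 100))
        back = fx.fp_decode(fx.fp_encode(x, CFG), CFG)
        assert np.max(np.abs(back - x)) <= 2**-32

    def test_overflow_raises(self):
        with pytest.raises(OverflowError):
            fx.fp_encode(2.0 ** (CFG.value_bits - CFG.frac_bits), CFG)

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            fx.FixedPointConfig(frac_bits=64, value_bits=64)
        with pytest.raises(ValueError):
            fx.FixedPointConfig(value_bits=150, padding_bits=64)


class TestSharing:
    def test_share_reconstruct_exact(self, ctx, rng):
        for _ in range(50):
            m = fx.fp_encode(rng.uniform(-50, 50, (4, 3)), ctx.cfg)
            assert np.array_equal(fx.reconstruct(fx.share(m, ctx)), m)

    def test_linearity_of_shares(self, ctx, rng):
        a = fx.fp_encode(rng.uniform(-5, 5, (3, 3)), ctx.cfg)
        b = fx.fp_encode(rng.uniform(-5, 5, (3, 3)), ctx.cfg)
        s = fx.smc_add(fx.share(a, ctx), fx.share(b, ctx))
        assert np.array_equal(fx.reconstruct(s), (a + b) % ctx.cfg.modulus)

    def test_share_of_zero_is_masked(self, ctx):
        s = fx.share(np.zeros((5, 5), dtype=object), ctx)
        assert np.all(s.shares[0] != 0)

    def test_share_low_bits_uniform(self, ctx):
        # the same secret shared 10^4 times: a single party's share should be
        # indistinguishable from uniform (low 16 bits, chi-squared on 64 bins)
        secret = fx.fp_encode(np.array([[3.75]]), ctx.cfg)
        low = [int(fx.share(secret, ctx).shares[0][0, 0]) & 0xFFFF for _ in range(10_000)]
        counts = np.bincount(np.asarray(low) >> 10, minlength=64)
        assert stats.chisquare(counts).pvalue > 0.001

    def test_multiparty_sharing(self):
        ctx = fx.DealerContext(seed=3, party_count=4)
        m = fx.fp_encode(np.full((2, 2), 1.5), ctx.cfg)
        s = fx.share(m, ctx)
        assert s.party_count == 4
        assert np.array_equal(fx.reconstruct(s), m)


class TestLocalOps:
    def test_add_sub_scale_need_no_communication(self, rng):
        ctx = fx.DealerContext(seed=5, forbid_communication=True)
        a = fx.share(fx.fp_encode(rng.uniform(-5, 5, (4, 4)), ctx.cfg), ctx)
        b = fx.share(fx.fp_encode(rng.uniform(-5, 5, (4, 4)), ctx.cfg), ctx)
        fx.smc_add(a, b)
        fx.smc_sub(a, b)
        fx.smc_scale_public(a, 3)
        fx.smc_scale_public(a, 0.5)
        fx.smc_add_public(a, 1.25)  # no open() raised CommunicationForbidden

    def test_open_is_communication(self, rng):
        ctx = fx.DealerContext(seed=5, forbid_communication=True)
        a = fx.share(fx.fp_encode(np.ones((2, 2)), ctx.cfg), ctx)
        with pytest.raises(fx.CommunicationForbidden):
            fx.open_shares(a, ctx)

    def test_add_decodes_correctly(self, ctx):
        a = fx.share(fx.fp_encode(np.array([[2.0]]), ctx.cfg), ctx)
        b = fx.share(fx.fp_encode(np.array([[3.0]]), ctx.cfg), ctx)
        assert fx.fp_decode(fx.reconstruct(fx.smc_add(a, b)), ctx.cfg)[0, 0] == 5.0

    def test_self_subtraction_is_exact_zero(self, ctx):
        a = fx.share(fx.fp_encode(np.array([[1.23]]), ctx.cfg), ctx)
        assert fx.reconstruct(fx.smc_sub(a, a))[0, 0] == 0

    def test_power_of_two_scaling_is_exact(self, ctx):
        a = fx.share(fx.fp_encode(np.array([[1.0 / 3.0]]), ctx.cfg), ctx)
        scaled = fx.fp_decode(fx.reconstruct(fx.smc_scale_public(a, 8)), ctx.cfg)
        base = fx.fp_decode(fx.reconstruct(a), ctx.cfg)
        assert scaled[0, 0] == 8 * base[0, 0]  # integer scaling adds no error

    def test_shape_mismatch_raises(self, ctx):
        a = fx.share(np.zeros((2, 2), dtype=object), ctx)
        b = fx.share(np.zeros((3, 2), dtype=object), ctx)
        with pytest.raises(ValueError):
            fx.smc_add(a, b)


class TestBeaver:
    def test_scalar_product(self, ctx):
        a = fx.share(fx.fp_encode(np.array([[2.0]]), ctx.cfg), ctx)
        b = fx.share(fx.fp_encode(np.array([[3.0]]), ctx.cfg), ctx)
        (t,) = fx.dealer_issue_triples(ctx, (1, 1), (1, 1))
        out = fx.fp_decode(fx.reconstruct(fx.smc_mul(a, b, t, ctx)), ctx.cfg)
        assert abs(out[0, 0] - 6.0) <= 2**-30

    def test_product_with_zero(self, ctx, rng):
        a = fx.share(fx.fp_encode(rng.uniform(-5, 5, (3, 3)), ctx.cfg), ctx)
        z = fx.share(fx.fp_encode(np.zeros((3, 3)), ctx.cfg), ctx)
        (t,) = fx.dealer_issue_triples(ctx, (3, 3), (3, 3))
        out = fx.fp_decode(fx.reconstruct(fx.smc_mul(a, z, t, ctx)), ctx.cfg)
        assert np.max(np.abs(out)) <= 2**-30

    def test_matrix_products_match_plaintext(self, ctx, rng):
        worst = 0.0
        for _ in range(100):
            A = rng.uniform(-10, 10, (8, 8))
            B = rng.uniform(-10, 10, (8, 8))
            sa = fx.share(fx.fp_encode(A, ctx.cfg), ctx)
            sb = fx.share(fx.fp_encode(B, ctx.cfg), ctx)
            (t,) = fx.dealer_issue_triples(ctx, (8, 8), (8, 8))
            out = fx.fp_decode(fx.reconstruct(fx.smc_mul(sa, sb, t, ctx)), ctx.cfg)
            worst = max(worst, float(np.max(np.abs(out - A @ B))))
        assert worst <= 1e-6

    def test_triple_reuse_rejected(self, ctx):
        a = fx.share(fx.fp_encode(np.ones((2, 2)), ctx.cfg), ctx)
        (t,) = fx.dealer_issue_triples(ctx, (2, 2), (2, 2))
        fx.smc_mul(a, a, t, ctx)
        with pytest.raises(fx.TripleReuseError):
            fx.smc_mul(a, a, t, ctx)


class TestTruncation:
    def test_exact_multiple_near_exact(self, ctx):
        s = fx.share(fx.fp_encode(np.array([[4.0]]), ctx.cfg), ctx)
        out = fx.fp_decode(
            fx.reconstruct(fx.smc_truncate(s, 8)), ctx.cfg
        )
        assert abs(out[0, 0] - 4.0 / 256) <= 2**-32 + 2**-24

    def test_squaring_restores_scale(self, ctx):
        s = fx.share(fx.fp_encode(np.array([[4.0]]), ctx.cfg), ctx)
        (t,) = fx.dealer_issue_triples(ctx, (1, 1), (1, 1))
        # smc_mul truncates by frac_bits internally, so the scale is preserved
        out = fx.fp_decode(fx.reconstruct(fx.smc_mul(s, s, t, ctx)), ctx.cfg)
        assert abs(out[0, 0] - 16.0) <= 2**-28

    def test_chained_multiplication_drift(self, ctx):
        # 1000 multiplications by 1.0: accumulated truncation error stays tiny
        s = fx.share(fx.fp_encode(np.array([[1.5]]), ctx.cfg), ctx)
        one = fx.share(fx.fp_encode(np.array([[1.0]]), ctx.cfg), ctx)
        for t in fx.dealer_issue_triples(ctx, (1, 1), (1, 1), count=1000):
            s = fx.smc_mul(s, one, t, ctx)
        drift = abs(fx.fp_decode(fx.reconstruct(s), ctx.cfg)[0, 0] - 1.5)
        assert drift < 1e-4

    def test_more_than_two_parties_unsupported(self):
        ctx = fx.DealerContext(seed=1, party_count=3)
        s = fx.share(np.zeros((1, 1), dtype=object), ctx)
        with pytest.raises(NotImplementedError):
            fx.smc_truncate(s, 8)


class TestDealer:
    def test_triples_satisfy_relation(self, ctx):
        for t in fx.dealer_issue_triples(ctx, (3, 2), (2, 4), count=10):
            a, b, c = (fx.reconstruct(x) for x in (t.a, t.b, t.c))
            assert np.array_equal((a @ b) % ctx.cfg.modulus, c)

    def test_triples_are_distinct(self, ctx):
        triples = fx.dealer_issue_triples(ctx, (1, 1), (1, 1), count=1000)
        values = {int(fx.reconstruct(t.a)[0, 0]) for t in triples}
        assert len(values) == 1000

    def test_issue_log_matches_requests(self):
        ctx = fx.DealerContext(seed=2)
        fx.dealer_issue_triples(ctx, (2, 3), (3, 2), count=4)
        fx.dealer_issue_triples(ctx, (2, 2), (2, 2), count=2, elementwise=True)
        assert ctx.log.triples_issued[((2, 3), (3, 2), False)] == 4
        assert ctx.log.triples_issued[((2, 2), (2, 2), True)] == 2
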