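"""Partitioned dataflow: aggregation, block products, distributed fits."""

import numpy as np
import pytest

from privimpute import fixedpoint as fx
from privimpute.distributed import (
    PartitionedMatrix,
    ShareBackend,
    aggregate,
    mhe_linreg_fit,
    mhe_logreg_fit,
    mhe_mice_analyze,
    partitioned_matmul,
)
from privimpute.engine import PlainEngine
from privimpute.mice import FitSpec
from privimpute.regression import linreg_fit, logreg_fit


def backend(seed=13):
    return ShareBackend(fx.DealerContext(seed=seed))


def split_rows(arr, parts):
    return [arr[c] for c in np.array_split(np.arange(len(arr)), parts)]


class TestPartitionedMatrix:
    def test_horizontal_shape_and_decode(self, rng):
        M = rng.normal(size=(9, 4))
        p = PartitionedMatrix("horizontal", blocks=split_rows(M, 3))
        assert p.global_shape == (9, 4)
        assert np.array_equal(p.decode(), M)

    def test_additive_blocks_must_align(self):
        with pytest.raises(ValueError):
            PartitionedMatrix("additive", blocks=[np.ones((2, 2)), np.ones((3, 2))])

    def test_unknown_partitioning_rejected(self):
        with pytest.raises(ValueError):
            PartitionedMatrix("diagonal", blocks=[np.ones((2, 2))])


class TestAggregate:
    def test_single_party_aggregate_is_the_block(self, rng):
        be = backend()
        M = rng.normal(size=(3, 3))
        agg = aggregate(PartitionedMatrix("additive", blocks=[M]), be)
        assert np.max(np.abs(agg.decode(be) - M)) <= 1e-8

    def test_three_blocks_of_ones(self):
        be = backend()
        blocks = [np.ones((3, 3))] * 3
        agg = aggregate(PartitionedMatrix("additive", blocks=blocks), be)
        assert np.max(np.abs(agg.decode(be) - 3.0)) <= 1e-8

    def test_random_additive_split_reassembles(self, rng):
        be = backend()
        M = rng.normal(size=(4, 5))
        a, b = rng.normal(size=(4, 5)), rng.normal(size=(4, 5))
        agg = aggregate(PartitionedMatrix("additive", blocks=[a, b, M - a - b]), be)
        assert np.max(np.abs(agg.decode(be) - M)) <= 1e-7


class TestPartitionedMatmul:
    def test_vertical_x_horizontal_gramian_exact(self, rng):
        X = rng.normal(size=(30, 4))
        rows = split_rows(X, 3)
        out = partitioned_matmul(
            PartitionedMatrix("vertical", blocks=[b.T for b in rows]),
            PartitionedMatrix("horizontal", blocks=rows),
        )
        assert out.partitioning == "additive"
        assert np.allclose(out.decode(), X.T @ X)  # block algebra, bit-exact

    def test_local_products_need_no_communication(self, rng):
        X = rng.normal(size=(12, 3))
        rows = split_rows(X, 2)
        # a no-traffic stub would make any open() raise; plain block products
        # never touch the backend at all
        out = partitioned_matmul(
            PartitionedMatrix("vertical", blocks=[b.T for b in rows]),
            PartitionedMatrix("horizontal", blocks=rows),
        )
        assert np.allclose(out.decode(), X.T @ X)

    def test_additive_x_aggregated_identity(self, rng):
        be = backend()
        blocks = [rng.normal(size=(3, 3)) for _ in range(3)]
        eye = aggregate(PartitionedMatrix("additive", blocks=[np.eye(3)]), be)
        out = partitioned_matmul(
            PartitionedMatrix("additive", blocks=blocks), eye, be
        )
        assert np.max(np.abs(out.decode(be) - sum(blocks))) <= 1e-6

    def test_three_party_product_matches_pooled(self, rng):
        be = backend()
        A = rng.normal(size=(6, 9))
        B = rng.normal(size=(9, 5))
        cols = np.array_split(np.arange(9), 3)
        out = partitioned_matmul(
            PartitionedMatrix("vertical", blocks=[A[:, c] for c in cols]),
            PartitionedMatrix("horizontal", blocks=[B[c] for c in cols]),
        )
        assert np.max(np.abs(out.decode() - A @ B)) <= 1e-6

    def test_unsupported_pairing_rejected(self, rng):
        h = PartitionedMatrix("horizontal", blocks=[np.ones((2, 2))])
        with pytest.raises(ValueError):
            partitioned_matmul(h, h)


class TestDistributedFits:
    def test_one_party_equals_centralized_linear(self, rng):
        X = rng.normal(size=(40, 2))
        y = X @ np.array([[2.0], [-1.0]]) + 0.5
        w = backend().decrypt(mhe_linreg_fit([X], [y], backend()).weights)
        wp = linreg_fit(PlainEngine(), X, y).weights
        assert np.max(np.abs(w - wp)) <= 1e-3

    def test_exact_line_distributed_row_each(self):
        be = backend()
        Xb = [np.array([[0.0]]), np.array([[1.0]]), np.array([[2.0]])]
        yb = [np.array([[1.0]]), np.array([[3.0]]), np.array([[5.0]])]
        w = be.decrypt(mhe_linreg_fit(Xb, yb, be).weights)
        assert np.max(np.abs(w.ravel() - [2.0, 1.0])) <= 1e-3

    def test_three_party_gd_matches_centralized_closed_form(self, rng):
        be = backend(2)
        X = rng.normal(size=(300, 5))
        y = X @ np.ones((5, 1)) + 1.0 + rng.normal(0, 0.2, (300, 1))
        w = be.decrypt(mhe_linreg_fit(split_rows(X, 3), split_rows(y, 3), be).weights)
        Xb = np.column_stack([X, np.ones(300)])
        exact = np.linalg.solve(Xb.T @ Xb, Xb.T @ y)
        assert np.max(np.abs(w - exact)) <= 1e-3

    def test_one_party_logistic_equals_centralized(self, rng):
        X = rng.normal(size=(100, 2))
        prob = 1 / (1 + np.exp(-(X @ np.array([1.0, -0.5]))))
        y = (rng.uniform(size=100) < prob).astype(float).reshape(-1, 1)
        be = backend(3)
        w = be.decrypt(mhe_logreg_fit([X], [y], be, epochs=100).weights)
        wp = logreg_fit(PlainEngine(), X, y, epochs=100).weights
        assert np.max(np.abs(w - wp)) <= 1e-4

    def test_three_party_logistic_matches_centralized(self, rng):
        X = rng.normal(size=(300, 2))
        prob = 1 / (1 + np.exp(-(X @ np.array([1.0, -0.5]) + 0.3)))
        y = (rng.uniform(size=300) < prob).astype(float).reshape(-1, 1)
        be = backend(4)
        w = be.decrypt(
            mhe_logreg_fit(split_rows(X, 3), split_rows(y, 3), be).weights
        )
        wp = logreg_fit(PlainEngine(), X, y).weights
        assert np.max(np.abs(w - wp)) <= 1e-2

    def test_zero_epochs_returns_initial_weights(self, rng):
        X = rng.normal(size=(30, 2))
        y = (rng.uniform(size=30) < 0.5).astype(float).reshape(-1, 1)
        be = backend(5)
        w = be.decrypt(mhe_logreg_fit([X], [y], be, epochs=0).weights)
        assert np.max(np.abs(w)) <= 1e-6

    def test_logistic_aggregates_data_exactly_twice(self, rng):
        X = rng.normal(size=(60, 2))
        y = (rng.uniform(size=60) < 0.5).astype(float).reshape(-1, 1)
        for epochs in (1, 7):
            be = backend(6)
            mhe_logreg_fit(split_rows(X, 3), split_rows(y, 3), be, epochs=epochs)
            assert be.oplog["aggregations"] == 2


class TestDistributedMice:
    def impute_inputs(self, rng, m=600):
        x1 = rng.normal(size=m)
        X = np.column_stack([2.0 * x1, x1])
        mask = np.ones((m, 2), dtype=int)
        mask[rng.uniform(size=m) < 0.3, 0] = 0
        y = (1.0 + X.sum(axis=1)).reshape(-1, 1)
        return X, X * mask, mask, y

    def test_one_party_no_missingness_is_plain_regression(self, rng):
        X = rng.normal(size=(50, 2))
        y = X @ np.ones((2, 1)) + 1.0
        be = backend(7)
        res = mhe_mice_analyze([X], [y], [np.ones((50, 2), dtype=int)],
                               ("continuous", "continuous"), backend=be, k=2, seed=0)
        wp = linreg_fit(PlainEngine(), X, y).weights
        assert np.max(np.abs(be.decrypt(res.pooled) - wp)) <= 1e-3

    def test_linear_relation_recovered_across_parties(self, rng):
        X, D, mask, y = self.impute_inputs(rng)
        be = backend(8)
        res = mhe_mice_analyze(
            split_rows(D, 3), split_rows(y, 3), split_rows(mask, 3),
            ("continuous", "continuous"), backend=be, k=1, seed=0,
            noise_variance=0.0, keep_imputed=True,
        )
        imputed = np.vstack(res.imputed_datasets[0])
        holes = mask[:, 0] == 0
        assert np.max(np.abs(imputed[holes, 0] - X[holes, 0])) <= 1e-2

    def test_row_shuffle_between_parties_is_invariant(self, rng):
        X, D, mask, y = self.impute_inputs(rng, m=240)
        out = []
        for perm_seed in (None, 77):
            order = np.arange(240)
            if perm_seed is not None:
                order = np.random.default_rng(perm_seed).permutation(240)
            be = backend(9)
            res = mhe_mice_analyze(
                split_rows(D[order], 3), split_rows(y[order], 3),
                split_rows(mask[order], 3),
                ("continuous", "continuous"), backend=be, k=1, seed=0,
                noise_variance=0.0,
            )
            out.append(be.decrypt(res.pooled))
        assert np.max(np.abs(out[0] - out[1])) <= 1e-6
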