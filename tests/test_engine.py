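"""Propagation engine: every propagated factor must agree with a fresh
decomposition of the target submatrix, counters must account exactly for the
plan's modifications, the factor store must round-trip bit-identically
through disk, and whitening must invert by resubstitution."""

import numpy as np
import pytest

from kgen.cholmod import FactorizationError, full_cholesky
from kgen.engine import (
    FactorStore,
    max_entrywise_diff,
    propagate_edge,
    run_kgen,
    run_naive,
    whiten,
)
from kgen.kinship import (
    KinshipMatrix,
    PhenotypeMatrix,
    apply_blockwise_mask,
    apply_mar_mask,
    simulate_wishart_kinship,
)

from conftest import random_pd


def mar_instance(n, d, rate, seed):
    K = simulate_wishart_kinship(n, dof=2000, seed=seed)
    Y = apply_mar_mask(np.zeros((n, d)), rate, seed=seed + 1)
    return K, Y


class TestPropagateEdge:
    def test_identical_obs_sets_unchanged(self, rng):
        K = KinshipMatrix(random_pd(6, rng))
        obs = np.array([0, 2, 4])
        L = full_cholesky(K.submatrix(obs), obs)
        out, ni, nd = propagate_edge(L, obs, K)
        assert (ni, nd) == (0, 0)
        np.testing.assert_array_equal(out.tri, L.tri)

    def test_one_delete_one_insert(self, rng):
        K = KinshipMatrix(random_pd(4, rng))
        src = np.array([0, 1, 2])
        tgt = np.array([0, 2, 3])
        L = full_cholesky(K.submatrix(src), src)
        out, ni, nd = propagate_edge(L, tgt, K)
        assert (ni, nd) == (1, 1)
        oracle = full_cholesky(K.submatrix(tgt), tgt)
        assert np.abs(out.tri - oracle.tri).max() <= 1e-12
        np.testing.assert_array_equal(out.sample_ids, tgt)

    def test_random_obs_pairs_match_submatrix_oracle(self):
        n = 10
        for seed in range(100):
            rng = np.random.default_rng(seed)
            K = KinshipMatrix(random_pd(n, rng))
            src = np.flatnonzero(rng.random(n) < 0.7)
            tgt = np.flatnonzero(rng.random(n) < 0.7)
            if src.size == 0 or tgt.size == 0:
                continue
            L = full_cholesky(K.submatrix(src), src)
            out, ni, nd = propagate_edge(L, tgt, K)
            assert ni == np.setdiff1d(tgt, src).size
            assert nd == np.setdiff1d(src, tgt).size
            oracle = full_cholesky(K.submatrix(tgt), tgt)
            assert np.abs(out.tri - oracle.tri).max() <= 1e-12


class TestRunKgen:
    def test_no_missingness_single_decomposition(self):
        K, _ = mar_instance(30, 1, 0.0, 0)
        Y = PhenotypeMatrix(np.zeros((30, 5)))
        res = run_kgen(K, Y)
        assert res.counters.full_decompositions == 1
        assert res.counters.total_modifications == 0
        ref = res.factor(0).tri
        for j in range(5):
            np.testing.assert_array_equal(res.factor(j).tri, ref)

    def test_threshold_zero_degenerates_to_naive(self):
        K, Y = mar_instance(60, 8, 0.05, 3)
        res = run_kgen(K, Y, short_circuit_threshold=0)
        nonzero_edges = sum(1 for w in res.plan.edge_weights if w > 0)
        assert res.counters.full_decompositions == 1 + nonzero_edges
        assert res.counters.total_modifications == 0
        naive = run_naive(K, Y)
        assert max_entrywise_diff(res, naive) == 0.0

    def test_matches_naive_at_scale(self):
        K, Y = mar_instance(500, 50, 0.01, 10)
        res = run_kgen(K, Y)
        naive = run_naive(K, Y)
        assert max_entrywise_diff(res, naive) <= 1e-12

    def test_counters_account_for_plan_weight(self):
        K, Y = mar_instance(80, 10, 0.05, 4)
        res = run_kgen(K, Y, short_circuit_threshold=np.inf)
        assert res.counters.full_decompositions == 1
        assert res.counters.short_circuits == 0
        assert res.counters.total_modifications == res.plan.total_weight
        for rec in res.counters.edges:
            assert rec.inserts + rec.deletes == rec.weight

    def test_blockwise_short_circuit(self):
        n, d = 300, 40
        K = simulate_wishart_kinship(n, dof=1000, seed=6)
        Y = apply_blockwise_mask(np.zeros((n, d)), block_size=20, mask_frac=0.1, seed=7)
        # between-block weight 2*30=60 > 50; within blocks weight 0
        res = run_kgen(K, Y, short_circuit_threshold=50)
        assert res.counters.full_decompositions == 2
        assert res.counters.short_circuits == 1
        assert res.counters.total_modifications == 0
        naive = run_naive(K, Y)
        assert max_entrywise_diff(res, naive) <= 1e-12

    def test_non_pd_kinship_reported_at_root(self):
        K = KinshipMatrix(np.diag([1.0, -2.0, 1.0]))
        Y = PhenotypeMatrix(np.zeros((3, 2)))
        with pytest.raises(FactorizationError):
            run_kgen(K, Y)

    def test_empty_column_names_the_phenotype(self):
        K = KinshipMatrix(np.eye(3))
        values = np.zeros((3, 2))
        values[:, 1] = np.nan
        with pytest.raises(ValueError, match="column 1"):
            run_kgen(K, PhenotypeMatrix(values))

    def test_naive_counters(self):
        K, Y = mar_instance(40, 6, 0.1, 8)
        res = run_naive(K, Y)
        assert res.counters.full_decompositions == 6
        assert res.counters.total_modifications == 0

    def test_max_obs_root_mode_also_correct(self):
        K, Y = mar_instance(60, 6, 0.1, 12)
        res = run_kgen(K, Y, root_mode="max-obs")
        counts = Y.observed_mask.sum(axis=0)
        assert res.plan.root == int(np.argmax(counts))
        assert max_entrywise_diff(res, run_naive(K, Y)) <= 1e-12


class TestMaxEntrywiseDiff:
    def test_zero_for_identical_runs(self):
        K, Y = mar_instance(50, 5, 0.05, 9)
        a = run_naive(K, Y)
        b = run_naive(K, Y)
        assert max_entrywise_diff(a, b) == 0.0

    def test_mismatched_obs_sets_rejected(self):
        K, Ya = mar_instance(30, 4, 0.1, 1)
        _, Yb = mar_instance(30, 4, 0.1, 2)
        with pytest.raises(ValueError):
            max_entrywise_diff(run_naive(K, Ya), run_naive(K, Yb))


class TestFactorStore:
    def test_lru_eviction_and_bit_identical_reload(self, tmp_path, rng):
        store = FactorStore(capacity=2, spill_dir=tmp_path)
        factors = {}
        for j in range(5):
            K = random_pd(8, rng)
            factors[j] = full_cholesky(K)
            store.put(j, factors[j])
        assert len(store._resident) == 2
        for j in range(5):
            loaded = store.get(j)
            assert np.array_equal(loaded.tri, factors[j].tri)  # bit-identical
            np.testing.assert_array_equal(loaded.sample_ids, factors[j].sample_ids)

    def test_checksum_detects_corruption(self, tmp_path, rng):
        store = FactorStore(capacity=1, spill_dir=tmp_path)
        store.put(0, full_cholesky(random_pd(4, rng)))
        store.put(1, full_cholesky(random_pd(4, rng)))  # evicts 0 to disk
        bin_path = tmp_path / "factor_00000.bin"
        data = bytearray(bin_path.read_bytes())
        data[0] ^= 0xFF
        bin_path.write_bytes(bytes(data))
        with pytest.raises(IOError, match="checksum"):
            store.get(0)

    def test_missing_key(self):
        with pytest.raises(KeyError):
            FactorStore().get(3)

    def test_bounded_run_matches_unbounded(self, tmp_path):
        K, Y = mar_instance(60, 8, 0.05, 21)
        bounded = run_kgen(K, Y, store=FactorStore(capacity=2, spill_dir=tmp_path))
        unbounded = run_kgen(K, Y)
        assert max_entrywise_diff(bounded, unbounded) == 0.0


class TestWhiten:
    def test_identity_factor_returns_input(self, rng):
        L = full_cholesky(np.eye(4))
        y = rng.standard_normal(4)
        np.testing.assert_array_equal(whiten(L, y), y)

    def test_scalar_case(self):
        L = full_cholesky(np.array([[4.0]]))
        np.testing.assert_allclose(whiten(L, np.array([2.0])), [1.0])

    def test_resubstitution(self, rng):
        K = random_pd(30, rng)
        L = full_cholesky(K)
        y = rng.standard_normal(30)
        x = whiten(L, y)
        assert np.abs(L.tri @ x - y).max() <= 1e-12
        # x^T x equals the quadratic form y^T K^-1 y
        assert np.isclose(x @ x, y @ np.linalg.solve(K, y), atol=1e-9)

    def test_dimension_mismatch(self, rng):
        L = full_cholesky(random_pd(4, rng))
        with pytest.raises(ValueError):
            whiten(L, np.zeros(5))
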