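"""HNSW construction, search, structural invariants, and persistence."""

import math

import numpy as np
import pytest

from eimatch.hnsw import (
    HNSWGraph,
    HNSWParams,
    assign_level,
    check_structure,
    expected_level_mean,
    load_index,
    save_index,
)


def unit_vectors(rng, n, d):
    X = rng.standard_normal((n, d)).astype(np.float32)
    return X / np.linalg.norm(X, axis=1, keepdims=True)


@pytest.fixture(scope="module")
def built_500():
    rng = np.random.default_rng(99)
    X = unit_vectors(rng, 500, 16)
    g = HNSWGraph(M=8, ef_construction=100, ef=60, seed=0).fit(X)
    return g, X


class TestLevelAssignment:
    def test_zero_multiplier_always_level_zero(self, rng):
        assert all(assign_level(0.0, rng) == 0 for _ in range(100))

    def test_fixed_seed_reproducible_sequence(self):
        a = [assign_level(0.5, np.random.default_rng(5)) for _ in range(1)]
        b = [assign_level(0.5, np.random.default_rng(5)) for _ in range(1)]
        r1, r2 = np.random.default_rng(5), np.random.default_rng(5)
        assert [assign_level(0.5, r1) for _ in range(50)] == [
            assign_level(0.5, r2) for _ in range(50)
        ]

    @pytest.mark.parametrize("m_l", [0.36, 1.0])
    def test_monte_carlo_mean_matches_closed_form(self, m_l):
        """Empirical mean of floor(-ln(u) m_l) vs 1/(e^{1/m_l} - 1)."""
        rng = np.random.default_rng(7)
        draws = np.array([assign_level(m_l, rng) for _ in range(100_000)])
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - expected_level_mean(m_l)) < 3 * se

    def test_survival_probability_decays_exponentially(self):
        rng = np.random.default_rng(11)
        m_l = 1.0
        draws = np.array([assign_level(m_l, rng) for _ in range(100_000)])
        for k in (1, 2):
            emp = (draws >= k).mean()
            assert emp == pytest.approx(math.exp(-k / m_l), rel=0.05)


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HNSWParams(M=1)
        with pytest.raises(ValueError):
            HNSWParams(M=8, ef_construction=4)
        with pytest.raises(ValueError):
            HNSWParams(ef=0)

    def test_default_level_multiplier(self):
        assert HNSWParams(M=16).level_multiplier == pytest.approx(1 / math.log(16))


class TestSearchLayer:
    def test_complete_graph_is_exact(self, rng):
        """With ef_construction = n the base layer is near-complete; search
        with ef = n returns the exact neighbor set."""
        X = unit_vectors(rng, 60, 8)
        g = HNSWGraph(M=30, ef_construction=60, ef=60, seed=0).fit(X)
        q = unit_vectors(rng, 1, 8)[0]
        res = g.search_layer(q, [g.entry_point_], ef=60, layer=0)
        got = [n for _, n in res[:10]]
        true = np.argsort(((X - q) ** 2).sum(axis=1))[:10]
        assert set(got) == set(true.tolist())

    def test_ef_one_is_greedy_descent(self, built_500):
        g, X = built_500
        q = X[123]
        res = g.search_layer(q, [g.entry_point_], ef=1, layer=0)
        assert len(res) == 1  # a single local minimum

    def test_distances_sorted_and_unique_ids(self, built_500, rng):
        g, X = built_500
        res = g.search_layer(unit_vectors(rng, 1, 16)[0], [g.entry_point_], 20, 0)
        ds = [d for d, _ in res]
        assert ds == sorted(ds)
        ns = [n for _, n in res]
        assert len(set(ns)) == len(ns)


class TestInsertion:
    def test_first_element_becomes_entry_point(self):
        g = HNSWGraph(M=4, ef_construction=8, ef=4, seed=0)
        g.fit(np.eye(3, dtype=np.float32)[:1], ids=["a"])
        assert g.entry_point_ == 0
        assert g.count_ == 1
        assert g.levels_[0] == g.max_level_

    def test_structural_audit_after_batch(self, built_500):
        g, _ = built_500
        assert check_structure(g) == []

    def test_duplicate_vector_geometry(self, built_500):
        g, X = built_500
        g2 = HNSWGraph(M=8, ef_construction=100, ef=60, seed=0).fit(X)
        g2.insert("twin", X[42])
        cl = g2.knn_search(X[42], k=2, ef=60)
        assert {c.id for c in cl} == {"42", "twin"}
        assert all(c.score == pytest.approx(0.0, abs=1e-6) for c in cl)

    def test_duplicate_id_rejected(self, built_500):
        g, X = built_500
        with pytest.raises(ValueError, match="duplicate"):
            HNSWGraph(M=4, ef_construction=8, ef=4).fit(X[:5], ids=list("abcde")).insert(
                "a", X[6]
            )

    def test_dimension_mismatch_rejected(self, built_500):
        g, _ = built_500
        with pytest.raises(ValueError):
            HNSWGraph(M=4, ef_construction=8, ef=4).fit(
                np.eye(4, dtype=np.float32)
            ).insert("x", np.ones(7, dtype=np.float32))

    def test_incremental_add_preserves_structure(self, rng):
        X = unit_vectors(rng, 300, 16)
        g = HNSWGraph(M=8, ef_construction=64, ef=32, seed=1).fit(X[:250])
        g.add(X[250:], ids=[f"n{i}" for i in range(50)])
        assert g.count_ == 300
        assert check_structure(g) == []


class TestKnnSearch:
    def test_self_retrieval(self, built_500):
        g, X = built_500
        cl = g.knn_search(X[7], k=1, ef=60)
        assert cl.entries[0].id == "7"
        assert cl.entries[0].score == pytest.approx(0.0, abs=1e-6)

    def test_two_element_index(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]], dtype=np.float32)
        g = HNSWGraph(M=2, ef_construction=2, ef=2, seed=0).fit(X, ids=["x", "y"])
        cl = g.knn_search(np.array([0.9, 0.1], dtype=np.float32), k=1, ef=2)
        assert cl.entries[0].id == "x"

    def test_k_greater_than_ef_rejected(self, built_500):
        g, X = built_500
        with pytest.raises(ValueError, match="ef"):
            g.knn_search(X[0], k=50, ef=10)

    def test_empty_index_rejected(self):
        g = HNSWGraph(M=4, ef_construction=8, ef=4)
        g._reset(4)
        with pytest.raises(ValueError, match="empty"):
            g.knn_search(np.ones(4, dtype=np.float32), k=1)

    def test_recall_against_brute_force(self, rng):
        """Moderate-size oracle check: >= 90% of exact neighbors found."""
        X = unit_vectors(rng, 2000, 32)
        Q = unit_vectors(rng, 50, 32)
        g = HNSWGraph(M=16, ef_construction=200, ef=100, seed=0).fit(X)
        _, idx = g.kneighbors(Q, k=10, ef=100)
        true = np.argsort(-(Q @ X.T), axis=1)[:, :10]
        recall = np.mean(
            [len(set(idx[i]) & set(true[i].tolist())) / 10 for i in range(50)]
        )
        assert recall >= 0.9

    def test_recall_monotone_in_ef(self, built_500, rng):
        g, X = built_500
        Q = unit_vectors(rng, 40, 16)
        true = np.argsort(-(Q @ X.T), axis=1)[:, :5]
        recalls = []
        for ef in (5, 10, 40):
            _, idx = g.kneighbors(Q, k=5, ef=ef)
            recalls.append(
                np.mean([len(set(idx[i]) & set(true[i].tolist())) / 5 for i in range(40)])
            )
        assert recalls[0] <= recalls[1] <= recalls[2] + 1e-9

    def test_full_ef_perfect_recall_small_index(self, built_500, rng):
        g, X = built_500
        Q = unit_vectors(rng, 20, 16)
        true = np.argsort(-(Q @ X.T), axis=1)[:, :5]
        _, idx = g.kneighbors(Q, k=5, ef=500)
        recall = np.mean([len(set(idx[i]) & set(true[i].tolist())) / 5 for i in range(20)])
        assert recall == 1.0

    def test_distance_counter_tracks_work(self, built_500, rng):
        g, _ = built_500
        g.reset_distance_counter()
        g.kneighbors(unit_vectors(rng, 5, 16), k=5, ef=20)
        assert 0 < g.n_distance_evals_ < 5 * g.count_  # far below brute force


class TestPersistence:
    def test_round_trip_queries_identical(self, built_500, tmp_path, rng):
        g, X = built_500
        path = tmp_path / "index.npz"
        save_index(g, path)
        g2 = load_index(path)
        Q = unit_vectors(rng, 50, 16)
        d1, i1 = g.kneighbors(Q, k=10, ef=60)
        d2, i2 = g2.kneighbors(Q, k=10, ef=60)
        assert np.array_equal(i1, i2)
        np.testing.assert_array_equal(d1, d2)
        assert g2.ids_ == g.ids_
        assert g2.graph_ == g.graph_

    def test_empty_index_round_trip(self, tmp_path):
        g = HNSWGraph(M=4, ef_construction=8, ef=4)
        g._reset(8)
        save_index(g, tmp_path / "empty.npz")
        g2 = load_index(tmp_path / "empty.npz")
        assert g2.count_ == 0

    def test_corrupted_container_gives_version_error(self, tmp_path):
        path = tmp_path / "bad.npz"
        np.savez(path, nonsense=np.arange(3))
        with pytest.raises(ValueError, match="header|version"):
            load_index(path)

    def test_save_load_then_expand(self, built_500, tmp_path, rng):
        g, X = built_500
        save_index(g, tmp_path / "i.npz")
        g2 = load_index(tmp_path / "i.npz")
        g2.add(unit_vectors(rng, 10, 16), ids=[f"new{i}" for i in range(10)])
        assert g2.count_ == 510
        assert check_structure(g2) == []


def test_determinism_same_seed_same_graph(rng):
    X = unit_vectors(rng, 200, 8)
    g1 = HNSWGraph(M=8, ef_construction=32, ef=16, seed=3).fit(X)
    g2 = HNSWGraph(M=8, ef_construction=32, ef=16, seed=3).fit(X)
    assert g1.levels_ == g2.levels_
    assert g1.graph_ == g2.graph_
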