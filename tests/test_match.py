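"""Matcher pipeline: variants, queries, mass filter, recall@k, expansion."""

import numpy as np
import pytest

from eimatch.embed import PeakWordEmbedder
from eimatch.hnsw import HNSWGraph
from eimatch.match import (
    MethodVariant,
    SpectrumMatcher,
    mass_filter,
    recall_at_k,
    top_k_overlap,
)
from eimatch.synth import NoiseParams, SynthParams, make_library, make_queries
from eimatch.vectorize import Candidate, CandidateList


SMALL_EMBEDDER = dict(dim=16, epochs=5, seed=0)
SMALL_INDEX = dict(M=8, ef_construction=64, ef=64, seed=0)


@pytest.fixture(scope="module")
def library():
    params = SynthParams(n_molecules=300, seed=7)
    return (params, *make_library(params))


@pytest.fixture(scope="module")
def fitted_matchers(library):
    params, spectra, truth, masses = library
    embedder = PeakWordEmbedder(**SMALL_EMBEDDER).fit(spectra)
    out = {}
    for variant in ("binned-brute", "embedding-brute", "binned-hnsw", "embedding-hnsw"):
        m = SpectrumMatcher(
            variant=variant, embedder=embedder, index=HNSWGraph(**SMALL_INDEX)
        )
        m.fit(spectra, keys=truth, masses=masses)
        out[variant] = m
    return out


class TestVariants:
    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            MethodVariant.parse("fancy-search")

    def test_brute_variant_builds_no_index(self, fitted_matchers):
        assert fitted_matchers["binned-brute"].index_ is None
        assert fitted_matchers["embedding-brute"].index_ is None

    def test_hnsw_variant_index_count(self, fitted_matchers, library):
        _, spectra, _, _ = library
        assert fitted_matchers["embedding-hnsw"].index_.count_ == len(spectra)

    def test_rebuild_is_deterministic(self, library):
        params, spectra, truth, masses = library
        kw = dict(
            variant="embedding-hnsw",
            embedder=PeakWordEmbedder(**SMALL_EMBEDDER),
            index=HNSWGraph(**SMALL_INDEX),
        )
        m1 = SpectrumMatcher(**kw).fit(spectra, keys=truth, masses=masses)
        m2 = SpectrumMatcher(**kw).fit(spectra, keys=truth, masses=masses)
        assert np.array_equal(m1.embeddings_, m2.embeddings_)
        assert m1.index_.graph_ == m2.index_.graph_


class TestQuery:
    @pytest.mark.parametrize("variant", ["binned-brute", "embedding-brute"])
    def test_library_spectrum_is_its_own_best_match(self, fitted_matchers, library, variant):
        _, spectra, _, _ = library
        m = fitted_matchers[variant]
        res = m.query(spectra[:15], k=5)
        for s in spectra[:15]:
            top = res[s.id].entries[0]
            assert top.id == s.id
            assert top.score == pytest.approx(1.0, abs=1e-6)

    def test_k_equal_library_size_total_ranking(self, fitted_matchers, library):
        _, spectra, _, _ = library
        res = fitted_matchers["binned-brute"].query([spectra[0]], k=len(spectra))
        assert sorted(res[spectra[0].id].ids()) == sorted(s.id for s in spectra)

    def test_hnsw_agrees_with_exact_on_identical_embeddings(self, fitted_matchers, library):
        params, spectra, _, _ = library
        queries, _ = make_queries(spectra, params, n_queries=60)
        exact = fitted_matchers["embedding-brute"].query(queries, k=10)
        approx = fitted_matchers["embedding-hnsw"].query(queries, k=10)
        overlap = np.mean(
            [top_k_overlap(exact[q.id], approx[q.id], 10) for q in queries]
        )
        assert overlap >= 0.9

    def test_k_exceeding_library_rejected(self, fitted_matchers, library):
        _, spectra, _, _ = library
        with pytest.raises(ValueError):
            fitted_matchers["binned-brute"].query([spectra[0]], k=10_000)


class TestMassFilter:
    def _cl(self, ids):
        return CandidateList([Candidate(i, 1.0 - 0.01 * n) for n, i in enumerate(ids)])

    def test_boundary_inclusive_at_tolerance(self):
        masses = {"a": 154.9, "b": 155.1}
        out = mass_filter(self._cl(["a", "b"]), masses, query_mass=150.0, tol=5.0)
        assert out.ids() == ["a"]

    def test_infinite_tolerance_is_identity(self):
        masses = {"a": 10.0, "b": 900.0}
        cl = self._cl(["a", "b"])
        out = mass_filter(cl, masses, query_mass=100.0, tol=float("inf"))
        assert out.ids() == cl.ids()

    def test_order_preserved_and_massless_counted(self):
        masses = {"a": 100.0, "c": 101.0}
        out = mass_filter(self._cl(["a", "b", "c"]), masses, query_mass=100.0, tol=5.0)
        assert out.ids() == ["a", "c"]
        assert out.n_massless == 1

    def test_filter_never_hurts_recall_with_exact_masses(self, library):
        params, spectra, truth, masses = library
        embedder = PeakWordEmbedder(**SMALL_EMBEDDER).fit(spectra)
        m = SpectrumMatcher(variant="embedding-brute", embedder=embedder)
        m.fit(spectra, keys=truth, masses=masses)
        queries, origin = make_queries(spectra, params, n_queries=80)
        qtruth = {q.id: truth[origin[q.id]] for q in queries}
        ks = list(range(1, 11))
        plain = m.query(queries, k=10)
        filt = m.query(queries, k=10, mass_filter_da=5.0)
        r_plain = recall_at_k(plain, qtruth, m.key_map_, ks)
        r_filt = recall_at_k(filt, qtruth, m.key_map_, ks)
        for k in ks:
            assert r_filt.per_k[k] >= r_plain.per_k[k]


class TestRecallAtK:
    def test_all_rank_one(self):
        results = {f"q{i}": CandidateList([Candidate(f"m{i}", 1.0)]) for i in range(5)}
        truth = {f"q{i}": f"m{i}" for i in range(5)}
        key_map = {f"m{i}": f"m{i}" for i in range(5)}
        res = recall_at_k(results, truth, key_map, [1])
        assert res.per_k[1] == 1.0

    def test_truth_at_rank_seven(self):
        ids = [f"m{j}" for j in range(10)]
        results = {
            "q": CandidateList([Candidate(i, 1.0 - 0.01 * j) for j, i in enumerate(ids)])
        }
        truth = {"q": "m6"}
        key_map = {i: i for i in ids}
        res = recall_at_k(results, truth, key_map, [1, 10])
        assert res.per_k[1] == 0.0
        assert res.per_k[10] == 1.0

    def test_recall_nondecreasing_in_k(self, fitted_matchers, library):
        params, spectra, truth, masses = library
        queries, origin = make_queries(spectra, params, n_queries=60)
        qtruth = {q.id: truth[origin[q.id]] for q in queries}
        for variant, m in fitted_matchers.items():
            res = m.query(queries, k=20)
            ks = [1, 2, 5, 10, 20]
            ev = recall_at_k(res, qtruth, m.key_map_, ks)
            vals = [ev.per_k[k] for k in ks]
            assert vals == sorted(vals), variant

    def test_random_ranking_matches_expectation(self, rng):
        """recall@10 of random rankings over N=100 molecules ~= 10/100."""
        n_lib, n_q, k = 100, 1000, 10
        key_map = {f"m{i}": f"m{i}" for i in range(n_lib)}
        results, truth = {}, {}
        for qi in range(n_q):
            order = rng.permutation(n_lib)[:k]
            results[f"q{qi}"] = CandidateList(
                [Candidate(f"m{j}", 1.0 - 0.001 * r) for r, j in enumerate(order)]
            )
            truth[f"q{qi}"] = f"m{rng.integers(n_lib)}"
        res = recall_at_k(results, truth, key_map, [k])
        expected = k / n_lib
        se = np.sqrt(expected * (1 - expected) / n_q)
        assert abs(res.per_k[k] - expected) < 4 * se

    def test_uncovered_truth_excluded_with_warning(self):
        results = {"q": CandidateList([Candidate("m0", 1.0)])}
        with pytest.warns(UserWarning, match="not in library"):
            res = recall_at_k(results, {"q": "ghost"}, {"m0": "m0"}, [1])
        assert res.n_uncovered == 1
        assert res.n_queries == 0

    def test_replicate_spectra_count_as_one_molecule(self):
        # two library spectra of the same molecule occupy one rank slot
        results = {
            "q": CandidateList(
                [Candidate("s1", 0.9), Candidate("s2", 0.8), Candidate("s3", 0.7)]
            )
        }
        key_map = {"s1": "molA", "s2": "molA", "s3": "molB"}
        res = recall_at_k(results, {"q": "molB"}, key_map, [2])
        assert res.per_k[2] == 1.0  # molB is the 2nd distinct molecule


class TestExpansion:
    def test_expand_by_zero_is_identity(self, library):
        params, spectra, truth, masses = library
        m = SpectrumMatcher(
            variant="embedding-hnsw",
            embedder=PeakWordEmbedder(**SMALL_EMBEDDER),
            index=HNSWGraph(**SMALL_INDEX),
        ).fit(spectra, keys=truth, masses=masses)
        before = m.index_.count_
        m.add([])
        assert m.index_.count_ == before

    def test_expand_increases_count_and_keeps_old_queries(self, library):
        params, spectra, truth, masses = library
        m = SpectrumMatcher(
            variant="embedding-hnsw",
            embedder=PeakWordEmbedder(**SMALL_EMBEDDER),
            index=HNSWGraph(**SMALL_INDEX),
        ).fit(spectra[:250], keys=truth, masses=masses)
        index_obj = m.index_
        m.add(spectra[250:])
        assert m.index_ is index_obj  # no rebuild
        assert m.index_.count_ == len(spectra)
        res = m.query(spectra[:5], k=3)
        for s in spectra[:5]:
            assert s.id in res[s.id].ids()

    def test_duplicate_ids_rejected(self, library):
        params, spectra, truth, masses = library
        m = SpectrumMatcher(
            variant="binned-brute", vectorizer=None
        ).fit(spectra, keys=truth, masses=masses)
        with pytest.raises(ValueError, match="duplicate"):
            m.add(spectra[:3])
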