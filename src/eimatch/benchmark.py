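"""Reference benchmarks: library accounting, index quality, ablation, scaling.

These routines define the package's standard evaluation protocol on the
synthetic benchmark (and, for the library-accounting arithmetic, on the
published component sizes of the EI libraries the filters were designed for).
They are used both by the test suite and by ``scripts/acceptance.py``, so the
numbers reported in either place come from one implementation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .embed import PeakWordEmbedder
from .hnsw import HNSWGraph, assign_level, check_structure, expected_level_mean
from .libprep import dedup_keys_across, dedup_keys_within
from .match import SpectrumMatcher, recall_at_k, top_k_overlap
from .msio import normalize_spectrum
from .synth import NoiseParams, SynthParams, make_library, make_queries, perturb_spectrum
from .vectorize import BinnedVectorizer, bin_spectrum, weighted_cosine

__all__ = [
    "LIBRARY_COMPONENT_SIZES",
    "library_accounting",
    "level_law",
    "hnsw_quality",
    "self_retrieval",
    "ablation",
    "expansion",
    "scaling",
    "noise_calibration",
]

#: Published sizes of the filtered, deduplicated component sets used to
#: assemble the EI in-silico libraries (molecule counts after the five
#: filtering rules).  Disjointness across components is the stated guarantee
#: of the cross-dataset deduplication.
LIBRARY_COMPONENT_SIZES = {
    "nist_training": 232_826,
    "nist_validation": 11_496,
    "nist_test": 11_499,
    "chembl": 1_890_869,
    "hmdb": 106_516,
    "extra_test": 10,
}


def library_accounting(sizes: dict[str, int] | None = None) -> dict[str, int]:
    """Recover the library totals from component sizes via key-level dedup.

    Builds disjoint synthetic key sets of exactly the component sizes (the
    post-deduplication guarantee), runs the within/across deduplication on
    them, and counts the resulting unions:

    * f-NIST = training + validation + test
    * in-silico library = f-NIST + f-ChEMBL
    * word2vec training set = training + f-ChEMBL
    * expanded library = in-silico + f-HMDB + extra test set
    """
    sizes = dict(LIBRARY_COMPONENT_SIZES if sizes is None else sizes)
    keys: dict[str, list[int]] = {}
    offset = 0
    for name, n in sizes.items():
        keys[name] = list(range(offset, offset + n))
        offset += n

    def union(*names: str) -> int:
        deduped = dedup_keys_across([dedup_keys_within(keys[n]) for n in names])
        return sum(len(ds) for ds in deduped)

    return {
        "fnist": union("nist_training", "nist_validation", "nist_test"),
        "insilico_library": union(
            "nist_training", "nist_validation", "nist_test", "chembl"
        ),
        "word2vec_training_set": union("nist_training", "chembl"),
        "expanded_library": union(
            "nist_training", "nist_validation", "nist_test", "chembl",
            "hmdb", "extra_test",
        ),
    }


# --- HNSW property benchmarks --------------------------------------------


@dataclass
class LevelLawResult:
    m_l: float
    empirical_mean: float
    expected_mean: float
    standard_error: float
    n_draws: int


def level_law(m_l: float = 1.0, n_draws: int = 100_000, seed: int = 0) -> LevelLawResult:
    """Monte-Carlo check of the level distribution against its closed form."""
    rng = np.random.default_rng(seed)
    draws = np.fromiter((assign_level(m_l, rng) for _ in range(n_draws)), dtype=np.int64)
    return LevelLawResult(
        m_l=m_l,
        empirical_mean=float(draws.mean()),
        expected_mean=expected_level_mean(m_l),
        standard_error=float(draws.std(ddof=1) / math.sqrt(n_draws)),
        n_draws=n_draws,
    )


def _unit(rng: np.random.Generator, n: int, d: int) -> np.ndarray:
    X = rng.standard_normal((n, d)).astype(np.float32)
    return X / np.linalg.norm(X, axis=1, keepdims=True)


@dataclass
class HNSWQualityResult:
    recall_at_10: float
    recall_by_ef: dict[int, float]
    structure_violations: int
    n_vectors: int
    n_queries: int


def hnsw_quality(
    seed: int = 0,
    n: int = 10_000,
    dim: int = 64,
    n_queries: int = 200,
    M: int = 16,
    ef_construction: int = 200,
    ef: int = 100,
    ef_sweep: tuple[int, ...] = (10, 20, 80),
) -> HNSWQualityResult:
    """Recall@10 vs exact search on random unit vectors, plus structure audit.

    The index is built in batches with the structural audit re-run after each
    batch; ``recall_by_ef`` exercises the monotone-in-ef property.
    """
    rng = np.random.default_rng(seed)
    X = _unit(rng, n, dim)
    Q = _unit(rng, n_queries, dim)
    g = HNSWGraph(M=M, ef_construction=ef_construction, ef=ef, seed=seed)
    violations = 0
    batch = n // 4
    g.fit(X[:batch])
    violations += len(check_structure(g))
    for start in range(batch, n, batch):
        g.add(X[start : start + batch])
        violations += len(check_structure(g))
    true = np.argsort(-(Q @ X.T), axis=1)[:, :10]

    def mean_recall(ef_q: int) -> float:
        _, idx = g.kneighbors(Q, k=10, ef=ef_q)
        return float(
            np.mean([len(set(idx[i]) & set(true[i].tolist())) / 10 for i in range(n_queries)])
        )

    return HNSWQualityResult(
        recall_at_10=mean_recall(ef),
        recall_by_ef={e: mean_recall(e) for e in ef_sweep},
        structure_violations=violations,
        n_vectors=n,
        n_queries=n_queries,
    )


# --- synthetic matching benchmarks ---------------------------------------

#: embedding settings for the desk-scale benchmark (reduced from the
#: production defaults of dim=500, epochs=60)
BENCH_EMBEDDER = dict(dim=64, epochs=30, seed=0)
BENCH_INDEX = dict(M=16, ef_construction=200, ef=100, seed=0)


def _benchmark_matchers(
    spectra, truth, masses, variants, embedder_kw=None, index_kw=None
):
    embedder_kw = {**BENCH_EMBEDDER, **(embedder_kw or {})}
    index_kw = {**BENCH_INDEX, **(index_kw or {})}
    needs_embedding = any(v.startswith("embedding") for v in variants)
    embedder = (
        PeakWordEmbedder(**embedder_kw).fit(spectra) if needs_embedding else None
    )
    matchers = {}
    for v in variants:
        matchers[v] = SpectrumMatcher(
            variant=v, embedder=embedder, index=HNSWGraph(**index_kw)
        ).fit(spectra, keys=truth, masses=masses)
    return matchers


def self_retrieval(
    seed: int = 0, n_molecules: int = 2000, n_queries: int = 200
) -> dict[str, float]:
    """Zero-noise sanity benchmark: recall@1 when query == library spectrum.

    Embedding training at the reduced desk scale of dim=64, epochs=10.
    """
    p = SynthParams(n_molecules=n_molecules, seed=seed)
    spectra, truth, masses = make_library(p)
    matchers = _benchmark_matchers(
        spectra, truth, masses,
        ("binned-brute", "embedding-brute", "binned-hnsw", "embedding-hnsw"),
        embedder_kw=dict(epochs=10, seed=seed),
        index_kw=dict(seed=seed),
    )
    rng = np.random.default_rng(seed + 1)
    picks = rng.choice(len(spectra), size=n_queries, replace=False)
    queries = [dataclasses.replace(spectra[int(i)], id=f"Q{spectra[int(i)].id}") for i in picks]
    qtruth = {q.id: truth[q.id[1:]] for q in queries}
    out = {}
    for v, m in matchers.items():
        res = m.query(queries, k=10)
        out[v] = recall_at_k(res, qtruth, m.key_map_, [1]).per_k[1]
    return out


@dataclass
class AblationResult:
    recall_at_1: dict[str, float]
    recall_at_10: dict[str, float]
    overlap_embedding: float  # exact vs HNSW top-10 on identical embeddings
    overlap_binned: float
    n_queries: int
    matchers: dict
    queries: list
    query_truth: dict[str, str]


def ablation(
    seed: int = 0, n_molecules: int = 2000, n_queries: int = 200
) -> AblationResult:
    """The four-variant comparison on the calibrated noisy benchmark."""
    p = SynthParams(n_molecules=n_molecules, seed=seed)
    spectra, truth, masses = make_library(p)
    matchers = _benchmark_matchers(
        spectra, truth, masses,
        ("binned-brute", "embedding-brute", "binned-hnsw", "embedding-hnsw"),
        embedder_kw=dict(seed=seed),
        index_kw=dict(seed=seed),
    )
    queries, origin = make_queries(spectra, p, n_queries=n_queries)
    qtruth = {q.id: truth[origin[q.id]] for q in queries}
    results = {v: m.query(queries, k=10) for v, m in matchers.items()}
    r1, r10 = {}, {}
    for v, res in results.items():
        ev = recall_at_k(res, qtruth, matchers[v].key_map_, [1, 10])
        r1[v], r10[v] = ev.per_k[1], ev.per_k[10]
    ov_emb = float(np.mean([
        top_k_overlap(results["embedding-brute"][q.id], results["embedding-hnsw"][q.id], 10)
        for q in queries
    ]))
    ov_bin = float(np.mean([
        top_k_overlap(results["binned-brute"][q.id], results["binned-hnsw"][q.id], 10)
        for q in queries
    ]))
    return AblationResult(
        recall_at_1=r1,
        recall_at_10=r10,
        overlap_embedding=ov_emb,
        overlap_binned=ov_bin,
        n_queries=n_queries,
        matchers=matchers,
        queries=queries,
        query_truth=qtruth,
    )


def mass_filter_gain(ab: AblationResult, tol: float = 5.0) -> dict[int, tuple[float, float]]:
    """recall@k before/after the mass filter, exact-mass queries, k = 1..10."""
    m = ab.matchers["embedding-brute"]
    ks = list(range(1, 11))
    plain = recall_at_k(m.query(ab.queries, k=10), ab.query_truth, m.key_map_, ks)
    filt = recall_at_k(
        m.query(ab.queries, k=10, mass_filter_da=tol), ab.query_truth, m.key_map_, ks
    )
    return {k: (plain.per_k[k], filt.per_k[k]) for k in ks}


@dataclass
class ExpansionResult:
    recall_before: dict[int, float]
    recall_after: dict[int, float]
    count_before: int
    count_after: int
    index_rebuilt: bool


def expansion(
    seed: int = 0, n_molecules: int = 2000, n_new: int = 100, n_queries: int = 200
) -> ExpansionResult:
    """Incremental index expansion: recall drift on the original query set."""
    p = SynthParams(n_molecules=n_molecules + n_new, seed=seed)
    spectra, truth, masses = make_library(p)
    base, extra = spectra[:n_molecules], spectra[n_molecules:]
    embedder = PeakWordEmbedder(**{**BENCH_EMBEDDER, "seed": seed}).fit(base)
    m = SpectrumMatcher(
        variant="embedding-hnsw", embedder=embedder,
        index=HNSWGraph(**{**BENCH_INDEX, "seed": seed}),
    ).fit(base, keys=truth, masses=masses)
    queries, origin = make_queries(base, p, n_queries=n_queries)
    qtruth = {q.id: truth[origin[q.id]] for q in queries}
    ks = [1, 10]
    before = recall_at_k(m.query(queries, k=10), qtruth, m.key_map_, ks).per_k
    index_obj = m.index_
    count_before = m.index_.count_
    m.add(extra, keys=truth, masses=masses)
    after = recall_at_k(m.query(queries, k=10), qtruth, m.key_map_, ks).per_k
    return ExpansionResult(
        recall_before=before,
        recall_after=after,
        count_before=count_before,
        count_after=m.index_.count_,
        index_rebuilt=m.index_ is not index_obj,
    )


def scaling(
    seed: int = 0,
    sizes: tuple[int, ...] = (1000, 4000, 16000, 64000),
    dim: int = 16,
    n_queries: int = 50,
) -> dict[int, dict[str, float]]:
    """Distance evaluations per query vs library size, HNSW vs brute force.

    Light index parameters (M=8, ef_construction=64, ef=32) keep the largest
    build tractable; the sublinear growth of the HNSW count against the
    linear brute-force count (= N) is the quantity of interest.
    """
    rng = np.random.default_rng(seed)
    X = _unit(rng, max(sizes), dim)
    Q = _unit(rng, n_queries, dim)
    g = HNSWGraph(M=8, ef_construction=64, ef=32, seed=seed)
    out: dict[int, dict[str, float]] = {}
    built = 0
    for n in sorted(sizes):
        if built == 0:
            g.fit(X[:n])
        else:
            g.add(X[built:n])
        built = n
        g.reset_distance_counter()
        g.kneighbors(Q, k=10, ef=32)
        out[n] = {
            "hnsw_evals_per_query": g.n_distance_evals_ / n_queries,
            "brute_evals_per_query": float(n),
        }
    return out


def noise_calibration(seed: int = 0, n_spectra: int = 1000) -> float:
    """Median weighted-cosine self-similarity under the default noise model."""
    p = SynthParams(n_molecules=n_spectra, seed=seed)
    spectra, _, _ = make_library(p)
    rng = np.random.default_rng(seed + 1)
    scheme = BinnedVectorizer().scheme
    sims = [
        weighted_cosine(
            bin_spectrum(perturb_spectrum(s, p.noise, rng), scheme),
            bin_spectrum(normalize_spectrum(s), scheme),
        )
        for s in spectra
    ]
    return float(np.median(sims))
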