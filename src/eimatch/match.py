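"""End-to-end spectrum matching: build, query, mass filter, recall@k, expand.

Four method variants combine a spectrum representation with a search engine:

=================  ==============  ========
variant            representation  search
=================  ==============  ========
``binned-brute``   weighted bins   exact cosine (the WCS baseline)
``embedding-brute``  peak-word embedding  exact cosine
``binned-hnsw``    weighted bins   HNSW approximate
``embedding-hnsw`` peak-word embedding  HNSW approximate (the fast path)
=================  ==============  ========

All representations are L2-normalized before indexing, so HNSW's squared
Euclidean ranking equals the cosine ranking and every candidate list reports
cosine similarity regardless of the internal metric.  Retrieval quality is
summarized as recall@k — the fraction of query spectra whose true molecule
key appears among the distinct molecule keys of the top-k candidates — with
an optional post-search molecular-mass filter (default tolerance 5 Da,
inclusive) applied to the retrieved list before re-ranking survivors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, clone

from .embed import PeakWordEmbedder
from .hnsw import HNSWGraph
from .msio import Spectrum, normalize_spectrum
from .vectorize import BinnedVectorizer, Candidate, CandidateList

__all__ = [
    "VARIANTS",
    "MethodVariant",
    "EvalResult",
    "SpectrumMatcher",
    "mass_filter",
    "recall_at_k",
    "top_k_overlap",
]

VARIANTS = ("binned-brute", "embedding-brute", "binned-hnsw", "embedding-hnsw")


@dataclass(frozen=True)
class MethodVariant:
    representation: str  # "binned" | "embedding"
    search: str  # "brute" | "hnsw"

    def __post_init__(self):
        if f"{self.representation}-{self.search}" not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.representation}-{self.search}; choose from {VARIANTS}"
            )

    @classmethod
    def parse(cls, name: str) -> "MethodVariant":
        rep, _, search = name.partition("-")
        return cls(rep, search)

    def __str__(self) -> str:
        return f"{self.representation}-{self.search}"


@dataclass
class EvalResult:
    """recall@k summary over a query set."""

    per_k: dict[int, float]
    n_queries: int
    variant: str
    mass_filter_da: float | None = None
    n_uncovered: int = 0  # queries whose truth key is absent from the library


def _l2_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero vector cannot be L2-normalized")
    return X / norms


class SpectrumMatcher(BaseEstimator):
    """Library matcher over one representation x search variant.

    ``fit`` ingests the library spectra (normalizing intensities), builds the
    representation matrices and — for HNSW variants — the index.  ``query``
    returns ranked :class:`CandidateList` objects carrying cosine similarity.
    ``add`` expands a fitted library incrementally without any rebuild.

    An already-fitted ``embedder`` may be supplied to reuse a trained word
    model; otherwise the embedder is trained on the library spectra at fit
    time (the library doubles as the word2vec corpus).
    """

    def __init__(
        self,
        variant: str = "embedding-hnsw",
        vectorizer: BinnedVectorizer | None = None,
        embedder: PeakWordEmbedder | None = None,
        index: HNSWGraph | None = None,
        topk_prefilter: int = 100,
    ):
        self.variant = variant
        self.vectorizer = vectorizer
        self.embedder = embedder
        self.index = index
        self.topk_prefilter = topk_prefilter

    # -- building ----------------------------------------------------------

    def fit(
        self,
        X: list[Spectrum],
        y=None,
        keys: dict[str, str] | None = None,
        masses: dict[str, float] | None = None,
    ):
        if not X:
            raise ValueError("library is empty")
        v = MethodVariant.parse(self.variant)
        self.variant_ = v
        spectra = [normalize_spectrum(s).validate() for s in X]
        self.spectra_ = spectra
        self.ids_ = [s.id for s in spectra]
        if len(set(self.ids_)) != len(self.ids_):
            raise ValueError("duplicate spectrum ids in library")
        self.key_map_ = dict(keys) if keys else {s.id: s.id for s in spectra}
        self.mass_map_ = (
            dict(masses)
            if masses
            else {s.id: s.mol_mass for s in spectra if s.mol_mass is not None}
        )

        self.vectorizer_ = clone(self.vectorizer) if self.vectorizer else BinnedVectorizer()
        self.vectorizer_.fit(spectra)
        if self.embedder is not None:
            self.embedder_ = self.embedder
            if not hasattr(self.embedder_, "model_"):
                self.embedder_ = clone(self.embedder).fit(spectra)
        elif v.representation == "embedding":
            self.embedder_ = PeakWordEmbedder().fit(spectra)
        else:
            self.embedder_ = None

        self.binned_ = _l2_rows(self.vectorizer_.transform(spectra))
        self.embeddings_ = (
            self.embedder_.transform(spectra) if self.embedder_ is not None else None
        )

        self.index_ = None
        if v.search == "hnsw":
            base = self.index if self.index is not None else HNSWGraph()
            self.index_ = clone(base)
            self.index_.fit(self._rep_matrix(), self.ids_)
        return self

    def _rep_matrix(self) -> np.ndarray:
        if self.variant_.representation == "binned":
            return self.binned_
        if self.embeddings_ is None:
            raise ValueError("embedding representation requested but no embedder fitted")
        return self.embeddings_

    def _represent_queries(self, queries: list[Spectrum]) -> np.ndarray:
        queries = [normalize_spectrum(q).validate() for q in queries]
        if self.variant_.representation == "binned":
            return _l2_rows(self.vectorizer_.transform(queries))
        return self.embedder_.transform(queries)

    # -- querying ----------------------------------------------------------

    def query(
        self,
        queries: list[Spectrum],
        k: int = 10,
        mass_filter_da: float | None = None,
        ef: int | None = None,
    ) -> dict[str, CandidateList]:
        """Rank the library for each query spectrum.

        Brute variants return the exact top-k by cosine; HNSW variants the
        approximate top-k.  When ``mass_filter_da`` is given, the filter is
        applied post-search to a deeper list (``topk_prefilter`` candidates)
        and the top k survivors are returned.
        """
        if k > len(self.ids_):
            raise ValueError(f"k={k} exceeds library size {len(self.ids_)}")
        depth = max(k, self.topk_prefilter) if mass_filter_da is not None else k
        depth = min(depth, len(self.ids_))
        Q = self._represent_queries(queries)
        rep = self._rep_matrix()
        out: dict[str, CandidateList] = {}
        if self.variant_.search == "brute":
            sims_all = Q @ rep.T  # rows already L2-normalized
            for q, sims in zip(queries, sims_all):
                order = np.argsort(-sims, kind="stable")[:depth]
                cl = CandidateList(
                    [Candidate(self.ids_[i], float(sims[i])) for i in order]
                )
                out[q.id] = cl
        else:
            ef_eff = ef if ef is not None else max(self.index_.ef, depth)
            dists, idxs = self.index_.kneighbors(Q, k=depth, ef=ef_eff)
            for q, drow, irow in zip(queries, dists, idxs):
                cl = CandidateList(
                    [
                        Candidate(self.ids_[i], float(1.0 - d / 2.0))
                        for d, i in zip(drow, irow)
                    ]
                )
                out[q.id] = cl
        if mass_filter_da is not None:
            for q in queries:
                qmass = q.mol_mass
                if qmass is None:
                    warnings.warn(f"query {q.id!r} lacks mol_mass; mass filter skipped")
                    out[q.id] = CandidateList(out[q.id].entries[:k])
                    continue
                filtered = mass_filter(out[q.id], self.mass_map_, qmass, mass_filter_da)
                out[q.id] = CandidateList(filtered.entries[:k])
        return out

    # -- expansion ---------------------------------------------------------

    def add(self, new_spectra: list[Spectrum], keys=None, masses=None):
        """Incrementally expand the library (no rebuild of the index)."""
        if not new_spectra:
            return self
        new_spectra = [normalize_spectrum(s).validate() for s in new_spectra]
        dup = {s.id for s in new_spectra} & set(self.ids_)
        if dup:
            raise ValueError(f"duplicate spectrum ids: {sorted(dup)[:5]}")
        if self.variant_.representation == "binned":
            new_rep = _l2_rows(self.vectorizer_.transform(new_spectra))
            self.binned_ = np.vstack([self.binned_, new_rep])
        else:
            new_rep = self.embedder_.transform(new_spectra)
            new_binned = _l2_rows(self.vectorizer_.transform(new_spectra))
            self.binned_ = np.vstack([self.binned_, new_binned])
            self.embeddings_ = np.vstack([self.embeddings_, new_rep])
        if self.index_ is not None:
            self.index_.add(new_rep, [s.id for s in new_spectra])
        self.spectra_.extend(new_spectra)
        self.ids_.extend(s.id for s in new_spectra)
        for s in new_spectra:
            self.key_map_[s.id] = (keys or {}).get(s.id, s.id)
            m = (masses or {}).get(s.id, s.mol_mass)
            if m is not None:
                self.mass_map_[s.id] = m
        return self


def mass_filter(
    candidates: CandidateList,
    masses: dict[str, float],
    query_mass: float,
    tol: float,
) -> CandidateList:
    """Keep candidates whose molecular mass is within ``tol`` Da (inclusive).

    Order is preserved (re-ranking is positional among survivors); candidates
    without a known mass are excluded and counted on the returned list's
    ``n_massless`` attribute rather than raising.
    """
    if tol < 0:
        raise ValueError("mass tolerance must be >= 0")
    kept = []
    massless = 0
    for c in candidates:
        m = masses.get(c.id)
        if m is None:
            massless += 1
            continue
        if abs(m - query_mass) <= tol:
            kept.append(c)
    out = CandidateList(kept, metric=candidates.metric)
    out.n_massless = massless
    return out


def recall_at_k(
    results: dict[str, CandidateList],
    truth: dict[str, str],
    key_map: dict[str, str],
    ks: list[int],
) -> EvalResult:
    """recall@k over queries: truth matched on molecule canonical key.

    The top-k candidate *molecules* are the distinct keys of the top-k
    candidates (replicate spectra of one molecule count once).  Queries whose
    truth key does not exist in the library are excluded from the denominator
    and counted in ``n_uncovered``.
    """
    library_keys = set(key_map.values())
    hits = {k: 0 for k in ks}
    n_eval = 0
    n_uncovered = 0
    for qid, cl in results.items():
        true_key = truth[qid]
        if true_key not in library_keys:
            warnings.warn(f"query {qid!r}: truth key {true_key!r} not in library")
            n_uncovered += 1
            continue
        n_eval += 1
        seen: list[str] = []
        rank = None
        for c in cl:
            key = key_map.get(c.id, c.id)
            if key not in seen:
                seen.append(key)
            if key == true_key:
                rank = len(seen)
                break
        if rank is None:
            continue
        for k in ks:
            if rank <= k:
                hits[k] += 1
    per_k = {k: (hits[k] / n_eval if n_eval else 0.0) for k in ks}
    return EvalResult(
        per_k=per_k, n_queries=n_eval, variant="", n_uncovered=n_uncovered
    )


def top_k_overlap(a: CandidateList, b: CandidateList, k: int) -> float:
    """|top-k(a) intersect top-k(b)| / k — agreement of two rankings."""
    return len(set(a.ids()[:k]) & set(b.ids()[:k])) / k
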