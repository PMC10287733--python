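"""Hierarchical navigable small-world (HNSW) approximate nearest neighbors.

A from-scratch implementation of the layered proximity graph: each inserted
vector draws a level ``l = floor(-ln(u) * mL)`` from an exponentially decaying
distribution and is present in layers 0..l; upper layers hold long-range
links, layer 0 holds the dense graph.  Search descends greedily (ef = 1) from
the top-layer entry point and runs a best-first *search-layer* with a dynamic
candidate list of size ``ef`` on layer 0, returning the K nearest of that
list.  Insertion runs search-layer with ``ef_construction`` on each layer from
min(l, L) down to 0 and links the new node bidirectionally to M selected
neighbors (a diversity heuristic by default), pruning any overfull neighbor
list back to the degree bound (M, or M0 = 2M on layer 0).  Pruned edges are
removed from both endpoints, so every edge in the structure stays
bidirectional.

Distances are squared Euclidean; vectors are expected L2-normalized upstream,
which makes the distance ranking identical to cosine ranking.  All distance
computations against a node's neighbor list are batched through numpy, and
``n_distance_evals_`` counts individual vector-vector evaluations so that
query cost can be compared against the N evaluations of exact search.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .vectorize import Candidate, CandidateList

__all__ = [
    "HNSWParams",
    "HNSWGraph",
    "assign_level",
    "check_structure",
    "save_index",
    "load_index",
]

_INDEX_FORMAT_VERSION = 1


@dataclass(frozen=True)
class HNSWParams:
    """Index hyperparameters.

    Defaults (M = 64, ef_construction = 600, ef = 300) are sized for
    million-scale spectral-embedding libraries; small benchmarks typically
    use much smaller values.  ``m_l`` defaults to 1/ln(M), the standard
    level-generation multiplier.
    """

    M: int = 64
    ef_construction: int = 600
    ef: int = 300
    m_l: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.M < 2:
            raise ValueError("M must be >= 2")
        if self.ef_construction < self.M:
            raise ValueError("ef_construction must be >= M")
        if self.ef < 1:
            raise ValueError("ef must be >= 1")
        if self.m_l is not None and self.m_l < 0:
            raise ValueError("m_l must be >= 0")

    @property
    def level_multiplier(self) -> float:
        return 1.0 / math.log(self.M) if self.m_l is None else self.m_l


def assign_level(m_l: float, rng: np.random.Generator) -> int:
    """Draw a node level: floor(-ln(u) * m_l), u ~ Uniform(0, 1).

    P(level >= k) = exp(-k / m_l); the m_l -> 0 limit always yields 0.
    """
    if m_l <= 0:
        return 0
    u = rng.random()
    while u <= 0.0:  # guard the measure-zero draw
        u = rng.random()
    return int(-math.log(u) * m_l)


def expected_level_mean(m_l: float) -> float:
    """Closed-form E[floor(-ln(u) * m_l)] = 1 / (e^(1/m_l) - 1)."""
    if m_l <= 0:
        return 0.0
    return 1.0 / math.expm1(1.0 / m_l)


class HNSWGraph(BaseEstimator):
    """Sklearn-style HNSW index: ``fit`` builds, ``kneighbors`` queries.

    Supports incremental expansion via :meth:`add` (no rebuild), persistence
    via :meth:`save` / :meth:`load`, and deterministic construction given the
    seed and insertion order (distance ties break by insertion order).
    """

    def __init__(
        self,
        M: int = 64,
        ef_construction: int = 600,
        ef: int = 300,
        m_l: float | None = None,
        seed: int = 0,
        neighbor_selection: str = "heuristic",
    ):
        self.M = M
        self.ef_construction = ef_construction
        self.ef = ef
        self.m_l = m_l
        self.seed = seed
        self.neighbor_selection = neighbor_selection

    # -- lifecycle ---------------------------------------------------------

    @property
    def params(self) -> HNSWParams:
        return HNSWParams(self.M, self.ef_construction, self.ef, self.m_l, self.seed)

    def _reset(self, dim: int) -> None:
        if self.neighbor_selection not in ("heuristic", "simple"):
            raise ValueError(f"unknown neighbor_selection {self.neighbor_selection!r}")
        self.dim_ = dim
        cap = 1024
        self._X = np.zeros((cap, dim), dtype=np.float32)
        self._sq = np.zeros(cap, dtype=np.float32)
        self.count_ = 0
        self.ids_: list[str] = []
        self._id_to_idx: dict[str, int] = {}
        self.levels_: list[int] = []
        # graph_[layer][node] -> list of neighbor node indices
        self.graph_: list[dict[int, list[int]]] = []
        self.entry_point_: int = -1
        self.max_level_: int = -1
        self._rng = np.random.default_rng(self.seed)
        self._visit_stamp = np.zeros(cap, dtype=np.int64)
        self._visit_gen = 0
        self.n_distance_evals_ = 0

    def fit(self, X, ids: list[str] | None = None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        self._reset(X.shape[1])
        self.add(X, ids)
        return self

    def add(self, X, ids: list[str] | None = None):
        """Insert rows of X incrementally (also usable on a built index)."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.dim_:
            raise ValueError(f"expected (n, {self.dim_}) array, got {X.shape}")
        if ids is None:
            ids = [str(self.count_ + i) for i in range(X.shape[0])]
        if len(ids) != X.shape[0]:
            raise ValueError("ids length must match number of vectors")
        for row, ext_id in zip(X, ids):
            self.insert(ext_id, row)
        return self

    # -- distance plumbing -------------------------------------------------

    def _grow(self, n_needed: int) -> None:
        cap = self._X.shape[0]
        if n_needed <= cap:
            return
        new_cap = max(cap * 2, n_needed)
        for name in ("_X",):
            arr = np.zeros((new_cap, self.dim_), dtype=np.float32)
            arr[: self.count_] = getattr(self, name)[: self.count_]
            setattr(self, name, arr)
        sq = np.zeros(new_cap, dtype=np.float32)
        sq[: self.count_] = self._sq[: self.count_]
        self._sq = sq
        stamp = np.zeros(new_cap, dtype=np.int64)
        stamp[: self.count_] = self._visit_stamp[: self.count_]
        self._visit_stamp = stamp

    def _dists(self, nodes: np.ndarray, q: np.ndarray, q_sq: float) -> np.ndarray:
        """Batched squared Euclidean distances from q to stored nodes."""
        self.n_distance_evals_ += len(nodes)
        return self._sq[nodes] + q_sq - 2.0 * (self._X[nodes] @ q)

    # -- search ------------------------------------------------------------

    def _search_layer(
        self, q: np.ndarray, q_sq: float, entries: list[int], ef: int, layer: int
    ) -> list[tuple[float, int]]:
        """Best-first search with a dynamic candidate list of size ef.

        Returns up to ef (distance, node) pairs sorted ascending.  Ties in
        distance break by node index, i.e. insertion order.
        """
        adj = self.graph_[layer]
        self._visit_gen += 1
        gen = self._visit_gen
        stamp = self._visit_stamp
        ep = [n for n in entries if n in adj]
        if not ep:
            return []
        darr = self._dists(np.array(ep, dtype=np.int64), q, q_sq)
        cand: list[tuple[float, int]] = []  # min-heap of frontier
        res: list[tuple[float, int]] = []  # max-heap (negated) of results
        for n, d in zip(ep, darr):
            if stamp[n] == gen:
                continue
            stamp[n] = gen
            d = float(d)
            heapq.heappush(cand, (d, n))
            heapq.heappush(res, (-d, n))
        while len(res) > ef:
            heapq.heappop(res)
        while cand:
            d_c, c = heapq.heappop(cand)
            if d_c > -res[0][0] and len(res) >= ef:
                break
            nbrs = [n for n in adj[c] if stamp[n] != gen]
            if not nbrs:
                continue
            for n in nbrs:
                stamp[n] = gen
            darr = self._dists(np.array(nbrs, dtype=np.int64), q, q_sq)
            worst = -res[0][0]
            for n, d in zip(nbrs, darr):
                d = float(d)
                if len(res) < ef or d < worst:
                    heapq.heappush(cand, (d, n))
                    heapq.heappush(res, (-d, n))
                    if len(res) > ef:
                        heapq.heappop(res)
                    worst = -res[0][0]
        return sorted((-nd, n) for nd, n in res)

    def search_layer(
        self, q: np.ndarray, entries: list[int], ef: int, layer: int
    ) -> list[tuple[float, int]]:
        """Public search-layer: (distance, node-index) pairs, ascending."""
        if layer < 0 or layer > self.max_level_:
            return []
        q = np.asarray(q, dtype=np.float32)
        return self._search_layer(q, float(q @ q), entries, ef, layer)

    def kneighbors(
        self, Q, k: int = 10, ef: int | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """k nearest stored vectors for each row of Q.

        Returns (distances, indices) arrays of shape (n_queries, k) with
        squared Euclidean distances ascending; ``indices`` index ``ids_``.
        Requires k <= ef (the candidate list must hold at least k entries).
        """
        if self.count_ == 0:
            raise ValueError("index is empty")
        ef = self.ef if ef is None else ef
        if k > ef:
            raise ValueError(f"k={k} must not exceed ef={ef}")
        if k > self.count_:
            raise ValueError(f"k={k} exceeds index size {self.count_}")
        Q = np.atleast_2d(np.asarray(Q, dtype=np.float32))
        dists = np.empty((Q.shape[0], k))
        idxs = np.empty((Q.shape[0], k), dtype=np.int64)
        for i, q in enumerate(Q):
            res = self._knn_single(q, k, ef)
            dists[i] = [d for d, _ in res]
            idxs[i] = [n for _, n in res]
        return dists, idxs

    def _knn_single(self, q: np.ndarray, k: int, ef: int) -> list[tuple[float, int]]:
        q_sq = float(q @ q)
        ep = [self.entry_point_]
        for layer in range(self.max_level_, 0, -1):
            found = self._search_layer(q, q_sq, ep, 1, layer)
            if found:
                ep = [found[0][1]]
        res = self._search_layer(q, q_sq, ep, ef, 0)
        return res[:k]

    def knn_search(self, q: np.ndarray, k: int, ef: int | None = None) -> CandidateList:
        """kNN query returning external ids with squared Euclidean distances."""
        ef = self.ef if ef is None else ef
        if k > ef:
            raise ValueError(f"k={k} must not exceed ef={ef}")
        if self.count_ == 0:
            raise ValueError("index is empty")
        res = self._knn_single(np.asarray(q, dtype=np.float32), min(k, self.count_), ef)
        return CandidateList(
            [Candidate(self.ids_[n], float(d)) for d, n in res], metric="sqeuclidean"
        )

    # -- insertion ---------------------------------------------------------

    def _select_neighbors(
        self, candidates: list[tuple[float, int]], M: int
    ) -> list[int]:
        """Choose up to M links from ascending-distance candidates.

        The heuristic keeps a candidate only if it is closer to the base
        point than to every already-selected neighbor (direction diversity),
        then backfills with the nearest discarded candidates so that M links
        are used whenever M candidates exist; "simple" keeps the closest M.
        """
        if self.neighbor_selection == "simple" or len(candidates) <= M:
            return [n for _, n in candidates[:M]]
        n = len(candidates)
        idxs = np.fromiter((c for _, c in candidates), dtype=np.int64, count=n)
        d_base = np.fromiter((d for d, _ in candidates), dtype=np.float64, count=n)
        V = self._X[idxs].astype(np.float64)
        sq = self._sq[idxs].astype(np.float64)
        # pairwise distances among candidates, one matmul
        G = sq[:, None] + sq[None, :] - 2.0 * (V @ V.T)
        self.n_distance_evals_ += n * (n - 1) // 2
        d_min = np.full(n, np.inf)  # distance to nearest already-selected
        selected: list[int] = []
        discarded: list[int] = []
        for i in range(n):
            if len(selected) >= M:
                break
            if d_min[i] <= d_base[i]:
                discarded.append(i)
                continue
            selected.append(i)
            np.minimum(d_min, G[:, i], out=d_min)
        for i in discarded:  # keep pruned connections, nearest first
            if len(selected) >= M:
                break
            selected.append(i)
        return [int(idxs[i]) for i in selected]

    def _prune(self, node: int, layer: int, bound: int) -> None:
        adj = self.graph_[layer]
        nbrs = adj[node]
        if len(nbrs) <= bound:
            return
        arr = np.array(nbrs, dtype=np.int64)
        d = self._dists(arr, self._X[node], float(self._sq[node]))
        cands = sorted(zip(map(float, d), map(int, arr)))
        keep = self._select_neighbors(cands, bound)
        keep_set = set(keep)
        # removed edges disappear from both endpoints to stay bidirectional
        for n in nbrs:
            if n not in keep_set:
                try:
                    self.graph_[layer][n].remove(node)
                except ValueError:
                    pass
        adj[node] = keep

    def insert(self, ext_id: str, v: np.ndarray) -> "HNSWGraph":
        """Insert one vector under a new external id."""
        if ext_id in self._id_to_idx:
            raise ValueError(f"duplicate id {ext_id!r}")
        v = np.asarray(v, dtype=np.float32)
        if v.shape != (self.dim_,):
            raise ValueError(f"expected vector of length {self.dim_}, got {v.shape}")
        self._grow(self.count_ + 1)
        idx = self.count_
        self._X[idx] = v
        self._sq[idx] = float(v @ v)
        self.ids_.append(ext_id)
        self._id_to_idx[ext_id] = idx
        self.count_ += 1

        level = assign_level(self.params.level_multiplier, self._rng)
        self.levels_.append(level)

        if self.entry_point_ < 0:
            for lay in range(level + 1):
                self.graph_.append({idx: []})
            self.entry_point_ = idx
            self.max_level_ = level
            return self

        for lay in range(min(level, self.max_level_) + 1):
            self.graph_[lay].setdefault(idx, [])

        q_sq = float(self._sq[idx])
        ep = [self.entry_point_]
        for layer in range(self.max_level_, level, -1):
            found = self._search_layer(v, q_sq, ep, 1, layer)
            if found:
                ep = [found[0][1]]

        for layer in range(min(level, self.max_level_), -1, -1):
            cands = self._search_layer(v, q_sq, ep, self.ef_construction, layer)
            bound = 2 * self.M if layer == 0 else self.M
            # new nodes link up to the full layer allowance (2M on layer 0,
            # as in faiss's HNSW); backlinks are pruned to the same bound
            neighbors = self._select_neighbors(cands, bound)
            adj = self.graph_[layer]
            adj[idx] = list(neighbors)
            for n in neighbors:
                adj[n].append(idx)
                if len(adj[n]) > bound:
                    self._prune(n, layer, bound)
            ep = [n for _, n in cands] or neighbors

        if level > self.max_level_:
            for lay in range(self.max_level_ + 1, level + 1):
                self.graph_.append({idx: []})
            # link the new top-level node downward is already done; just move entry
            self.entry_point_ = idx
            self.max_level_ = level
        return self

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        save_index(self, path)

    @classmethod
    def load(cls, path) -> "HNSWGraph":
        return load_index(path)

    def reset_distance_counter(self) -> None:
        self.n_distance_evals_ = 0


def check_structure(index: HNSWGraph) -> list[str]:
    """Structural audit; returns a list of violation descriptions (empty = ok).

    Checks edge bidirectionality, degree bounds (M, M0 = 2M on layer 0),
    layer-membership monotonicity (a level-l node appears in layers 0..l),
    and that the entry point lives on the top layer.
    """
    problems: list[str] = []
    if index.count_ == 0:
        return problems
    M = index.M
    for layer, adj in enumerate(index.graph_):
        bound = 2 * M if layer == 0 else M
        for node, nbrs in adj.items():
            if len(nbrs) > bound:
                problems.append(f"layer {layer}: node {node} degree {len(nbrs)} > {bound}")
            if len(set(nbrs)) != len(nbrs):
                problems.append(f"layer {layer}: node {node} duplicate edges")
            if node in nbrs:
                problems.append(f"layer {layer}: node {node} self-loop")
            for n in nbrs:
                if node not in adj.get(n, []):
                    problems.append(f"layer {layer}: edge {node}->{n} not bidirectional")
    for node, level in enumerate(index.levels_):
        for lay in range(level + 1):
            if node not in index.graph_[lay]:
                problems.append(f"node {node} (level {level}) missing from layer {lay}")
        for lay in range(level + 1, len(index.graph_)):
            if node in index.graph_[lay]:
                problems.append(f"node {node} (level {level}) present on layer {lay}")
    if index.levels_[index.entry_point_] != index.max_level_:
        problems.append("entry point is not on the top layer")
    return problems


def save_index(index: HNSWGraph, path) -> None:
    """Persist the full structure: vectors, adjacency, entry point, params."""
    n = index.count_
    layers = []
    for adj in index.graph_:
        nodes = sorted(adj)
        layers.append({str(k): adj[k] for k in nodes})
    header = {
        "format_version": _INDEX_FORMAT_VERSION,
        "dim": index.dim_,
        "count": n,
        "entry_point": index.entry_point_,
        "max_level": index.max_level_,
        "params": {
            "M": index.M,
            "ef_construction": index.ef_construction,
            "ef": index.ef,
            "m_l": index.m_l,
            "seed": index.seed,
            "neighbor_selection": index.neighbor_selection,
        },
    }
    np.savez(
        path,
        header_json=np.array([json.dumps(header)]),
        vectors=index._X[:n],
        sqnorms=index._sq[:n],
        levels=np.array(index.levels_, dtype=np.int64),
        ids=np.array(index.ids_),
        graph_json=np.array([json.dumps(layers)]),
    )


def load_index(path) -> HNSWGraph:
    """Inverse of :func:`save_index`; raises on unknown format versions."""
    with np.load(path, allow_pickle=False) as data:
        if "header_json" not in data:
            raise ValueError(f"{path}: not a recognizable index file (missing header)")
        header = json.loads(str(data["header_json"][0]))
        if header.get("format_version") != _INDEX_FORMAT_VERSION:
            raise ValueError(
                f"{path}: unsupported index format version {header.get('format_version')!r}"
            )
        p = header["params"]
        index = HNSWGraph(
            M=p["M"],
            ef_construction=p["ef_construction"],
            ef=p["ef"],
            m_l=p["m_l"],
            seed=p["seed"],
            neighbor_selection=p["neighbor_selection"],
        )
        index._reset(header["dim"])
        n = header["count"]
        index._grow(max(n, 1))
        index._X[:n] = data["vectors"]
        index._sq[:n] = data["sqnorms"]
        index.count_ = n
        index.ids_ = [str(i) for i in data["ids"]]
        index._id_to_idx = {ext: i for i, ext in enumerate(index.ids_)}
        index.levels_ = [int(x) for x in data["levels"]]
        index.graph_ = [
            {int(k): [int(x) for x in v] for k, v in layer.items()}
            for layer in json.loads(str(data["graph_json"][0]))
        ]
        index.entry_point_ = header["entry_point"]
        index.max_level_ = header["max_level"]
        # rng state is not persisted; further inserts restart the level stream
        index._rng = np.random.default_rng(index.seed)
        return index
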