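"""Binned spectrum vectors and the weighted cosine similarity baseline.

The classical route to spectrum matching represents each spectrum as an
m-dimensional vector over fixed-width m/z bins, with entries weighted as

    w(bin k) = sum over peaks in bin k of  intensity**a * mz**b

(defaults a = 0.5, b = 2, the Stein & Scott weighting family), and scores a
pair of spectra by the cosine of their weighted vectors (WCS).  Because
vectors are nonnegative the score lies in [0, 1].  After L2 normalization the
squared Euclidean distance is 2 - 2*cos, so distance and cosine orderings
coincide — which is what lets a Euclidean ANN index stand in for cosine
ranking downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .msio import Spectrum

__all__ = [
    "WeightingScheme",
    "BinnedVectorizer",
    "Candidate",
    "CandidateList",
    "bin_spectrum",
    "weighted_cosine",
    "brute_force_rank",
]


@dataclass(frozen=True)
class WeightingScheme:
    """Weighting exponents and binning geometry for spectrum vectors.

    ``intensity_power`` (a) and ``mz_power`` (b) are applied per peak before
    summation into bins; bins are half-open ``[k*w, (k+1)*w)`` with 0-based
    indices, so the vector length is ``ceil(max_mz / bin_width)``.
    """

    intensity_power: float = 0.5
    mz_power: float = 2.0
    bin_width: float = 1.0
    max_mz: float = 1000.0

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.max_mz <= 0:
            raise ValueError("max_mz must be > 0")

    @property
    def n_bins(self) -> int:
        return int(math.ceil(self.max_mz / self.bin_width))


@dataclass(frozen=True)
class Candidate:
    id: str
    score: float  # cosine similarity in [0, 1]


@dataclass
class CandidateList:
    """Ranked retrieval output: descending similarity, unique ids."""

    entries: list[Candidate]
    metric: str = "cosine"

    def ids(self) -> list[str]:
        return [c.id for c in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def bin_spectrum(s: Spectrum, scheme: WeightingScheme) -> np.ndarray:
    """Weighted binned vector of one (normalized) spectrum.

    Peaks beyond ``max_mz`` are dropped (the caller can count them via
    :class:`BinnedVectorizer`); an empty or all-out-of-range spectrum raises.
    """
    if not s.peaks:
        raise ValueError(f"spectrum {s.id!r} has no peaks")
    v = np.zeros(scheme.n_bins)
    dropped = 0
    for p in s.peaks:
        k = int(p.mz // scheme.bin_width)
        if k >= scheme.n_bins:
            dropped += 1
            continue
        v[k] += p.intensity**scheme.intensity_power * p.mz**scheme.mz_power
    if not v.any():
        raise ValueError(f"spectrum {s.id!r}: no peaks within (0, {scheme.max_mz}]")
    return v


class BinnedVectorizer(BaseEstimator, TransformerMixin):
    """Transform spectra into weighted binned vectors (rows of a matrix).

    Parameters mirror :class:`WeightingScheme`.  ``fit`` only records the
    scheme; ``transform`` accepts a list of :class:`Spectrum` and returns an
    ``(n_spectra, n_bins)`` float array.  ``n_dropped_peaks_`` counts peaks
    beyond ``max_mz`` seen during the last transform.
    """

    def __init__(
        self,
        intensity_power: float = 0.5,
        mz_power: float = 2.0,
        bin_width: float = 1.0,
        max_mz: float = 1000.0,
    ):
        self.intensity_power = intensity_power
        self.mz_power = mz_power
        self.bin_width = bin_width
        self.max_mz = max_mz

    @property
    def scheme(self) -> WeightingScheme:
        return WeightingScheme(
            self.intensity_power, self.mz_power, self.bin_width, self.max_mz
        )

    def fit(self, X, y=None):
        self.scheme_ = self.scheme
        return self

    def transform(self, X: list[Spectrum]) -> np.ndarray:
        scheme = self.scheme
        out = np.empty((len(X), scheme.n_bins))
        dropped = 0
        for i, s in enumerate(X):
            n_in = sum(p.mz < scheme.max_mz for p in s.peaks)
            dropped += len(s.peaks) - n_in
            out[i] = bin_spectrum(s, scheme)
        self.n_dropped_peaks_ = dropped
        return out


def weighted_cosine(
    x: np.ndarray,
    y: np.ndarray,
    scheme_x: WeightingScheme | None = None,
    scheme_y: WeightingScheme | None = None,
) -> float:
    """Cosine similarity <x, y> / (||x|| ||y||) of two binned vectors.

    Symmetric, 1.0 for proportional vectors, 0.0 for disjoint bin support.
    Raises on zero vectors or mismatched weighting schemes.
    """
    if scheme_x is not None and scheme_y is not None and scheme_x != scheme_y:
        raise ValueError("weighting scheme mismatch between vectors")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"vector length mismatch: {x.shape} vs {y.shape}")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine undefined for a zero vector")
    return float(np.dot(x, y) / (nx * ny))


def brute_force_rank(
    q: np.ndarray, library: np.ndarray, ids: list[str], k: int
) -> CandidateList:
    """Exact top-k of a library by descending cosine similarity to ``q``.

    Ties are broken by ascending library id for reproducibility.  Equivalent
    to ascending squared Euclidean distance on L2-normalized vectors.
    """
    library = np.asarray(library, dtype=float)
    if library.ndim != 2 or library.shape[0] == 0:
        raise ValueError("library must be a non-empty 2-D array")
    if k > library.shape[0]:
        raise ValueError(f"k={k} exceeds library size {library.shape[0]}")
    q = np.asarray(q, dtype=float)
    nq = np.linalg.norm(q)
    if nq == 0:
        raise ValueError("cosine undefined for a zero query vector")
    norms = np.linalg.norm(library, axis=1)
    sims = (library @ q) / (norms * nq)
    order = sorted(range(len(ids)), key=lambda i: (-sims[i], ids[i]))[:k]
    return CandidateList([Candidate(ids[i], float(sims[i])) for i in order])
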