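"""Peak-word documents and word2vec-style spectral embeddings.

A spectrum becomes a short "document" whose words are its fragment positions
at integer precision — a fragment at m/z 89 is the word ``Peak@89``.  A CBOW
(or skip-gram) model with negative sampling is trained on a corpus of such
documents; because fragment order in a spectrum is meaningless, the context
window is set wider than any document (default 1000) so that every peak is
context for every other peak, and what the model learns is pure fragment
co-occurrence.  A spectrum-level embedding is the intensity-weighted sum of
its peak vectors, L2-normalized so squared Euclidean distance and cosine give
the same ranking downstream.

The trainer is a single-threaded numba kernel with all randomness (vector
initialization and negative-sample draws) taken from one seeded generator, so
training is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from sklearn.base import BaseEstimator, TransformerMixin

from .msio import Spectrum, normalize_spectrum, round_peaks

__all__ = [
    "PeakDocument",
    "EmbeddingParams",
    "PeakEmbeddingModel",
    "PeakWordEmbedder",
    "spectrum_to_document",
    "train_embedding_model",
    "embed_spectrum",
    "save_model",
    "load_model",
]


@dataclass
class PeakDocument:
    """One spectrum as unique peak words plus per-word intensity weights."""

    words: list[str]
    weights: list[float]

    def __post_init__(self):
        if len(self.words) != len(self.weights):
            raise ValueError("words and weights must align")


@dataclass(frozen=True)
class EmbeddingParams:
    """Word2vec hyperparameters.

    Defaults are the values tuned for million-scale EI library embedding:
    dimension 500, window 1000 (wider than any spectrum, so order-free),
    CBOW, 5 negative samples, initial learning rate 0.025 decaying 0.00025
    per epoch, 60 epochs.  ``alpha`` is the exponent on relative intensity
    used when summing peak vectors into a spectrum embedding.
    """

    dim: int = 500
    window: int = 1000
    architecture: str = "cbow"  # or "skipgram"
    negative: int = 5
    lr0: float = 0.025
    lr_decay: float = 0.00025
    epochs: int = 60
    min_count: int = 1
    alpha: float = 0.5
    precision: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.dim <= 0 or self.window < 1 or self.epochs < 1:
            raise ValueError("invalid embedding parameters")
        if self.architecture not in ("cbow", "skipgram"):
            raise ValueError(f"unknown architecture {self.architecture!r}")


@dataclass
class PeakEmbeddingModel:
    """Trained vocabulary: word -> d-vector, plus training provenance."""

    words: list[str]
    vectors: np.ndarray  # (V, d) float32 input vectors
    params: EmbeddingParams
    corpus_fingerprint: str
    word2idx: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.word2idx = {w: i for i, w in enumerate(self.words)}

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def __contains__(self, word: str) -> bool:
        return word in self.word2idx


def peak_word(mz: float, precision: int = 0) -> str:
    if precision == 0:
        return f"Peak@{int(round(mz))}"
    return f"Peak@{round(mz, precision)}"


def spectrum_to_document(
    s: Spectrum, precision: int = 0, alpha: float = 0.5
) -> PeakDocument:
    """Translate a spectrum into its peak-word document.

    Peaks are merged at the given integer precision; each distinct rounded
    m/z yields one word, ordered by ascending m/z (order is irrelevant to
    training).  The word weight is (relative intensity)**alpha, used later
    for the embedding summation, not during training.
    """
    if not s.peaks:
        raise ValueError(f"spectrum {s.id!r} has no peaks")
    merged = round_peaks(normalize_spectrum(s).peaks, precision)
    merged = [p for p in merged if p.intensity > 0]
    base = max(p.intensity for p in merged)
    words = [peak_word(p.mz, precision) for p in merged]
    weights = [(p.intensity / base) ** alpha for p in merged]
    return PeakDocument(words=words, weights=weights)


# --- training kernels -----------------------------------------------------
# Plain word2vec with negative sampling.  The sigmoid is clipped at +-6 (the
# reference implementation's convention); the CBOW hidden state is the mean of
# the context vectors and the context gradient is distributed evenly.


@njit(cache=True, fastmath=False)
def _train_cbow_epoch(w_in, w_out, words, offsets, negs, lr, window):
    d = w_in.shape[1]
    h = np.empty(d, dtype=np.float32)
    e = np.empty(d, dtype=np.float32)
    c_idx = 0
    for doc in range(offsets.shape[0] - 1):
        start = offsets[doc]
        n = offsets[doc + 1] - start
        if n < 2:
            c_idx += n
            continue
        for i in range(n):
            center = words[start + i]
            lo = i - window if i - window > 0 else 0
            hi = i + window + 1 if i + window + 1 < n else n
            cnt = 0
            for t in range(d):
                h[t] = 0.0
            for j in range(lo, hi):
                if j == i:
                    continue
                wj = words[start + j]
                for t in range(d):
                    h[t] += w_in[wj, t]
                cnt += 1
            inv = np.float32(1.0 / cnt)
            for t in range(d):
                h[t] *= inv
                e[t] = 0.0
            for sidx in range(negs.shape[1] + 1):
                if sidx == 0:
                    target = center
                    label = np.float32(1.0)
                else:
                    target = negs[c_idx, sidx - 1]
                    if target == center:
                        continue
                    label = np.float32(0.0)
                dot = np.float32(0.0)
                for t in range(d):
                    dot += h[t] * w_out[target, t]
                if dot > 6.0:
                    f = np.float32(1.0)
                elif dot < -6.0:
                    f = np.float32(0.0)
                else:
                    f = np.float32(1.0 / (1.0 + np.exp(-dot)))
                g = (label - f) * np.float32(lr)
                for t in range(d):
                    e[t] += g * w_out[target, t]
                    w_out[target, t] += g * h[t]
            for j in range(lo, hi):
                if j == i:
                    continue
                wj = words[start + j]
                for t in range(d):
                    w_in[wj, t] += e[t] * inv
            c_idx += 1


@njit(cache=True, fastmath=False)
def _train_sg_epoch(w_in, w_out, words, offsets, negs, lr, window):
    d = w_in.shape[1]
    e = np.empty(d, dtype=np.float32)
    c_idx = 0
    for doc in range(offsets.shape[0] - 1):
        start = offsets[doc]
        n = offsets[doc + 1] - start
        if n < 2:
            c_idx += n
            continue
        for i in range(n):
            center = words[start + i]
            lo = i - window if i - window > 0 else 0
            hi = i + window + 1 if i + window + 1 < n else n
            for j in range(lo, hi):
                if j == i:
                    continue
                ctx = words[start + j]
                for t in range(d):
                    e[t] = 0.0
                for sidx in range(negs.shape[1] + 1):
                    if sidx == 0:
                        target = center
                        label = np.float32(1.0)
                    else:
                        target = negs[c_idx, sidx - 1]
                        if target == center:
                            continue
                        label = np.float32(0.0)
                    dot = np.float32(0.0)
                    for t in range(d):
                        dot += w_in[ctx, t] * w_out[target, t]
                    if dot > 6.0:
                        f = np.float32(1.0)
                    elif dot < -6.0:
                        f = np.float32(0.0)
                    else:
                        f = np.float32(1.0 / (1.0 + np.exp(-dot)))
                    g = (label - f) * np.float32(lr)
                    for t in range(d):
                        e[t] += g * w_out[target, t]
                        w_out[target, t] += g * w_in[ctx, t]
                for t in range(d):
                    w_in[ctx, t] += e[t]
            c_idx += 1


def _corpus_fingerprint(corpus: list[PeakDocument]) -> str:
    h = hashlib.sha1()
    for doc in corpus:
        h.update(" ".join(doc.words).encode())
        h.update(b"\n")
    return h.hexdigest()


def train_embedding_model(
    corpus: list[PeakDocument], params: EmbeddingParams | None = None
) -> PeakEmbeddingModel:
    """Train a peak-word embedding model on a document corpus.

    Deterministic for a given seed (single-threaded).  Words with corpus
    frequency below ``min_count`` are excluded from the vocabulary; negative
    samples are drawn from the unigram distribution raised to 3/4.
    """
    if not corpus:
        raise ValueError("training corpus is empty")
    params = params or EmbeddingParams()

    freq: dict[str, int] = {}
    for doc in corpus:
        for w in doc.words:
            freq[w] = freq.get(w, 0) + 1
    vocab = sorted(
        (w for w, c in freq.items() if c >= params.min_count),
        key=lambda w: (-freq[w], w),
    )
    if not vocab:
        raise ValueError("no word meets min_count; vocabulary is empty")
    word2idx = {w: i for i, w in enumerate(vocab)}

    docs_idx = [
        np.array([word2idx[w] for w in doc.words if w in word2idx], dtype=np.int64)
        for doc in corpus
    ]
    offsets = np.zeros(len(docs_idx) + 1, dtype=np.int64)
    for i, d in enumerate(docs_idx):
        offsets[i + 1] = offsets[i] + len(d)
    flat = np.concatenate(docs_idx) if docs_idx else np.zeros(0, dtype=np.int64)
    n_centers = int(offsets[-1])

    rng = np.random.default_rng(params.seed)
    w_in = ((rng.random((len(vocab), params.dim), dtype=np.float32) - 0.5) / params.dim).astype(
        np.float32
    )
    w_out = np.zeros((len(vocab), params.dim), dtype=np.float32)

    counts = np.array([freq[w] for w in vocab], dtype=np.float64)
    noise = counts**0.75
    noise /= noise.sum()
    cum = np.cumsum(noise)

    kernel = _train_cbow_epoch if params.architecture == "cbow" else _train_sg_epoch
    # skip-gram draws one negative set per center and reuses it for each of the
    # center's context pairs; CBOW consumes one set per center as usual
    for epoch in range(params.epochs):
        lr = max(params.lr0 - epoch * params.lr_decay, params.lr0 * 1e-4)
        negs = np.searchsorted(cum, rng.random((max(n_centers, 1), params.negative))).astype(
            np.int64
        )
        kernel(w_in, w_out, flat, offsets, negs, lr, params.window)

    return PeakEmbeddingModel(
        words=vocab,
        vectors=w_in,
        params=params,
        corpus_fingerprint=_corpus_fingerprint(corpus),
    )


def embed_document(
    doc: PeakDocument, model: PeakEmbeddingModel, normalize: bool = True
) -> tuple[np.ndarray, int]:
    """Weighted sum of peak vectors; returns (vector, n_out_of_vocabulary)."""
    v = np.zeros(model.dim, dtype=np.float64)
    oov = 0
    for w, wt in zip(doc.words, doc.weights):
        i = model.word2idx.get(w)
        if i is None:
            oov += 1
            continue
        v += wt * model.vectors[i].astype(np.float64)
    if oov == len(doc.words):
        raise ValueError("all words out of vocabulary")
    if normalize:
        n = np.linalg.norm(v)
        if n > 0:
            v /= n
    return v, oov


def embed_spectrum(
    s: Spectrum, model: PeakEmbeddingModel, normalize: bool = True
) -> np.ndarray:
    """Spectral embedding: intensity-weighted sum of peak vectors.

    Out-of-vocabulary words are skipped; if every word is unknown a
    ``ValueError`` naming the spectrum is raised.
    """
    doc = spectrum_to_document(s, model.params.precision, model.params.alpha)
    try:
        v, _ = embed_document(doc, model, normalize=normalize)
    except ValueError as exc:
        raise ValueError(f"spectrum {s.id!r}: {exc}") from exc
    return v


class PeakWordEmbedder(BaseEstimator, TransformerMixin):
    """Sklearn-style wrapper: fit trains the word model, transform embeds.

    ``fit`` accepts a list of :class:`Spectrum` (the training corpus, usually
    the predicted library); ``transform`` maps spectra to L2-normalized
    ``(n, dim)`` embeddings.  ``n_oov_`` counts skipped unknown words from the
    last transform.
    """

    def __init__(
        self,
        dim: int = 500,
        window: int = 1000,
        architecture: str = "cbow",
        negative: int = 5,
        lr0: float = 0.025,
        lr_decay: float = 0.00025,
        epochs: int = 60,
        min_count: int = 1,
        alpha: float = 0.5,
        precision: int = 0,
        seed: int = 0,
    ):
        self.dim = dim
        self.window = window
        self.architecture = architecture
        self.negative = negative
        self.lr0 = lr0
        self.lr_decay = lr_decay
        self.epochs = epochs
        self.min_count = min_count
        self.alpha = alpha
        self.precision = precision
        self.seed = seed

    def _params(self) -> EmbeddingParams:
        return EmbeddingParams(
            dim=self.dim,
            window=self.window,
            architecture=self.architecture,
            negative=self.negative,
            lr0=self.lr0,
            lr_decay=self.lr_decay,
            epochs=self.epochs,
            min_count=self.min_count,
            alpha=self.alpha,
            precision=self.precision,
            seed=self.seed,
        )

    def fit(self, X: list[Spectrum], y=None):
        corpus = [spectrum_to_document(s, self.precision, self.alpha) for s in X]
        self.model_ = train_embedding_model(corpus, self._params())
        self.vocabulary_ = list(self.model_.words)
        return self

    def transform(self, X: list[Spectrum]) -> np.ndarray:
        out = np.empty((len(X), self.model_.dim))
        oov = 0
        for i, s in enumerate(X):
            doc = spectrum_to_document(s, self.precision, self.alpha)
            try:
                v, n_oov = embed_document(doc, self.model_)
            except ValueError as exc:
                raise ValueError(f"spectrum {s.id!r}: {exc}") from exc
            out[i] = v
            oov += n_oov
        self.n_oov_ = oov
        return out


# --- persistence ----------------------------------------------------------

_MODEL_FORMAT_VERSION = 1


def save_model(model: PeakEmbeddingModel, path) -> None:
    """Persist as npz: params JSON + vocabulary + vector table."""
    np.savez(
        path,
        format_version=np.array([_MODEL_FORMAT_VERSION]),
        params_json=np.array([json.dumps(model.params.__dict__)]),
        words=np.array(model.words),
        vectors=model.vectors,
        fingerprint=np.array([model.corpus_fingerprint]),
    )


def load_model(path) -> PeakEmbeddingModel:
    with np.load(path, allow_pickle=False) as data:
        if "format_version" not in data or int(data["format_version"][0]) != _MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported embedding-model format version in {path}")
        params = EmbeddingParams(**json.loads(str(data["params_json"][0])))
        return PeakEmbeddingModel(
            words=[str(w) for w in data["words"]],
            vectors=data["vectors"].astype(np.float32),
            params=params,
            corpus_fingerprint=str(data["fingerprint"][0]),
        )
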