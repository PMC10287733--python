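# Methods

This note documents the models implemented in `eimatch`, the parameter
choices that matter, what the synthetic benchmark does and does not
emulate, and the numerical decisions a maintainer would want recorded.

## Spectrum representation

All internal computation uses base-peak-normalized intensities in [0, 1];
raw MSP intensity scales (0–999 or percent) are normalized at ingest.
Peak m/z are rounded to a configurable precision (default: integer Da,
the unit resolution of standard EI libraries), merging duplicates by
intensity *sum* to conserve total ion signal. The MSP writer emits stored
intensity values verbatim so that write→read round-trips are exact at peak
level; a `scale=999` option produces the NIST convention instead, and the
output scale is therefore whatever the stored spectra carry — normalized
spectra round-trip as [0, 1] values.

### Weighted binned vectors

Bins are half-open intervals [k·w, (k+1)·w), 0-based, w = 1 Da by default,
up to 1000 Da (matching the library mass filter ceiling). Entry k holds
Σ intensityᵃ · mzᵇ over its peaks with defaults a = 0.5, b = 2, the
Stein–Scott weighting family; both exponents are configurable and all
baseline comparisons use one scheme. Cosine similarity of nonnegative
vectors lies in [0, 1]; on L2-normalized vectors squared Euclidean
distance is 2 − 2 cos, so metric and similarity orderings coincide —
the property that lets one HNSW implementation serve both representations.

## Peak-word embeddings

A spectrum becomes a document of words `Peak@<m/z>` (one word per distinct
rounded m/z). The word2vec model is CBOW with negative sampling
(skip-gram available), trained by a single-threaded numba kernel:

* window 1000 — wider than any spectrum, so every peak is context for
  every other; peak order carries no information and none is used;
* dimension 500, negative = 5, initial learning rate 0.025 with linear
  decay 0.00025 per epoch (floored at 10⁻⁴ of the initial rate),
  60 epochs, min_count 1 — the production defaults; desk-scale benchmarks
  use dim 64 with 10–30 epochs (see below);
* negative samples are drawn from the unigram distribution raised to 3/4;
  a draw equal to the target is skipped;
* the sigmoid is clipped at |x| = 6 (the reference word2vec convention);
  the CBOW hidden state is the mean of the context vectors and the
  context gradient is distributed evenly (divided by the context size);
* vocabulary order is frequency-descending with lexicographic tie-break;
  input vectors initialize uniform in [−0.5/d, 0.5/d), output vectors at
  zero; all randomness (init, negative draws) comes from one seeded
  generator, so training is bit-reproducible. Skip-gram draws one
  negative set per center word and reuses it across that center's
  context pairs.

A spectrum embedding is Σᵢ Iᵢᵅ·v(wᵢ) with α = 0.5 (relative intensities),
L2-normalized. Out-of-vocabulary words are skipped and counted; a
spectrum whose words are all unknown is an error naming the spectrum.
Document weights enter only this summation, not training, where word
frequency plays that role.

## HNSW index

Levels are drawn as ℓ = ⌊−ln(u)·m_L⌋ with m_L = 1/ln M by default, giving
P(ℓ ≥ k) = exp(−k/m_L) and E[ℓ] = 1/(e^{1/m_L} − 1) — the closed form the
Monte-Carlo tests check against. Search is the standard best-first
*search-layer* with a visited set, a frontier min-heap and a bounded
result heap of size ef, terminating when the nearest frontier candidate is
farther than the worst retained result. Queries descend with ef = 1
through layers L…1 and search layer 0 with the user ef (k ≤ ef enforced).

Insertion searches each layer from min(ℓ, L) to 0 with efConstruction and
links the new node to neighbors chosen by the diversity heuristic (keep a
candidate only if it is closer to the new point than to every
already-selected neighbor), backfilled with the nearest discarded
candidates up to the allowance — and the allowance for the *new* node is
the full per-layer bound: M above layer 0 and M₀ = 2M on layer 0, as in
faiss's HNSW. Linking only M neighbors at layer 0 measurably lowered
recall at the reference operating point (10k random 64-d unit vectors,
M = 16, efC = 200, ef = 100: ≈0.91 vs ≈0.95), so the wider initial linking
is the default. Overfull neighbor lists are re-selected by the same
heuristic; edges removed by pruning are deleted from *both* endpoints, so
every edge in the graph is bidirectional at all times — the structural
audit (`check_structure`) verifies bidirectionality, degree bounds, layer
membership of each node up to its level, and the entry point's level.

Distances are squared Euclidean, computed in float32 against batches of
neighbor vectors; an evaluation counter supports cost accounting against
the N evaluations of exhaustive search. Distance ties break by insertion
order (heap entries carry node index), making construction and search
deterministic for a fixed seed and insertion sequence. Persistence stores
vectors, stored square-norms (so reloaded searches are bit-identical),
adjacency, entry point, levels and parameters in an npz container with a
format-version header; the level-generator state is not persisted, so an
index expanded after reload draws levels from a restarted stream.

## Library preparation

The five rules: mass < 1000 Da (average molecular weight, exclusive
bound), elements ⊆ {H, C, O, N, P, S, Cl, F, Br, I, Si}, non-ionic (any
nonzero formal charge after sanitization; neutral multi-fragment records
such as hydrates are not ionic), Crippen logP in [−12, 24] (inclusive),
and deduplication — within each dataset, then across datasets in priority
order (earlier datasets keep their molecules). Molecule identity is the
full 27-character InChIKey (representation-robust); canonical-SMILES
equality is available as an alternative. All rule violations are
reported, not only the first, and filters are order-independent.

## Synthetic benchmark

The generator emulates the two statistical properties the matching stack
depends on, without any licensed data:

* **Fragment co-occurrence.** Fragments are grouped into 40 disjoint
  8-fragment *motifs* — the analogue of a substructure's fragmentation
  pattern. Each molecule expresses ~3 motifs drawn mostly from its
  structural class (25 classes, 5 characteristic motifs each, with a 50%
  chance of one motif from outside the class), each fragment with
  probability 0.75, plus private fragments; the total peak count is
  exactly max(3, Poisson(30)).
* **Positional variation.** A motif fragment has a base m/z (bases spaced
  3 Da apart so variants never collide) but is expressed at base ± 1 Da
  with probability 0.25 per side, per molecule. The same fragment
  therefore appears as adjacent peak words in similar contexts across the
  corpus, which is what lets the embedding learn that `Peak@m` and
  `Peak@m±1` are related — while any individual binned spectrum contains
  only its own variant, so unit m/z jitter in a query defeats binning but
  not the embedding. This is the synthetic analogue of systematic
  placement differences between predicted and measured spectra.

Intensities are Pareto-tailed (shape 1.2, capped at 10³ before
normalization); the metadata molecular mass is the largest fragment m/z
(the molecular-ion analogue), which makes mass-filter experiments exact.

The query noise model applies, in order: ±1 Da position jitter
(p = 0.25 per peak), multiplicative log-normal intensity error
(σ = 0.30), peak dropout (p = 0.10, floor of one retained peak), and
Poisson(3) spurious peaks at 0.5–5% of the base peak. These defaults were
calibrated once so the median weighted-cosine self-similarity of
perturbed vs. original spectra falls in the 0.7–0.95 band reported for
predicted-vs-measured EI spectra, and so the representation comparison is
informative at the 2,000-molecule benchmark scale. Zero noise returns
the input spectrum unchanged.

What the generator does *not* emulate: real fragmentation chemistry,
isotope envelopes, correlated intensity structure across molecules, mass
spectra of actual formulas, or retention information. Passing benchmarks
therefore demonstrate the correctness and the qualitative behavior of the
pipeline (embedding robustness to position jitter, index quality, filter
and expansion guarantees), not identification rates on real libraries.

## Benchmark protocol and sizes

Desk-scale sizes were chosen to keep the full suite within a few minutes
on one CPU while leaving the measured properties stable:

* HNSW quality: 10,000 random 64-d unit vectors, M = 16, efC = 200,
  ef = 100, 200 queries; recall@10 vs exact search, ef sweep {10, 20, 80},
  structural audit after each of four insertion batches.
* Matching benchmarks: 2,000-molecule library, 200 queries; embedding
  dim 64 with 30 epochs (10 epochs for the zero-noise self-retrieval
  check, where training quality is immaterial); index M = 16, efC = 200,
  ef = 100.
* Scaling: N = 1,000 → 64,000 random 16-d unit vectors with a light index
  (M = 8, efC = 64, ef = 32), 50 queries; distance evaluations per query
  are compared with the N of brute force.
* Level law: 100,000 draws; library accounting: key-level deduplication
  over synthetic disjoint key sets of the published component sizes.

## Known limitations

* The CBOW trainer is desk-scale: single-threaded and optimized for
  corpora of 10³–10⁵ documents, not the multi-million-document production
  setting (no hierarchical softmax, no frequent-word subsampling, no
  multi-worker training).
* On small corpora with dense co-occurrence, word vectors share a large
  common component (absolute cosines between embeddings run high); rank
  order, which is all retrieval uses, is unaffected.
* HNSW supports insertion only — no deletion or rebalancing — and the
  symmetric pruning policy, chosen to keep the bidirectionality invariant
  auditable, can leave individual nodes below the degree bound.
* The mass filter is applied post-search to a deeper candidate list
  (default 100), so a true molecule outside that list cannot be recovered
  by filtering.
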