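"""Synthetic EI-MS-like spectra with fragment co-occurrence structure.

Real EI libraries have two statistical features the matching stack depends on:

* recurrent fragments — the same substructures fragment into the same ions
  across structurally related molecules, so fragment peaks co-occur in
  blocks; this is what a peak-word embedding learns from;
* a measured-vs-predicted gap — query (measured) spectra differ from the
  library (predicted) spectra by intensity errors, missing peaks, spurious
  peaks and small m/z shifts.

The generator emulates both without any licensed data.  Fragments are
organized into *motifs* (blocks of ~8 fragment ions that co-occur, the
analogue of a substructure's fragmentation pattern); each molecule expresses
a few motifs — mostly drawn from its structural class — plus private
fragments.  A motif fragment has a base m/z but is expressed at base ± 1 Da
in different molecules (*positional variation*, the analogue of hydrogen
rearrangement / isotope bookkeeping differences between predictors and
instruments).  Because the same fragment therefore appears as adjacent peak
words in similar contexts across the corpus, a word embedding learns that
``Peak@m`` and ``Peak@m±1`` are related — whereas each individual binned
spectrum contains only its own variant, so unit m/z jitter in a query
defeats fixed binning but not the embedding.

Intensities are heavy-tailed (Pareto) and base-peak normalized; each
spectrum carries a metadata molecular mass equal to its largest fragment m/z
(the molecular-ion analogue).

The perturbation model (:func:`perturb_spectrum`) produces "measured"
queries: multiplicative log-normal intensity jitter, peak dropout, spurious
low-intensity peaks and ±1 Da position jitter.  Default noise is calibrated
so the median weighted-cosine self-similarity of perturbed vs. original
spectra falls in the 0.7-0.95 band typical of predicted-vs-measured EI
spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .msio import Peak, Spectrum, normalize_spectrum, round_peaks

__all__ = ["NoiseParams", "SynthParams", "make_library", "perturb_spectrum", "make_queries"]


@dataclass(frozen=True)
class NoiseParams:
    """Measured-vs-predicted perturbation model.

    intensity_sigma: sd of the log-normal multiplicative intensity jitter;
    dropout_p: per-peak removal probability (at least one peak always kept);
    spurious_rate: expected number of added low-intensity peaks (Poisson);
    mz_jitter_p: per-peak probability of a ±1 Da position shift.
    """

    intensity_sigma: float = 0.30
    dropout_p: float = 0.10
    spurious_rate: float = 3.0
    mz_jitter_p: float = 0.25

    def is_zero(self) -> bool:
        return (
            self.intensity_sigma == 0
            and self.dropout_p == 0
            and self.spurious_rate == 0
            and self.mz_jitter_p == 0
        )


@dataclass(frozen=True)
class SynthParams:
    """Library-generation settings.

    The defaults define the benchmark conditions used throughout the test
    suite: 2,000 molecules in 25 structural classes, ~30 peaks per spectrum
    drawn from 40 disjoint 8-fragment motifs (base positions 3 Da apart so
    ±1 variants never collide), Pareto-tailed intensities.
    """

    n_molecules: int = 2000
    mz_range: tuple[int, int] = (29, 989)
    peaks_per_spectrum: float = 30.0
    intensity_tail: float = 1.2  # Pareto shape; smaller = heavier tail
    n_motifs: int = 40
    motif_size: int = 8
    n_classes: int = 25
    class_motifs: int = 5  # motifs characteristic of one class
    motifs_per_molecule: int = 3
    extra_motif_p: float = 0.5  # chance of one motif from outside the class
    fragment_prob: float = 0.75  # per-fragment expression probability
    position_variation: float = 0.25  # P(fragment expressed at base+1) = P(base-1)
    slot_spacing: int = 3
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.mz_range
        if not (0 < lo < hi <= 1000):
            raise ValueError(f"mz_range must lie within (0, 1000], got {self.mz_range}")
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        for p in (self.extra_motif_p, self.fragment_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if not 0 <= self.position_variation <= 0.5:
            raise ValueError("position_variation must be in [0, 0.5]")

    @property
    def shared_fragment_pool(self) -> int:
        """Total number of distinct fragment ions across all motifs."""
        return self.n_motifs * self.motif_size


def make_library(
    p: SynthParams,
) -> tuple[list[Spectrum], dict[str, str], dict[str, float]]:
    """Generate the synthetic library.

    Returns ``(spectra, truth, masses)`` where ``truth`` maps spectrum id to
    its molecule canonical key and ``masses`` maps spectrum id to the metadata
    molecular mass.  Deterministic for a given seed.  The fragment count of
    each spectrum is exactly ``max(3, Poisson(peaks_per_spectrum))``.
    """
    rng = np.random.default_rng(p.seed)
    lo, hi = p.mz_range
    slots = np.arange(lo + 1, hi - 1, p.slot_spacing)
    need = p.n_motifs * p.motif_size
    if need > len(slots):
        raise ValueError(
            f"{p.n_motifs}x{p.motif_size} motif fragments need {need} slots, "
            f"only {len(slots)} available in {p.mz_range} at spacing {p.slot_spacing}"
        )
    base = rng.choice(slots, size=need, replace=False)
    motifs = base.reshape(p.n_motifs, p.motif_size)
    class_sets = [
        rng.choice(p.n_motifs, size=min(p.class_motifs, p.n_motifs), replace=False)
        for _ in range(p.n_classes)
    ]
    all_mz = np.arange(lo, hi + 1)

    spectra: list[Spectrum] = []
    truth: dict[str, str] = {}
    masses: dict[str, float] = {}
    for i in range(p.n_molecules):
        cls = i % p.n_classes
        mots = list(
            rng.choice(class_sets[cls], size=min(p.motifs_per_molecule, len(class_sets[cls])), replace=False)
        )
        if rng.random() < p.extra_motif_p:
            extra = int(rng.integers(p.n_motifs))
            if extra not in mots:
                mots.append(extra)
        n_target = max(3, int(rng.poisson(p.peaks_per_spectrum)))

        frag_bases: list[int] = []
        for m in mots:
            for b in motifs[m]:
                if rng.random() < p.fragment_prob:
                    frag_bases.append(int(b))
        rng.shuffle(frag_bases)
        frag_bases = frag_bases[:n_target]
        pv = p.position_variation
        deltas = rng.choice([-1, 0, 1], size=len(frag_bases), p=[pv, 1 - 2 * pv, pv])
        mzs = [b + int(d) for b, d in zip(frag_bases, deltas)]

        n_priv = n_target - len(mzs)
        if n_priv > 0:
            # private fragments keep >= 2 Da clearance from expressed ones so
            # the spectrum's peak count is exactly the Poisson draw
            used = np.array(sorted(set(mzs)))
            banned = np.unique(np.concatenate([used - 1, used, used + 1]))
            remaining = np.setdiff1d(all_mz, banned)
            mzs.extend(
                int(x) for x in rng.choice(remaining, size=min(n_priv, len(remaining)), replace=False)
            )
        mzs = sorted(set(mzs))
        intens = np.minimum(1.0 + rng.pareto(p.intensity_tail, size=len(mzs)), 1e3)
        peaks = round_peaks(
            [Peak(float(m), float(v)) for m, v in zip(mzs, intens)], precision=0
        )

        sid = f"LIB{i:05d}"
        key = f"M{i:05d}"
        mol_mass = max(pk.mz for pk in peaks)
        spec = normalize_spectrum(
            Spectrum(id=sid, peaks=peaks, name=key, mol_mass=mol_mass, source="synthetic")
        ).validate()
        spectra.append(spec)
        truth[sid] = key
        masses[sid] = mol_mass
    return spectra, truth, masses


def perturb_spectrum(s: Spectrum, noise: NoiseParams, rng: np.random.Generator) -> Spectrum:
    """Apply the measured-vs-predicted perturbation model to one spectrum.

    The truth key, id and metadata mass are untouched.  With all noise terms
    zero the input is returned unchanged (exact identity).
    """
    if noise.is_zero():
        return s
    lo = 14.0
    hi = max(p.mz for p in s.peaks)
    peaks: list[Peak] = []
    for p in s.peaks:
        mz = p.mz
        if noise.mz_jitter_p > 0 and rng.random() < noise.mz_jitter_p:
            mz = mz + (1.0 if rng.random() < 0.5 else -1.0)
            if mz <= 0:
                mz = p.mz
        inten = p.intensity
        if noise.intensity_sigma > 0:
            inten *= math.exp(rng.normal(0.0, noise.intensity_sigma))
        peaks.append(Peak(mz, inten))
    if noise.dropout_p > 0:
        kept = [pk for pk in peaks if rng.random() >= noise.dropout_p]
        if not kept:  # floor: retain the strongest peak
            kept = [max(peaks, key=lambda pk: pk.intensity)]
        peaks = kept
    n_spur = rng.poisson(noise.spurious_rate) if noise.spurious_rate > 0 else 0
    base = max(pk.intensity for pk in peaks)
    for _ in range(n_spur):
        mz = float(rng.integers(int(lo), int(hi) + 1))
        peaks.append(Peak(mz, float(base * rng.uniform(0.005, 0.05))))
    peaks = round_peaks(peaks, precision=0)
    return normalize_spectrum(replace(s, peaks=peaks, source="synthetic")).validate()


def make_queries(
    spectra: list[Spectrum],
    p: SynthParams,
    n_queries: int,
    seed: int | None = None,
) -> tuple[list[Spectrum], dict[str, str]]:
    """Draw ``n_queries`` library spectra and perturb them into queries.

    Returns the query spectra (ids ``Q<lib id>``) and a map from query id to
    the library spectrum id it was derived from.
    """
    rng = np.random.default_rng(p.seed + 1 if seed is None else seed)
    if n_queries > len(spectra):
        raise ValueError("n_queries exceeds library size")
    picks = rng.choice(len(spectra), size=n_queries, replace=False)
    queries = []
    origin: dict[str, str] = {}
    for i in picks:
        s = spectra[int(i)]
        q = perturb_spectrum(s, p.noise, rng)
        q = replace(q, id=f"Q{s.id}")
        queries.append(q)
        origin[q.id] = s.id
    return queries, origin
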