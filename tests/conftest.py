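import numpy as np
import pytest

from eimatch.msio import Peak, Spectrum, normalize_spectrum
from eimatch.synth import SynthParams, make_library


def random_spectrum(rng: np.random.Generator, sid: str, n_peaks: int = 12) -> Spectrum:
    mzs = np.sort(rng.choice(np.arange(20, 800), size=n_peaks, replace=False))
    intens = rng.uniform(0.5, 999.0, size=n_peaks)
    return Spectrum(
        id=sid,
        peaks=[Peak(float(m), float(i)) for m, i in zip(mzs, intens)],
        name=f"compound-{sid}",
        mol_mass=float(mzs[-1]),
    ).validate()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_spectra(rng):
    return [random_spectrum(rng, f"S{i:03d}") for i in range(50)]


@pytest.fixture(scope="session")
def small_library():
    """A 300-molecule synthetic library shared across tests (read-only)."""
    params = SynthParams(n_molecules=300, seed=7)
    spectra, truth, masses = make_library(params)
    return params, spectra, truth, masses


@pytest.fixture
def normalized_spectra(random_spectra):
    return [normalize_spectrum(s) for s in random_spectra]
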