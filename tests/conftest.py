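import numpy as np
import pytest

from pbnet.ms_io import Peak, Spectrum
from pbnet.spectral_similarity import SimilarityParams, preprocess
from pbnet.synthetic_fixtures import GeneratorConfig, generate_dataset


def random_spectrum(rng: np.random.Generator, feature_id: str = "S", n_peaks: int = 8) -> Spectrum:
    """A random spectrum with peaks safely below the precursor window."""
    precursor = float(rng.uniform(400.0, 900.0))
    mz = np.sort(rng.uniform(100.0, precursor - 25.0, size=n_peaks))
    intensity = rng.uniform(1.0, 100.0, size=n_peaks)
    return Spectrum(
        feature_id=feature_id,
        precursor_mz=precursor,
        charge=1,
        rt=float(rng.uniform(0.0, 20.0)),
        peaks=tuple(Peak(m, i) for m, i in zip(mz, intensity)),
    )


@pytest.fixture(scope="session")
def default_params() -> SimilarityParams:
    return SimilarityParams()


@pytest.fixture(scope="session")
def synthetic_dataset():
    """One default-condition benchmark shared across the session."""
    return generate_dataset(GeneratorConfig(seed=0))


def exhaustive_modified_cosine(a, b, params: SimilarityParams) -> float:
    """Independent oracle: optimum over all one-to-one candidate assignments.

    Enumerates every maximal conflict-free subset of candidate pairs by
    recursion; exponential, so only for small spectra.
    """
    from pbnet.spectral_similarity import _candidate_pairs

    pairs = _candidate_pairs(a, b, params)

    def best(idx: int, used_a: frozenset, used_b: frozenset) -> float:
        if idx == len(pairs):
            return 0.0
        i, j, prod, _, _ = pairs[idx]
        skip = best(idx + 1, used_a, used_b)
        if i in used_a or j in used_b:
            return skip
        take = prod + best(idx + 1, used_a | {i}, used_b | {j})
        return max(skip, take)

    return min(best(0, frozenset(), frozenset()), 1.0)
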