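import numpy as np
import pytest

from sigtrace import synthetic
from sigtrace.catalog import SignatureCatalog
from sigtrace.spectrum import Spectrum96


@pytest.fixture(scope="session")
def block5():
    """Five disjoint-support toy signatures."""
    return synthetic.block_catalog(5)


@pytest.fixture(scope="session")
def block2():
    return synthetic.block_catalog(2)


@pytest.fixture(scope="session")
def catalog10():
    return synthetic.random_catalog(10, seed=42)


def spectrum_from_mixture(
    catalog: SignatureCatalog,
    weights: np.ndarray,
    n: int,
    rng: np.random.Generator | None = None,
    sample_id: str = "X",
) -> Spectrum96:
    """Multinomial draw (or exact expectation when rng is None) of a mixture."""
    p = catalog.matrix.T @ np.asarray(weights, dtype=float)
    p = p / p.sum()
    if rng is None:
        counts = np.round(p * n).astype(np.int64)
    else:
        counts = rng.multinomial(n, p)
    return Spectrum96(sample_id, counts)


@pytest.fixture(scope="session")
def small_cohort():
    """3-type labeled cohort with planted signatures, reused across tests."""
    catalog = synthetic.random_catalog(5, seed=7)
    profiles = synthetic.default_profiles(
        catalog, type_names=["A", "B", "C"], specific_weight=0.4
    )
    spectra, genes, truth = synthetic.simulate_cohort(
        profiles, 30, catalog, seed=11, burden_dist=(np.log(500), 0.3)
    )
    return catalog, profiles, spectra, genes, truth
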