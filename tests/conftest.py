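import numpy as np
import pytest

from flocuscnv import LocusParams, assemble_locus_sequence


@pytest.fixture(scope="session")
def small_params() -> LocusParams:
    return LocusParams.small(seed=11)


@pytest.fixture(scope="session")
def loci(small_params):
    """Assembled small-scale loci for the three reference architectures."""
    return {h: assemble_locus_sequence(h, small_params)
            for h in ("A", "AG", "AGG")}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
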