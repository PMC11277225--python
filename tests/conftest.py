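import numpy as np
import pytest
from rdkit import RDLogger

from reprotox import SynthSpec, gen_toy_molecules, morgan_fingerprint

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def toy_records():
    """Sixty noise-free motif-labeled molecules (28 positive / 32 negative)."""
    return gen_toy_molecules(SynthSpec(n=60, positive_fraction=0.47,
                                       label_noise=0.0, seed=11))


@pytest.fixture(scope="session")
def toy_fingerprints(toy_records):
    return [morgan_fingerprint(r) for r in toy_records]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
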