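import numpy as np
import pytest

from knockin.dataset import curate
from knockin.synthetic import GeneratorConfig, generate


@pytest.fixture(scope="session")
def labelled_samples():
    """A mid-sized synthetic dataset with default planted signal, curated."""
    samples, _ = curate(generate(GeneratorConfig(seed=7, n_samples=80)))
    return samples


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))
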