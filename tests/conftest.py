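import numpy as np
import pytest

from bcrcnn.phantom import PhantomSpec, generate_case, generate_dataset


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(seed=42, n_cases=12)


@pytest.fixture(scope="session")
def small_case(small_spec):
    return generate_case(small_spec, 0)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory, small_spec):
    """A 12-case dual-plane VOC dataset on disk (8 train / 2 val / 2 test)."""
    d = tmp_path_factory.mktemp("voc")
    manifest = generate_dataset(small_spec, d, split_counts=(8, 2, 2))
    return d, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
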