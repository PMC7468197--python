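import pytest

from crucivir.pipeline import PipelineConfig
from crucivir.synthetic_data import SyntheticSpec, generate_genome, generate_reference_library


@pytest.fixture(scope="session")
def refs():
    return generate_reference_library()


@pytest.fixture(scope="session")
def planted():
    """One default synthetic genome with its truth record."""
    return generate_genome(SyntheticSpec(seed=1))


@pytest.fixture()
def fast_config():
    return PipelineConfig(compute_pi=False)
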