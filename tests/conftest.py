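import pytest

from ptbridge import (
    SyntheticConfig,
    default_bases,
    generate_dataset,
    load_table3,
)


@pytest.fixture(scope="session")
def table3():
    return load_table3()


@pytest.fixture(scope="session")
def para_meta_bases():
    return default_bases(("para", "meta"))


@pytest.fixture(scope="session")
def noiseless_records():
    """Full para+meta grid generated noiselessly from the packaged table."""
    return generate_dataset(SyntheticConfig(seed=7))
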