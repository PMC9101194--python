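import pytest

from pffuzzy import datasets


@pytest.fixture(scope="session")
def example_samples():
    return datasets.example_measurements()


@pytest.fixture(scope="session")
def example_specs():
    return datasets.example_specs()


@pytest.fixture(scope="session")
def printed_estimates():
    """Published point estimates per item (2-dp rounded)."""
    df = datasets.example_printed_statistics()
    return dict(zip(df["item_id"], df["pf_star"]))
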