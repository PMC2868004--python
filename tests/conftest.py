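import pytest

from probmde import CountLibrary, ExpressionDataset


@pytest.fixture
def toy_dataset() -> ExpressionDataset:
    """Three libraries of 100 tags with a gene rising across them."""
    return ExpressionDataset(
        libraries=[
            CountLibrary("L1", {"g1": 2, "g2": 10, "g3": 5}, 100),
            CountLibrary("L2", {"g1": 8, "g2": 10, "g3": 5}, 100),
            CountLibrary("L3", {"g1": 25, "g2": 10, "g3": 5}, 100),
        ]
    )


@pytest.fixture
def pair_dataset() -> ExpressionDataset:
    """Two libraries with one clearly up-regulated gene."""
    return ExpressionDataset(
        libraries=[
            CountLibrary("A", {"g1": 20, "g2": 5}, 100),
            CountLibrary("B", {"g1": 5, "g2": 20}, 100),
        ]
    )
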