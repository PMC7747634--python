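import numpy as np
import pytest

from bodysize_assembly.data_model import CountTable, SampleInfo


@pytest.fixture
def tiny_table() -> CountTable:
    """3 samples × 5 OTUs with mixed abundances and a zero column."""
    counts = np.array(
        [
            [5, 3, 0, 1, 0],
            [2, 0, 4, 1, 0],
            [0, 6, 1, 2, 0],
        ]
    )
    return CountTable(["s1", "s2", "s3"], ["o1", "o2", "o3", "o4", "o5"], counts)


@pytest.fixture
def transect_samples() -> list[SampleInfo]:
    """4 equally spaced sites with one environmental gradient 1..4."""
    return [
        SampleInfo(f"s{i + 1}", latitude=20.0 + i, longitude=110.0, env={"env1": float(i + 1)})
        for i in range(4)
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
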