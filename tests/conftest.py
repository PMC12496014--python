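import numpy as np
import pytest

from mvdst import SRTDataset


@pytest.fixture
def tiny_counts_ds() -> SRTDataset:
    """3 spots x 4 genes of raw counts with simple coordinates."""
    counts = np.array(
        [
            [2, 0, 1, 0],
            [0, 3, 0, 0],
            [5, 1, 0, 0],
        ],
        dtype=float,
    )
    return SRTDataset(
        expression=counts,
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
        spot_ids=["s1", "s2", "s3"],
        gene_ids=["gA", "gB", "gC", "gD"],
    )


@pytest.fixture
def normalized_ds(tiny_counts_ds) -> SRTDataset:
    from mvdst import normalize_log

    return normalize_log(tiny_counts_ds, target_sum=10.0)


def pytest_configure(config):
    config.addinivalue_line("markers", "slow: long-running end-to-end checks")
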