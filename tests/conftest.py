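import numpy as np
import pytest

from mapbench.genome_forge import random_contig


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_reference():
    """A 50 kb synthetic single-contig reference shared across tests."""
    return [random_contig("syn", 50_000, np.random.default_rng(77))]


@pytest.fixture(scope="session")
def benchmark_reference():
    """A 250 kb synthetic reference at the standard benchmark scale."""
    return [random_contig("syn", 250_000, np.random.default_rng(78))]


def semiglobal_edit_distance(read: str, window: str) -> int:
    """Independent brute-force oracle: full DP, free end gaps on the window.

    Deliberately written without traceback, banding or vectorization so it
    shares no code with the implementation under test.
    """
    n, m = len(read), len(window)
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        ri = read[i - 1]
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j - 1] + (ri != window[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return min(prev)
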