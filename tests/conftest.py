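import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def staged_two_gap_fixture():
    """Truth genome with two 3 kb gaps around a short (1.2 kb) contig and four
    exact reads arranged so that, at default thresholds, each gap is supported
    on exactly one side in the first pass and the residual N runs are spanned
    only afterwards."""
    rng = np.random.default_rng(42)
    truth = random_dna(rng, 15_200)
    a, b, c, d = 4_000, 7_000, 8_200, 11_200
    gapped = truth[:a] + "N" * (b - a) + truth[b:c] + "N" * (d - c) + truth[d:]
    from tilegap import LongRead, Scaffold

    reads = [
        LongRead("R1", truth[1_500:7_500]),
        LongRead("R2", truth[5_000:8_900]),
        LongRead("R3", truth[7_700:13_700]),
        LongRead("R4", truth[6_300:10_200]),
    ]
    return truth, Scaffold("s1", gapped), reads, (a, b, c, d)
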