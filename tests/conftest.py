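import pytest

from asepipe.read_simulator import FixtureSpec, generate_fixture
from asepipe.toy_aligner import AlignerParams

# Aligner geometry matching the desk-scale fixture reads (2 x 50 bp, 20 bp insert).
FIXTURE_ALIGNER = AlignerParams(k=20, max_mismatch=5, insert_size=20, insert_slack=10)


@pytest.fixture(scope="session")
def fixture20():
    """A 20-gene synthetic experiment: ~1 kb transcripts, 5 fixed SNPs each."""
    return generate_fixture(FixtureSpec(seed=20260924, n_genes=20))


@pytest.fixture(scope="session")
def fixture_small():
    """A fast 6-gene experiment with 3 replicates for pipeline-level tests."""
    return generate_fixture(
        FixtureSpec(seed=77, n_genes=6, n_replicates=3, depth=100)
    )
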