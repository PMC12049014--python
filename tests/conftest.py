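import pytest
from hypothesis import HealthCheck, settings

from rhtmap import (
    IndexParams,
    ScoringScheme,
    SequenceRecord,
    build_rht,
    simulate_reference,
)

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("det")

# strict 4-line FASTQ with record byte spans [0,16), [16,36), [36,52), [52,72)
FASTQ4 = (
    b"@r1\nACGT\n+\nIIII\n"
    b"@r2\nACGTAC\n+\nIIIIII\n"
    b"@r3\nTTTT\n+\nIIII\n"
    b"@r4\nGGGGGG\n+\nIIIIII\n"
)
FASTQ4_SPANS = [(0, 16), (16, 36), (36, 52), (52, 72)]


@pytest.fixture
def fastq4(tmp_path):
    path = tmp_path / "four.fq"
    path.write_bytes(FASTQ4)
    return str(path)


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def toy_rht():
    """Index of 'ACGTACGT' with k=2, L_win=4: windows [0,4) [2,6) [4,8) [6,8)."""
    return build_rht(SequenceRecord(id="toy", sequence="ACGTACGT"), IndexParams(k=2, L_win=4))


@pytest.fixture(scope="session")
def small_ref_index():
    """20 kb uniform reference indexed at k=11 for mapper-level tests."""
    ref = simulate_reference(20_000, 11)
    rht = build_rht(ref, IndexParams(k=11))
    return ref, rht
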