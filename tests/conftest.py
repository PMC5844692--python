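import numpy as np
import pytest

from pirnascape.rio import AlignmentRecord, GenomeIndex
from pirnascape.simkit import SimConfig, simulate_genome, simulate_pirna_reads


def make_record(
    contig="chr1",
    start=100,
    end=125,
    strand="+",
    copies=1,
    read_id="r",
    **kwargs,
):
    return AlignmentRecord(
        read_id=read_id, contig=contig, start=start, end=end, strand=strand,
        copies=copies, **kwargs,
    )


@pytest.fixture(scope="session")
def default_scenario():
    """Reference simulated scenario: genome, truth and piRNA reads."""
    config = SimConfig(seed=7)
    genome, truth = simulate_genome(config)
    reads = simulate_pirna_reads(genome, truth, config)
    return config, genome, truth, reads


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_genome():
    """Two short contigs with known sequence."""
    rng = np.random.default_rng(0)
    seqs = {
        "chr1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 12_000)]),
        "chr2": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 8_000)]),
    }
    return GenomeIndex(lengths={k: len(v) for k, v in seqs.items()}, sequences=seqs)
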