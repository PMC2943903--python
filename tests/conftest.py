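from __future__ import annotations

import pytest

from readbias import (
    BiasSpec,
    Read,
    background_from_reference,
    count_kmers_by_position,
    generate_genome,
    generate_reads,
)


def make_read(seq: str, quals: list[int] | None = None, rid: str = "r") -> Read:
    return Read(id=rid, seq=seq, quals=quals if quals is not None else [40] * len(seq))


@pytest.fixture(scope="session")
def genome_100k():
    return generate_genome(100_000, gc=0.5, seed=11)


@pytest.fixture(scope="session")
def unbiased_reads_100k(genome_100k):
    """100k zero-error reads sampled uniformly from the 100 kb genome."""
    return list(generate_reads(genome_100k, 100_000, 36, BiasSpec(), seed=12))


@pytest.fixture(scope="session")
def unbiased_table_k3(unbiased_reads_100k):
    return count_kmers_by_position(unbiased_reads_100k, 3)


@pytest.fixture(scope="session")
def reference_background_k3(genome_100k):
    return background_from_reference(genome_100k, 3, both_strands=True)


@pytest.fixture()
def fastq_writer(tmp_path):
    def write(lines: list[str], name: str = "reads.fastq"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        return path

    return write
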