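import numpy as np
import pytest

from immunostrata.io_tables import BlastHit, ProteinRecord


@pytest.fixture
def proteins_two_genes() -> list[ProteinRecord]:
    """Two genes: gA with two isoforms, gB with one."""
    return [
        ProteinRecord("gA.t1", "gA", "MKKRLLDEAG" * 10),
        ProteinRecord("gA.t2", "gA", "MKKRLLDEAG" * 6),
        ProteinRecord("gB.t1", "gB", "MGGSSTTNNQ" * 12),
    ]


def make_hit(
    query="gA.t1",
    subject="S1",
    species="sp",
    evalue=1e-10,
    bitscore=100.0,
    positives=50.0,
    align_len=80,
    qlen=100,
    slen=100,
) -> BlastHit:
    return BlastHit(
        query_protein=query,
        subject_protein=subject,
        subject_species=species,
        evalue=evalue,
        bitscore=bitscore,
        pct_positives=positives,
        align_len=align_len,
        query_len=qlen,
        subject_len=slen,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230901)
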