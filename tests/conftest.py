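import numpy as np
import pytest

from mitobait.seqio import Read, SeqRecord
from mitobait.simulate import (
    SimConfig,
    TruthSet,
    make_mitogenome,
    simulate_reads,
    tiny_gene_order,
)


def make_read(seq: str, rid: str = "r", q: int = 40, **kw) -> Read:
    return Read(rid, seq, [q] * len(seq), **kw)


@pytest.fixture(scope="session")
def tiny_cfg() -> SimConfig:
    """Small (~4.2 kb) genome, high mito fraction: fast full-pipeline runs."""
    return SimConfig(
        seed=1,
        gene_order=tiny_gene_order(),
        genome_length=4200,
        n_reads=2500,
        mito_fraction=0.7,
        contaminant_fraction=0.1,
        polycistron_baseline=80.0,
        error_rate=0.0,
    )


@pytest.fixture(scope="session")
def tiny_truth(tiny_cfg):
    genome, annotation = make_mitogenome(tiny_cfg)
    return TruthSet(genome, annotation)


@pytest.fixture(scope="session")
def tiny_readset(tiny_cfg, tiny_truth):
    return simulate_reads(tiny_truth, tiny_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
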