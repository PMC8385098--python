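import numpy as np
import pytest

from scapa.annotation import PasRecord, PasSet, UtrModel
from scapa.simulate import SimConfig, simulate_dataset


def make_pas(positions, strand="+", chrom="chr1", source="dbX", prefix="p"):
    """PasRecord list from bare positions (test helper)."""
    return [
        PasRecord(chrom=chrom, strand=strand, pos=int(p), source=source, id=f"{prefix}{i}")
        for i, p in enumerate(positions)
    ]


def make_pas_set(positions, strand="+", chrom="chr1", source="dbX", prefix="p"):
    return PasSet(records=make_pas(positions, strand, chrom, source, prefix))


def make_model(gene_id="gA", chrom="chr1", strand="+", blocks=((1000, 1200), (1500, 2500)),
               linked=()):
    stop = blocks[0][0] if strand == "+" else blocks[-1][1] - 1
    return UtrModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        chrom=chrom,
        strand=strand,
        stop_codon=stop,
        exon_blocks=[tuple(b) for b in blocks],
        linked_pas=list(linked),
    )


@pytest.fixture(scope="session")
def sim_small():
    """Small end-to-end synthetic dataset shared across tests."""
    cfg = SimConfig(n_genes=12, n_cells_per_stage=25, read_depth=15, seed=11)
    ann, dbs, reads = simulate_dataset(cfg)
    return cfg, ann, dbs, reads


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
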