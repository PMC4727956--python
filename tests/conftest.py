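import numpy as np
import pytest

from exoncap.baitdesign import TargetExon


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length, gc=0.5):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def make_exon(seq, exon_id="e1", gene_id="g1", chrom="chr1", start=0, frame=0):
    return TargetExon(exon_id=exon_id, gene_id=gene_id, chromosome=chrom,
                      start=start, end=start + len(seq), sequence=seq,
                      cds_frame_offset=frame)


@pytest.fixture
def small_dataset():
    """A small simulated study shared by integration-style tests."""
    from exoncap import simdata
    cfg = simdata.SimulationConfig(
        seed=11, n_genes=24,
        violations={"short": 1, "gc": 1, "non_unique": 1, "repeat": 1,
                    "high_copy": 1, "skewed_taxon": 1,
                    "contaminant_plastid": 1, "contaminant_mito": 1})
    return simdata.simulate_dataset(cfg)
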