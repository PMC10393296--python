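import numpy as np
import pytest

from ciliareg.seqmotif import GeneModel, build_pwm
from ciliareg.synthetic import SynthConfig


@pytest.fixture(scope="session")
def desk_cfg():
    return SynthConfig.desk_scale(seed=1)


@pytest.fixture(scope="session")
def desk_data(desk_cfg):
    """One desk-scale simulated dataset shared across tests: genome, gene
    models, battery, regulator + background peak sets, and truth tables."""
    from ciliareg.synthetic import synth_genome_and_genes, synth_peaksets

    genome, models, battery, gtruth = synth_genome_and_genes(desk_cfg)
    peaksets, ptruth = synth_peaksets(
        desk_cfg, models, battery, genome=genome,
        motif_truth=gtruth["planted_motifs"])
    return dict(genome=genome, models=models, battery=battery,
                gtruth=gtruth, peaksets=peaksets, ptruth=ptruth)


@pytest.fixture
def toy_genome():
    rng = np.random.default_rng(7)
    return {
        "chr1": "".join(rng.choice(list("ACGT"), size=5000)),
        "chr2": "".join(rng.choice(list("ACGT"), size=3000)),
    }


@pytest.fixture
def simple_pwm():
    # strongly prefers ACGT in order
    counts = np.array([
        [10, 0, 0, 0],
        [0, 10, 0, 0],
        [0, 0, 10, 0],
        [0, 0, 0, 10],
    ])
    return build_pwm(counts, pseudocount=0.5, name="acgt")


def make_model(gene_id="g1", chrom="chr1", strand="+", tss=2000, tls=None,
               start=None, end=None):
    if tls is None:
        tls = tss + 150 if strand == "+" else tss - 150
    if start is None:
        start = tss if strand == "+" else max(0, tss - 2000)
    if end is None:
        end = tss + 2000 if strand == "+" else tss
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand,
                     tss=tss, tls=tls, start=min(start, end), end=max(start, end))
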