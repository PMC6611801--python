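import numpy as np
import pytest

from glomlnc.annotation import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    LncRNAModel,
)
from glomlnc.simulate import SimulationConfig, generate_annotation


def make_gene(gene_id, chrom, start, end, strand="+"):
    return GeneModel(
        gene_id=gene_id,
        symbol=gene_id.capitalize(),
        interval=GenomicInterval(chrom, start, end, strand),
    )


def make_lnc(lnc_id, chrom, start, end, strand="+"):
    return LncRNAModel(
        lnc_id=lnc_id, interval=GenomicInterval(chrom, start, end, strand)
    )


def random_annotation(rng: np.random.Generator, n_genes=30, n_lnc=30, n_chroms=2,
                      chrom_length=500_000) -> AnnotationSet:
    """Unstructured random annotation (overlaps allowed) for oracle tests."""
    genes, lncs = [], []
    for i in range(n_genes):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, chrom_length - 50_000))
        length = int(rng.integers(1_000, 40_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(make_gene(f"g{i}", chrom, start, start + length, strand))
    for i in range(n_lnc):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, chrom_length - 10_000))
        length = int(rng.integers(200, 5_000))
        strand = "+" if rng.random() < 0.5 else "-"
        lncs.append(make_lnc(f"l{i}", chrom, start, start + length, strand))
    return AnnotationSet(genes=genes, lncrnas=lncs)


@pytest.fixture
def simple_annotation():
    """One + gene on chr1 with lncRNAs in each spatial situation."""
    genes = [make_gene("geneA", "chr1", 1000, 5000, "+")]
    lncs = [
        make_lnc("lnc_sense", "chr1", 2000, 3000, "+"),
        make_lnc("lnc_anti", "chr1", 2000, 3000, "-"),
        make_lnc("lnc_near", "chr1", 6000, 7000, "+"),
        make_lnc("lnc_far", "chr1", 56_000, 57_000, "+"),
    ]
    return AnnotationSet(genes=genes, lncrnas=lncs)


@pytest.fixture(scope="session")
def default_cohort():
    """Annotation + truth from the default simulation config (seed 1)."""
    cfg = SimulationConfig(seed=1)
    ann, truth = generate_annotation(cfg)
    return cfg, ann, truth
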