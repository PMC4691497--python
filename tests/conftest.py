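import numpy as np
import pytest

from h2azdyn import SimulationConfig, simulate_all
from h2azdyn.genome_model import ChromSizes, GeneModel


@pytest.fixture(scope="session")
def default_world():
    """One full synthetic dataset at the default study conditions (seed 7)."""
    return simulate_all(SimulationConfig())


@pytest.fixture
def toy_genome():
    """A 10 kb chromosome with one plus-strand single-exon gene at [2000, 5000)."""
    sizes = ChromSizes({"chr1": 10_000})
    gene = GeneModel(gene_id="geneA", chrom="chr1", strand="+", tss=2000, tes=5000,
                     exons=((2000, 5000),))
    return [gene], sizes


def random_toy_annotation(seed: int, chrom_length: int = 30_000, n_genes: int = 3):
    """Small random annotation for property tests: genes may overlap freely."""
    rng = np.random.default_rng(seed)
    sizes = ChromSizes({"chrA": chrom_length, "chrB": chrom_length // 2})
    genes = []
    for i in range(n_genes):
        chrom = "chrA" if rng.random() < 0.7 else "chrB"
        length = int(rng.integers(1_500, 8_000))
        lo = int(rng.integers(0, sizes[chrom] - length))
        hi = lo + length
        strand = "+" if rng.random() < 0.5 else "-"
        # 1-3 exons; sometimes a CDS, sometimes non-coding
        n_exons = int(rng.integers(1, 4))
        cuts = np.sort(rng.choice(np.arange(lo + 1, hi), size=2 * n_exons - 2,
                                  replace=False)) if n_exons > 1 else np.array([])
        bounds = [lo, *cuts.tolist(), hi]
        exons = tuple((bounds[2 * j], bounds[2 * j + 1]) for j in range(n_exons))
        cds = None
        if rng.random() < 0.7:
            a, b = sorted(rng.integers(lo, hi, size=2).tolist())
            cds = (a, b + 1)
        tss, tes = (lo, hi) if strand == "+" else (hi, lo)
        genes.append(GeneModel(gene_id=f"g{i}", chrom=chrom, strand=strand,
                               tss=tss, tes=tes, exons=exons, cds=cds))
    return genes, sizes
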