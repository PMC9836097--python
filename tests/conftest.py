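import numpy as np
import pytest

from skewscape.genome_io import CircularChromosome, GeneAnnotation, GenomeRecord
from skewscape.synthetic import SyntheticSpec, generate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


def random_sequence(rng, n, letters="ACGT"):
    return "".join(rng.choice(list(letters), size=n))


@pytest.fixture
def toy_record():
    """12 bp circular chromosome with three genes, one wrapping the origin."""
    chrom = CircularChromosome(id="toy", sequence="ACGTACGTGGCC", ori=1)
    genes = [
        GeneAnnotation(gene_id="gA", start=2, end=4, strand="+"),
        GeneAnnotation(gene_id="gB", start=7, end=9, strand="-"),
        GeneAnnotation(gene_id="gC", start=11, end=1, strand="+"),  # wraps
    ]
    return GenomeRecord(chromosome=chrom, genes=genes)


@pytest.fixture(scope="session")
def small_synthetic():
    """One modest genome with genes, a planted high-skew segment and a cluster."""
    spec = SyntheticSpec(
        length=120_000,
        n_genes=60,
        skew_amplitude=0.1,
        peak_segments=[(10_000, 30_000, 0.3)],
        cluster=(60_000, 5, "+"),
        seed=42,
    )
    return generate_genome(spec)
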