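import numpy as np
import pytest

from lowcov import MultiplexReadSet, TruthSet, VariantSite, simulate_reads, simulate_truth


@pytest.fixture(scope="session")
def small_truth() -> TruthSet:
    return simulate_truth(4, 60, ("uniform", 0.1, 0.5), seed=101)


@pytest.fixture(scope="session")
def small_reads(small_truth):
    return simulate_reads(small_truth, 5.0, 0.01, seed=202)


@pytest.fixture
def one_site_truth() -> TruthSet:
    """A single heterozygous sample at a single A/G site."""
    site = VariantSite("chr1", 100, "A", "G")
    return TruthSet(
        sites=[site],
        genotypes=np.array([[1]], dtype=np.int8),
        allele_freqs=np.array([0.5]),
        samples=["S000"],
        seed=0,
    )


def make_reads(truth: TruthSet, alleles, mapq=None, proper_pair=None,
               secondary=None, duplicate=None, site=0) -> MultiplexReadSet:
    """Hand-build a read set for sample 0 at one site with explicit flags."""
    n = len(alleles)
    return MultiplexReadSet(
        samples=list(truth.samples),
        fragment_id=np.arange(n, dtype=np.int64),
        true_sample=np.zeros(n, dtype=np.int32),
        assigned_sample=np.zeros(n, dtype=np.int32),
        site=np.full(n, site, dtype=np.int32),
        allele=np.asarray(alleles, dtype=np.int8),
        mapq=None if mapq is None else np.asarray(mapq, dtype=np.uint8),
        proper_pair=None if proper_pair is None else np.asarray(proper_pair, dtype=bool),
        secondary=None if secondary is None else np.asarray(secondary, dtype=bool),
        duplicate=None if duplicate is None else np.asarray(duplicate, dtype=bool),
    )
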