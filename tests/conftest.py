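import numpy as np
import pytest

from demodfe.sumstats import HaplotypeSample


@pytest.fixture
def four_pop_sample():
    """Small deterministic 4-population sample (8 haplotypes per pop)."""
    rng = np.random.default_rng(7)
    n_hap, n_sites, length = 32, 40, 20_000
    positions = np.sort(rng.choice(length, size=n_sites, replace=False))
    freqs = rng.uniform(0.05, 0.6, size=n_sites)
    geno = (rng.random((n_hap, n_sites)) < freqs).astype(np.uint8)
    # ensure every site is polymorphic somewhere
    geno[0, geno.sum(axis=0) == 0] = 1
    pops = np.repeat(["AFR", "EUR", "EAS", "SAS"], 8)
    return HaplotypeSample(positions=positions.astype(float), genotypes=geno,
                           populations=pops, length=length)


@pytest.fixture
def tiny_sample():
    """The 4-haplotype, 3-site toy used for hand-computed statistics."""
    geno = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1]], dtype=np.uint8)
    return HaplotypeSample(positions=[100.0, 200.0, 300.0], genotypes=geno,
                           populations=np.repeat("AFR", 4), length=1_000)
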