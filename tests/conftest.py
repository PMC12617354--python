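import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from ldne import GenotypePanel, SampleRecord, VariantRecord, make_fixture_panel
from ldne.panel import MISSING


@pytest.fixture
def toy_panel() -> GenotypePanel:
    return make_fixture_panel("ld_toy_3snp")


@pytest.fixture
def qc_panel() -> GenotypePanel:
    return make_fixture_panel("qc_edge_cases")


def random_panel(rng: np.random.Generator, n: int = 12, m: int = 8,
                 missing_rate: float = 0.1, n_chrom: int = 2) -> GenotypePanel:
    """A random small panel with arbitrary frequencies and missingness."""
    freqs = rng.uniform(0.0, 1.0, size=m)
    g = (rng.random((n, m)) < freqs).astype(np.int8)
    g += (rng.random((n, m)) < freqs).astype(np.int8)
    g[rng.random((n, m)) < missing_rate] = MISSING
    # keep every column's allele1 observable so a text-dialect round trip
    # cannot flip orientation (text carries no dosage-allele marker)
    for j in range(m):
        called = g[:, j][g[:, j] != MISSING]
        if called.size == 0 or called.min() == 2:
            g[0, j] = 1
    variants = [
        VariantRecord(chrom=str(1 + j % n_chrom), vid=f"v{j}",
                      cm=0.0, bp=10_000 + 7919 * j, allele1="A", allele2="B")
        for j in range(m)
    ]
    samples = [SampleRecord("r", f"s{i}") for i in range(n)]
    return GenotypePanel(samples=samples, variants=variants, genotypes=g)
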