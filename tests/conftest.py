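import numpy as np
import pytest

from phylopop.simulate import simulate_coalescent, two_population_model
from phylopop.types import GenotypeTable, empty_site_frame


def make_table(genotypes, chrom="c1", positions=None, seq_length=None,
               annotations=None, vartypes=None, samples=None):
    """Build a small GenotypeTable from a nested genotype list
    (sites x samples x 2) with clean quality metrics."""
    g = np.array(genotypes, dtype=np.int8)
    n, m = g.shape[:2]
    sites = empty_site_frame(n)
    sites["chrom"] = chrom if isinstance(chrom, str) else list(chrom)
    sites["pos"] = (
        np.arange(1, n + 1) * 10 if positions is None else np.asarray(positions)
    )
    if annotations is not None:
        sites["annotation"] = annotations
    if vartypes is not None:
        sites["vartype"] = vartypes
    dp = np.full((n, m), 30, dtype=np.int32)
    gq = np.full((n, m), 99, dtype=np.int32)
    ad = np.zeros((n, m, 2), dtype=np.int32)
    hom_ref = (g[:, :, 0] == 0) & (g[:, :, 1] == 0)
    hom_alt = (g[:, :, 0] > 0) & (g[:, :, 1] > 0)
    het = ~hom_ref & ~hom_alt
    ad[:, :, 0][hom_ref] = 30
    ad[:, :, 1][hom_alt] = 30
    ad[:, :, 0][het] = 15
    ad[:, :, 1][het] = 15
    return GenotypeTable(
        sites=sites,
        genotypes=g,
        gq=gq,
        dp=dp,
        ad=ad,
        samples=samples or [f"s{i}" for i in range(m)],
        seq_length=seq_length,
    )


@pytest.fixture(scope="session")
def table_factory():
    return make_table


@pytest.fixture(scope="session")
def two_pop_dataset():
    """A modest two-population isolation dataset reused across tests."""
    model = two_population_model(10000, 20000, n_loci=80, locus_length=2000)
    return simulate_coalescent(model, {"A": 6, "B": 6}, seed=42)
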