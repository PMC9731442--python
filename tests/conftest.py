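import numpy as np
import pytest

from magpop.counts import AlleleCountTable
from magpop.simulate import SimulationConfig, simulate_annotation, simulate_metapopulation


def make_counts(ref, pool_counts, contig="ctg1", start=10, spacing=5):
    """Build an AlleleCountTable from explicit per-pool A:T:C:G:N:del rows.

    ``pool_counts``: list over loci of lists over pools of 6-tuples.
    """
    n_loci = len(pool_counts)
    counts = np.array(pool_counts, dtype=np.int64)
    return AlleleCountTable(
        np.array([contig] * n_loci, dtype=object),
        np.arange(start, start + spacing * n_loci, spacing)[:n_loci],
        np.array(list(ref), dtype=object),
        counts,
    )


@pytest.fixture(scope="session")
def neutral_dataset():
    """Small neutral island-model dataset shared across tests."""
    return simulate_metapopulation(
        SimulationConfig(n_pools=4, n_loci=1200, fst_target=0.05, coverage_mean=100, seed=42)
    )


@pytest.fixture(scope="session")
def annotation_fixture():
    """Toy genome + mutations with 50/30/15/5 context mix and Ts/Tv 1.5."""
    annotation, mutations = simulate_annotation(
        n_genes=24,
        tstv_ratio=1.5,
        effect_mix=(0.46, 0.533, 0.007),
        seed=7,
        context_mix=(0.5, 0.3, 0.15, 0.05),
        n_mutations=3000,
    )
    return annotation, mutations
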