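import pytest

from panpav.simulate import SimConfig, simulate_all


def small_config(seed=11, **overrides):
    """A fast cohort: paper-like group structure, few genes."""
    defaults = dict(
        group_sizes={"IMP_A": 40, "IMP_M": 30, "LDR_A": 30, "LDR_M": 25, "WT": 5},
        n_core_genes=60,
        n_softcore_genes=0,  # infeasible below 100 accessions
        n_shell_genes=60,
        n_cloud_genes=5,
        n_selected_genes=10,
        n_trait_genes=3,
        n_reference_contigs=8,
        n_novel_contigs=8,
        n_partial_contigs=5,
        n_contaminant_contigs=3,
        n_chromosomes=3,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_all(small_config())


@pytest.fixture(scope="session")
def sequence_bundle():
    """Small cohort with reference/contig sequences generated."""
    return simulate_all(small_config(seed=17, n_core_genes=30, n_shell_genes=30))
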