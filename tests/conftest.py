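import pytest

from ribomine5s import (AssemblyConfig, SimulationConfig, assemble_units,
                        build_tandem_array, filter_reads, generate_ribotype_set,
                        make_probes, simulate_reads)


@pytest.fixture(scope="session")
def small_sim():
    """Error-free 3-ribotype locus at 100x with its simulated library."""
    cfg = SimulationConfig(seed=7, n_ribotypes=3, min_pairwise_distance=2,
                           array_copies=18)
    ancestor, ribotypes, truth = generate_ribotype_set(cfg)
    array = build_tandem_array(ribotypes, truth, cfg)
    library = simulate_reads(array, cfg)
    return cfg, ancestor, ribotypes, truth, array, library


@pytest.fixture(scope="session")
def small_units(small_sim):
    """Repeat units assembled from the small locus (filtered reads, k=31)."""
    cfg, _, ribotypes, truth, _, library = small_sim
    filtered = filter_reads(library, make_probes(truth.cds))
    units = assemble_units(filtered, truth.cds,
                           AssemblyConfig(min_kmer_coverage=5))
    return units, ribotypes, truth, library
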