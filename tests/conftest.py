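import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

try:
    from hypothesis import settings

    settings.register_profile("suite", derandomize=True, max_examples=40,
                              deadline=None)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session", autouse=True)
def _warm_numba():
    """Compile the alignment kernel once up front."""
    from probeforge.simsearch import best_local_alignment

    best_local_alignment("ACGTACGTACGT", "ACGTACGTACGT")


@pytest.fixture(scope="session")
def sim_design():
    """One full synthetic design input (seed 1), shared across tests."""
    from probeforge.synthfix import SimConfig, simulate_annotated_genome

    return simulate_annotated_genome(SimConfig(seed=1))


@pytest.fixture(scope="session")
def sim_hits(sim_design):
    """Precomputed hit tables for the shared design input."""
    from probeforge.simsearch import SearchParams, local_search

    sp = SearchParams()
    return (
        local_search(sim_design.queries, sim_design.genome_a, sp),
        local_search(sim_design.queries, sim_design.genome_b, sp),
    )


@pytest.fixture(scope="session")
def sim_result(sim_design, sim_hits):
    """Design cascade output on the shared input."""
    from probeforge.probedesign import design_probe_set

    hits_a, hits_b = sim_hits
    return design_probe_set(
        sim_design.genome_a, sim_design.genome_b, sim_design.queries,
        hits_a=hits_a, hits_b=hits_b,
    )
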