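"""Shared fixtures: one small simulated panel reused by read-only tests."""
import pytest

from hdacsig.simulate import SimulationSpec, simulate_panel


@pytest.fixture(scope="session")
def small_spec():
    return SimulationSpec(
        n_genes=600, n_samples=90, n_pathways=6, genes_per_pathway=20,
        n_causal_pathways=2, effect_size=1.5, n_drugs=4, seed=7,
    )


@pytest.fixture(scope="session")
def small_panel(small_spec):
    """(expression, response, mutations, pathways, truth) — do not mutate."""
    return simulate_panel(small_spec)
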