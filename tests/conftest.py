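import pytest

from codonshift import SimulationConfig, builtin_code, simulate_panel


@pytest.fixture(scope="session")
def small_standard_study():
    """A small standard-code study shared by read-only tests."""
    cfg = SimulationConfig(seed=11, n_genes=4, gene_length_range=(80, 120))
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def uga_trp_study():
    """A study under a UGA->Trp / AUA->Met mitochondrial code."""
    cfg = SimulationConfig(seed=7, focal_code=builtin_code("pedinomonadales-mito"))
    return simulate_panel(cfg)
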