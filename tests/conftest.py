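import numpy as np
import pytest

from homeokit import sim


@pytest.fixture(scope="session")
def clean_dataset():
    """Small synthetic dataset without fragment noise (chimera/FV/missing)."""
    params = sim.SimParams(
        seq_length=300_000, n_accessions_per_pop=3, seed=11,
        missing_rate=0.0, chimera_rate=0.0, fv_rate=0.0,
    )
    panels = sim.simulate_parental_panels(params)
    unphased, truth = sim.simulate_tetraploids(panels, params)
    fragments = sim.emit_fragments(truth, unphased, params)
    return dict(params=params, panels=panels, unphased=unphased, truth=truth, fragments=fragments)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Synthetic dataset with chimeric fragments, FV flags and missing data."""
    params = sim.SimParams(
        seq_length=500_000, n_accessions_per_pop=3, seed=23,
        missing_rate=0.05, chimera_rate=0.2, fv_rate=0.02,
    )
    panels = sim.simulate_parental_panels(params)
    unphased, truth = sim.simulate_tetraploids(panels, params)
    fragments = sim.emit_fragments(truth, unphased, params)
    return dict(params=params, panels=panels, unphased=unphased, truth=truth, fragments=fragments)


@pytest.fixture(scope="session")
def ld_dataset():
    """Two coalescent subgenomes with within- but not between-subgenome LD."""
    co, cg = sim.coalescent_subgenomes(
        n_accessions=25, seq_length=1_500_000, ne=50_000, recomb=2e-9, seed=5
    )
    return co, cg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
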