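import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

import snpimpute as si


@pytest.fixture(scope="session")
def small_panel():
    """A small but non-trivial panel with LD: 20 founders -> 40 mosaics, 400 sites."""
    founders = si.simulate_founders(20, 400, 0.05, seed=101)
    gmap = si.make_genetic_map(founders.sites.pos, 1.0)
    panel = si.recombine_panel(founders, 40, gmap, 100, seed=102)
    return panel, gmap


@pytest.fixture(scope="session")
def tiny_benchmark_config():
    """A seconds-scale benchmark configuration for orchestration tests."""
    return si.BenchmarkConfig(
        n_sites=600,
        n_founders=30,
        n_panel_haplotypes=60,
        observed_counts=(60, 200),
        fractions=(0.25, 0.75),
        thresholds=(0.5, 0.95),
        n_replicates=3,
        pop_sizes=(30, 30),
        master_seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
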