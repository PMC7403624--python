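import numpy as np
import pytest

import segvar as sv


@pytest.fixture(scope="session")
def small_cross():
    """A 400-segregant x 300-marker cross reused by read-only tests."""
    mm, geno = sv.simulate_segregant_panel(
        sv.PanelConfig(n_chromosomes=16, n_markers=300), 400, seed=101)
    return mm, geno


@pytest.fixture(scope="session")
def adaptive_panel(small_cross):
    """Traits generated in adaptive-divergence mode on the shared cross."""
    _, geno = small_cross
    archs, panel, growth, extras = sv.simulate_traits(
        geno, sv.ArchitectureConfig(n_traits=30), n_replicates=2, seed=202)
    return archs, panel, growth, extras


@pytest.fixture(scope="session")
def kinship(small_cross):
    _, geno = small_cross
    return sv.compute_kinship(geno)
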