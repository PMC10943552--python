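import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from hexorigin.simgenome import SimConfig, default_fehii_spec, simulate_hexaploid


@pytest.fixture(scope="session")
def default_dataset():
    """A default three-group hexaploid simulation (no gene family)."""
    return simulate_hexaploid(SimConfig(seed=11))


@pytest.fixture(scope="session")
def family_dataset():
    """Three groups plus the planted nine-copy GH32-like family."""
    return simulate_hexaploid(
        SimConfig(n_groups=3, family_spec=default_fehii_spec(), seed=5))


@pytest.fixture(scope="session")
def records_by_id(default_dataset):
    return {r.gene_id: r for r in default_dataset.all_records()}
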