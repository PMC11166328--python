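import logging

import pytest

from tribekit.pipeline import make_demo
from tribekit.simulate import GenotypeDesign, SimulationConfig, simulate_dataset

logging.getLogger("tribekit").setLevel(logging.WARNING)

#: demo parameters scaled for the test suite (same code path as the full demo)
SMALL_DEMO = dict(
    n_genes=60,
    wt_targets=30,
    mut_targets=15,
    shared_targets=5,
    coverage=(20.0, 200.0),
    seq_error_rate=0.001,
)


@pytest.fixture(scope="session")
def sim_depth50(tmp_path_factory):
    """Two-genotype dataset at constant depth 50, no sequencing errors:
    every planted site should be exactly recoverable."""
    cfg = SimulationConfig(
        n_genes=100,
        genotypes=(
            GenotypeDesign("WT", 100, "utr3_only", 0.5, sites_per_target=2),
            GenotypeDesign("MUT", 40, "uniform", 0.25, sites_per_target=2),
        ),
        coverage=50.0,
        seq_error_rate=0.0,
        seed=101,
    )
    out = simulate_dataset(cfg, tmp_path_factory.mktemp("sim50"))
    return out


@pytest.fixture(scope="session")
def demo_small(tmp_path_factory):
    """Scaled-down two-genotype demo dataset (full study design, fewer genes)."""
    return make_demo(tmp_path_factory.mktemp("demo"), seed=11, **SMALL_DEMO)
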