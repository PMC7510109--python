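import numpy as np
import pandas as pd
import pytest

import bulkdecon as bd

# One simulated experiment shared across the suite: five cell types with
# four purified replicates each, 60 exclusive markers per type at 10-fold
# elevation, 10% shared markers between adjacent types, 20% log-normal
# replicate noise.


@pytest.fixture(scope="session")
def sim_config():
    return bd.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def simulated(sim_config):
    expr, sheet, truth = bd.simulate_reference(sim_config)
    return expr, sheet, truth


@pytest.fixture(scope="session")
def reference_profile(simulated):
    expr, sheet, _ = simulated
    return bd.collapse_replicates(expr, sheet)


@pytest.fixture(scope="session")
def stage1(simulated, reference_profile):
    expr, _, _ = simulated
    return bd.identify_markers(expr, reference_profile, seed=2)


@pytest.fixture(scope="session")
def signature_matrix(stage1, reference_profile):
    return bd.build_signature(
        stage1.allocations, reference_profile, stage1.specificity["pi"]
    )


@pytest.fixture()
def tiny_reference():
    """4 genes x 3 cell types with one obvious marker per type."""
    return pd.DataFrame(
        {
            "A": [90.0, 1.0, 1.0, 10.0],
            "B": [1.0, 80.0, 1.0, 10.0],
            "C": [1.0, 1.0, 70.0, 10.0],
        },
        index=["gA", "gB", "gC", "flat"],
    )


@pytest.fixture(scope="session")
def exclusive_markers(simulated):
    """Planted markers belonging to exactly one cell type."""
    _, _, truth = simulated
    counts = truth.groupby("gene")["cell_type"].transform("size")
    return truth[counts == 1]


@pytest.fixture(scope="session")
def shared_markers(simulated):
    """Planted markers elevated in two correlated cell types."""
    _, _, truth = simulated
    counts = truth.groupby("gene")["cell_type"].transform("size")
    return truth[counts == 2]
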