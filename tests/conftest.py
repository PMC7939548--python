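import numpy as np
import pandas as pd
import pytest

import mfabkit as mk
from mfabkit.pipeline import default_scenario


@pytest.fixture(scope="session")
def scenario():
    """The packaged synthetic study at a fixed seed."""
    return default_scenario(seed=7)


@pytest.fixture(scope="session")
def coproseq_abundance(scenario):
    """Absolute-abundance table from one simulated COPRO-Seq run."""
    design, params, _, _ = scenario
    counts = mk.simulate_coproseq(design, params)
    relab = mk.relative_abundance(counts)
    return design, mk.absolute_abundance(relab, mk.SpikeInSpec())


@pytest.fixture()
def toy_counts():
    """Two-strain single-sample count table with hand-checkable arithmetic."""
    return pd.DataFrame(
        {
            "sample": ["s1", "s1"],
            "strain": ["X", "A_acidiphilus"],
            "count": [8000, 1000],
            "genome_size_bp": [4e6, 2e6],
            "mass_g": [0.05, 0.05],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
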