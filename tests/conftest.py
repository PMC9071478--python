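import numpy as np
import pytest

import refanno as ra


@pytest.fixture(scope="session")
def small_scenario():
    """Compact 3-type scenario shared by unit tests (fast to annotate)."""
    cfg = ra.ScenarioConfig(
        seed=42,
        n_genes=800,
        ref_types={"alpha": 40, "beta": 40, "delta": 40},
        query_types={"alpha": 40, "beta": 40, "delta": 40},
        markers_per_type=15,
        atlas_types=40,
        broad_genes=80,
        batch_sigma=0.3,
    )
    return cfg, ra.generate_scenario(cfg)


@pytest.fixture
def tiny_counts():
    genes = ["gA", "gB", "gC", "gD"]
    cells = ["c1", "c2", "c3"]
    counts = np.array(
        [[5, 0, 1],
         [2, 3, 0],
         [0, 0, 4],
         [1, 1, 1]]
    )
    return ra.CountMatrix(genes, cells, counts)
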