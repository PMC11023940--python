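import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import deconvbench as db

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_sc() -> db.SingleCellDataset:
    """Handmade 6-gene x 8-cell dataset with two cell types."""
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 20, size=(6, 8))
    gene_ids = [f"g{i}" for i in range(6)]
    cell_ids = [f"c{i}" for i in range(8)]
    annotation = pd.DataFrame({
        "cell_id": cell_ids,
        "sample_id": ["s1", "s2"] * 4,
        "cell_type": ["A"] * 4 + ["B"] * 4,
    })
    return db.SingleCellDataset(counts=counts, gene_ids=gene_ids,
                                cell_ids=cell_ids, annotation=annotation)


@pytest.fixture(scope="session")
def small_synth() -> db.SingleCellDataset:
    """Quick synthetic dataset (500 genes, 3 types, 80 cells/type)."""
    cfg = db.SynthConfig(n_genes=500, cell_types=("a", "b", "c"),
                         cells_per_type=80, n_markers_per_type=10, seed=7)
    return db.generate_sc(cfg)
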