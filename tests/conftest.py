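import numpy as np
import pandas as pd
import pytest

from refstab import CqTable, aggregate_replicates, default_panel_config, simulate_cq_dataset


@pytest.fixture
def small_cq_table() -> CqTable:
    """Two genes x four samples (2 groups) x triplicates, consistent Cq."""
    rows = []
    base = {"REF1": 20.0, "REF2": 24.0}
    for gene, mu in base.items():
        for i, (sample, grp) in enumerate(
            [("wt1", "WT"), ("wt2", "WT"), ("ko1", "KO"), ("ko2", "KO")]
        ):
            for r in range(1, 4):
                rows.append((gene, sample, grp, r, mu + 0.1 * i + 0.01 * r))
    return CqTable(pd.DataFrame(
        rows, columns=["gene_id", "sample_id", "group", "replicate_index", "cq"]
    ))


@pytest.fixture
def panel_agg():
    """Aggregated 10-gene panel (8 stable, 1 shift, 1 noisy), n_g = 7."""
    cfg = default_panel_config(
        n_stable=8, shift_genes={"SHIFT": 0.8}, noise_genes={"NOISY": 0.6},
        group_sizes={"WT": 7, "KO": 7}, seed=42,
    )
    table, truth = simulate_cq_dataset(cfg)
    return aggregate_replicates(table), truth


@pytest.fixture
def toy_deseq_table() -> pd.DataFrame:
    """Five genes, exactly one (A) passing every reference filter."""
    return pd.DataFrame({
        "gene_id": list("ABCDE"),
        "base_mean": [600.0, 600.0, 600.0, 600.0, 100.0],
        "log2fc": [0.05, 0.05, 0.5, 0.05, 0.05],
        "padj": [0.8, 0.01, 0.8, 0.8, 0.8],
        "dispersion": [0.0225, 0.0225, 0.0225, 0.0625, 0.0225],
    })
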