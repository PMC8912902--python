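"""Screen RNA-Seq results for reference-gene candidates and DE targets.

Simulates the RNA-Seq arm of the study, applies the four candidate
filters (padj > 0.05, |log2FC| <= 0.1, CVfromDisp in [10, 20],
baseMean >= 500), partitions the surviving pool into baseMean quartiles
and draws a 3/3/3/1 panel; separately selects 3 up- and 3 down-regulated
target genes (padj < 0.05, |log2FC| > 0.6).

Writes results/candidate_panel.csv and results/target_genes.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import screened_panel

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts, results, truth, pool, panel, up, down = screened_panel()
    OUT.mkdir(exist_ok=True)

    n_sig = int((results["padj"] < 0.05).sum())
    print(f"screened {len(results)} genes "
          f"({n_sig} significant at padj < 0.05)")
    print(f"four-filter candidate pool: {len(pool)} genes, "
          f"baseMean {pool['base_mean'].min():.0f}-{pool['base_mean'].max():.0f}")
    panel.table.to_csv(OUT / "candidate_panel.csv", index=False)
    print(f"panel (3/3/3/1 by baseMean quartile): {', '.join(panel.gene_ids)}")

    stable_truth = set(truth.stable_genes)
    n_truly_stable = sum(g in stable_truth for g in panel.gene_ids)
    print(f"{n_truly_stable}/10 panel genes carry no planted effect "
          "(ground truth)")

    targets = pd.DataFrame({
        "gene_id": up + down,
        "direction": ["up"] * len(up) + ["down"] * len(down),
    }).merge(results[["gene_id", "log2fc", "padj"]], on="gene_id")
    targets.to_csv(OUT / "target_genes.csv", index=False)
    print(f"targets: up = {', '.join(up)}; down = {', '.join(down)}")


if __name__ == "__main__":
    main()
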