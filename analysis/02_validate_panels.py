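"""Validate both candidate panels on the simulated qPCR plate.

Runs the full stability workflow on each 10-gene panel: replicate QC,
CV analysis of 2^-Cq with the 50% gate, exact Mann-Whitney testing of the
2^-dCq profiles, NormFinder stability ranking and best-pair search.

Writes results/stability_rnaseq_panel.csv and
results/stability_conventional_panel.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import CONVENTIONAL_PANEL, qpcr_plate

from refstab import stability_report
from refstab.qpcr_io import AggregatedCq

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    agg, rnaseq_panel, truth = qpcr_plate()
    OUT.mkdir(exist_ok=True)
    for name, genes in [("rnaseq", rnaseq_panel),
                        ("conventional", CONVENTIONAL_PANEL)]:
        sub = AggregatedCq(cq=agg.cq.loc[genes], sd=agg.sd.loc[genes],
                           flags=agg.flags.loc[genes], group_map=agg.group_map)
        rep = stability_report(sub, calibrator="WT")
        path = OUT / f"stability_{name}_panel.csv"
        rep.to_csv(path)
        n_sig = int(rep.table["mw_significant"].sum())
        n_excl = int((rep.table["status"] == "excluded_cv").sum())
        print(f"{name} panel: CV range "
              f"{rep.table['cv_percent'].min():.1f}-"
              f"{rep.table['cv_percent'].max():.1f}%, "
              f"{n_excl} gene(s) excluded by the 50% gate, "
              f"{n_sig} with significant intrinsic variation")
        print(f"  best pair {rep.best_pair[0]}/{rep.best_pair[1]} "
              f"(grouped stability {rep.pair_stability:.3f}) -> {path.name}")
    planted = set(truth.unstable_genes) & set(rnaseq_panel + CONVENTIONAL_PANEL)
    print(f"planted condition-dependent panel genes: {sorted(planted)}")


if __name__ == "__main__":
    main()
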