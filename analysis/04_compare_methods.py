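"""Compare fold-change distributions across the three normalization routes.

Per target, the KO-group fold changes from (1) the conventional panel's
NF, (2) the RNA-Seq-derived panel's NF and (3) RNA-Seq normalized counts
are compared with a tie-corrected Kruskal-Wallis test followed by Dunn's
post test with the conventional NF as control (Bonferroni over the two
planned comparisons).  The WT calibrator group is omitted: its fold
changes average 1 under every method by construction.

Writes results/method_comparison.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import CONVENTIONAL_PANEL, TARGET_EFFECTS, qpcr_plate, target_counts

from refstab import (
    compare_methods,
    comparison_table,
    ddct_fold_change,
    normalization_factor,
    rnaseq_fold_change,
    stability_report,
)
from refstab.qpcr_io import AggregatedCq

OUT = Path(__file__).resolve().parent.parent / "results"
METHODS = ["nf_conventional", "nf_rnaseq", "rnaseq_counts"]


def best_pair(agg, genes):
    sub = AggregatedCq(cq=agg.cq.loc[genes], sd=agg.sd.loc[genes],
                       flags=agg.flags.loc[genes], group_map=agg.group_map)
    return stability_report(sub, calibrator="WT").best_pair


def main() -> None:
    agg, rnaseq_panel, _ = qpcr_plate()
    norm_counts, count_groups, _ = target_counts()
    group_map = pd.Series(count_groups)
    nf_conv = normalization_factor(agg, best_pair(agg, CONVENTIONAL_PANEL))
    nf_rseq = normalization_factor(agg, best_pair(agg, rnaseq_panel))

    comparisons = []
    for target in TARGET_EFFECTS:
        arms = [
            ddct_fold_change(agg, target, nf_conv, "WT"),
            ddct_fold_change(agg, target, nf_rseq, "WT"),
            rnaseq_fold_change(norm_counts, target, "WT", group_map),
        ]
        comparisons.append(
            compare_methods(arms, control=0, labels=METHODS))
    table = comparison_table(comparisons)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "method_comparison.csv", index=False)

    for c in comparisons:
        verdict = ("no difference" if not c.any_significant()
                   else "difference detected")
        print(f"{c.target}: KW H = {c.h_statistic:.2f} "
              f"(p = {c.kw_p_value:.3f}); Dunn vs {c.control}: "
              + ", ".join(f"{r['comparison'].split(' vs ')[1]} "
                          f"p_adj = {r['p_adjusted']:.3f}"
                          for _, r in c.dunn.iterrows())
              + f" -> {verdict}")
    n_sig_qpcr = sum(
        c.dunn.iloc[0]["p_adjusted"] < 0.05 for c in comparisons)
    print(f"\nqPCR-vs-qPCR (the two NFs): {n_sig_qpcr}/{len(comparisons)} "
          "targets differ significantly")


if __name__ == "__main__":
    main()
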