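"""Cross-method comparison of fold-change distributions.

Each target gene's fold changes in the non-calibrator group are computed
by several normalization routes (conventional-panel NF, RNA-Seq-derived
NF, RNA-Seq normalized counts).  The distributions are compared per gene
with a tie-corrected Kruskal-Wallis test followed by Dunn's post test of
every method against a designated control method (the conventional NF in
the original design).  The calibrator group is omitted: its mean fold
change is 1 by construction under every method, so testing it is
redundant.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .normalization import FoldChangeResult
from .stats import dunns_posthoc, kruskal_wallis


class CompareError(ValueError):
    pass


@dataclass
class ComparisonResult:
    """Per-target Kruskal-Wallis + Dunn control-vs-others summary."""

    target: object
    h_statistic: float
    kw_p_value: float
    dunn: pd.DataFrame  # comparison, z, p_raw, p_adjusted
    control: str

    def any_significant(self, alpha: float = 0.05) -> bool:
        return bool((self.dunn["p_adjusted"] < alpha).any())


def compare_methods(results: list[FoldChangeResult], control: int = 0,
                    adjust: str = "bonferroni",
                    exclude_calibrator: bool = True,
                    labels: list[str] | None = None) -> ComparisonResult:
    """Compare one target's fold changes across normalization methods.

    ``results`` holds one FoldChangeResult per method for the same target.
    The calibrator group's samples are dropped before testing (see module
    docstring).  Control-versus-others Dunn z values are adjusted over the
    len(results) - 1 planned comparisons.
    """
    if len(results) < 2:
        raise CompareError("need >= 2 methods to compare")
    targets = {str(r.target) for r in results}
    if len(targets) > 1:
        raise CompareError(f"results mix targets: {sorted(targets)}")
    if not (0 <= control < len(results)):
        raise CompareError(f"control index {control} out of range")
    if labels is None:
        labels = [f"{r.method}[{i}]" for i, r in enumerate(results)]
    groups = []
    for r in results:
        fc = r.fold_changes
        if exclude_calibrator:
            keep = [s for s in fc.index if r.group_map.get(s) != r.calibrator]
            fc = fc[keep]
        groups.append(fc.to_numpy())
    h, p = kruskal_wallis(groups)
    dunn = dunns_posthoc(groups, control=control, adjust=adjust, labels=labels)
    return ComparisonResult(target=results[0].target, h_statistic=h,
                            kw_p_value=p, dunn=dunn, control=labels[control])


def comparison_table(comparisons: list[ComparisonResult]) -> pd.DataFrame:
    """Flatten per-target comparisons into one long table."""
    rows = []
    for c in comparisons:
        for _, d in c.dunn.iterrows():
            rows.append({
                "target": c.target, "kw_h": c.h_statistic, "kw_p": c.kw_p_value,
                "comparison": d["comparison"], "dunn_z": d["z"],
                "p_raw": d["p_raw"], "p_adjusted": d["p_adjusted"],
            })
    return pd.DataFrame(rows)
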