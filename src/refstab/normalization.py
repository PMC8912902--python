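"""Normalization-factor construction and relative quantification.

The normalization factor (NF) for a sample is the arithmetic mean of the
best reference pair's Cq values in that sample — the Cq-scale equivalent
of the geometric mean of their expression levels.  Target genes are then
quantified by the 2^-ddCt method: dCq = Cq_target - NF per sample, ddCq
re-centers dCq on the calibrator group's mean, and FC = 2^-ddCq, so the
calibrator group's fold changes have geometric mean 1.  For comparison
with sequencing, per-sample RNA-Seq fold changes divide each sample's
normalized count by the calibrator group's mean normalized count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qpcr_io import AggregatedCq
from .stats import mann_whitney_exact

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizationFactor:
    """Per-sample NF: arithmetic mean of the pair's Cq values (cycles)."""

    pair: tuple
    values: pd.Series  # sample -> NF (cycles)


@dataclass
class FoldChangeResult:
    """Per-sample fold changes with per-group summaries and a group test.

    ``method`` is ``qpcr_nf`` (2^-ddCt against a stated NF) or
    ``rnaseq_counts`` (normalized counts over the calibrator mean).
    """

    method: str
    target: object
    calibrator: object
    fold_changes: pd.Series          # sample -> FC
    group_map: pd.Series
    group_stats: pd.DataFrame        # group -> mean, sd, n
    p_value: float | None = None     # two-group exact Mann-Whitney

    def group_values(self, group) -> pd.Series:
        cols = [s for s in self.fold_changes.index if self.group_map.get(s) == group]
        return self.fold_changes[cols]


def normalization_factor(agg: AggregatedCq | pd.DataFrame, pair) -> NormalizationFactor:
    """Per-sample arithmetic mean of the two reference genes' Cq.

    Samples missing either gene's Cq are omitted with a log message.
    Passing the same gene twice degenerates to that gene's Cq (warned).
    """
    cq = agg.cq if isinstance(agg, AggregatedCq) else agg
    pair = tuple(pair)
    if len(pair) != 2:
        raise NormalizationError("pair must contain exactly 2 gene ids")
    a, b = pair
    for g in {a, b}:
        if g not in cq.index:
            raise NormalizationError(f"gene {g!r} absent from the Cq matrix")
    if a == b:
        logger.warning("degenerate NF: pair is the same gene twice (%r)", a)
    nf = (cq.loc[a] + cq.loc[b]) / 2.0
    missing = nf.index[nf.isna()]
    if len(missing):
        logger.info("NF undefined for samples %s; omitted", list(missing))
        nf = nf.dropna()
    return NormalizationFactor(pair=pair, values=nf)


def _group_stats(fc: pd.Series, group_map: pd.Series) -> pd.DataFrame:
    rows = []
    for grp in sorted(pd.Series(group_map).unique()):
        vals = fc[[s for s in fc.index if group_map.get(s) == grp]]
        rows.append({"group": grp, "mean_fc": vals.mean(),
                     "sd_fc": vals.std(ddof=1), "n": len(vals)})
    return pd.DataFrame(rows).set_index("group")


def ddct_fold_change(agg: AggregatedCq | pd.DataFrame, target,
                     nf: NormalizationFactor, calibrator,
                     group_map: pd.Series | None = None) -> FoldChangeResult:
    """Relative expression of a target gene by the 2^-ddCt method.

    dCq = Cq_target - NF per sample; ddCq subtracts the calibrator-group
    mean dCq (arithmetic on the Cq scale = geometric on the linear scale),
    so calibrator fold changes scatter around 1.  A two-sided exact
    Mann-Whitney p compares the two groups' FC values when exactly two
    groups are present.
    """
    if isinstance(agg, AggregatedCq):
        cq, group_map = agg.cq, agg.group_map
    else:
        cq = agg
        if group_map is None:
            raise NormalizationError("group_map required for a raw Cq matrix")
    if target not in cq.index:
        raise NormalizationError(f"target gene {target!r} absent")
    if calibrator not in set(group_map):
        raise NormalizationError(f"unknown calibrator group {calibrator!r}")
    common = [s for s in cq.columns if s in nf.values.index]
    dcq = cq.loc[target, common] - nf.values[common]
    cal_samples = [s for s in common if group_map.get(s) == calibrator]
    if not cal_samples:
        raise NormalizationError(f"calibrator group {calibrator!r} has no samples")
    ddcq = dcq - dcq[cal_samples].mean()
    fc = 2.0 ** (-ddcq)
    fc.name = target
    stats_df = _group_stats(fc, group_map)
    p = None
    groups = sorted(pd.Series(group_map).unique())
    if len(groups) == 2:
        va = fc[[s for s in fc.index if group_map.get(s) == groups[0]]]
        vb = fc[[s for s in fc.index if group_map.get(s) == groups[1]]]
        if len(va) >= 2 and len(vb) >= 2:
            _, p = mann_whitney_exact(va.to_numpy(), vb.to_numpy())
    return FoldChangeResult(method="qpcr_nf", target=target, calibrator=calibrator,
                            fold_changes=fc, group_map=pd.Series(group_map),
                            group_stats=stats_df, p_value=p)


def rnaseq_fold_change(norm_counts: pd.DataFrame, target, calibrator,
                       group_map: pd.Series) -> FoldChangeResult:
    """Per-sample RNA-Seq fold change relative to the calibrator-group mean.

    FC(sample) = normalized count / mean(normalized count over calibrator
    samples), so the calibrator group's mean FC is 1 by construction.
    """
    if target not in norm_counts.index:
        raise NormalizationError(f"target gene {target!r} absent from counts")
    cal_samples = [s for s in norm_counts.columns if group_map.get(s) == calibrator]
    if not cal_samples:
        raise NormalizationError(f"calibrator group {calibrator!r} has no samples")
    cal_mean = norm_counts.loc[target, cal_samples].mean()
    if cal_mean == 0:
        raise NormalizationError(
            f"calibrator mean count is 0 for {target!r}; FC undefined"
        )
    fc = norm_counts.loc[target] / cal_mean
    fc.name = target
    stats_df = _group_stats(fc, group_map)
    p = None
    groups = sorted(pd.Series(group_map).unique())
    if len(groups) == 2:
        va = fc[[s for s in fc.index if group_map.get(s) == groups[0]]]
        vb = fc[[s for s in fc.index if group_map.get(s) == groups[1]]]
        if len(va) >= 2 and len(vb) >= 2:
            _, p = mann_whitney_exact(va.to_numpy(), vb.to_numpy())
    return FoldChangeResult(method="rnaseq_counts", target=target,
                            calibrator=calibrator, fold_changes=fc,
                            group_map=pd.Series(group_map),
                            group_stats=stats_df, p_value=p)
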