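"""Cq data ingest, technical-replicate aggregation and amplification-efficiency QC.

Quantification-cycle (Cq) values arrive as long-format tables with one row
per technical replicate.  Each biological sample is typically run in
triplicate; replicates whose standard deviation exceeds 0.20 cycles are
treated as inconsistent, and a single outlier replicate is removed in an
attempt to restore consistency.  Amplification efficiency of a primer pair
is estimated from a serial-dilution standard curve as E = 10^(-1/slope),
where the slope is the OLS regression of Cq on log10 relative concentration;
an ideal primer doubles the amplicon each cycle (E = 2, slope ~ -3.32).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Flag values for aggregated (gene, sample) cells.
FLAG_OK = "ok"
FLAG_OUTLIER_DROPPED = "outlier_dropped"
FLAG_INCONSISTENT = "inconsistent"

DEFAULT_COLUMNS = {
    "gene": "gene",
    "sample": "sample",
    "group": "group",
    "replicate": "replicate",
    "cq": "cq",
}


class CqFormatError(ValueError):
    """A Cq input file is malformed (missing column, bad dialect)."""


class CqValidationError(ValueError):
    """A Cq table violates an invariant (duplicates, inconsistent groups)."""


@dataclass
class CqTable:
    """Long-format technical-replicate Cq measurements.

    ``data`` holds columns gene_id, sample_id, group, replicate_index, cq.
    Invariants: cq finite and > 0; (gene_id, sample_id, replicate_index)
    unique; each sample_id maps to exactly one group.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = ["gene_id", "sample_id", "group", "replicate_index", "cq"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise CqFormatError(f"CqTable missing columns: {missing}")
        cq = pd.to_numeric(df["cq"], errors="raise")
        if not np.all(np.isfinite(cq)) or (cq <= 0).any():
            raise CqValidationError("cq values must be finite and > 0")
        dup = df.duplicated(subset=["gene_id", "sample_id", "replicate_index"])
        if dup.any():
            rows = df.loc[dup, ["gene_id", "sample_id", "replicate_index"]]
            raise CqValidationError(
                f"duplicate (gene, sample, replicate) rows: {rows.values.tolist()[:5]}"
            )
        n_groups_per_sample = df.groupby("sample_id")["group"].nunique()
        bad = n_groups_per_sample[n_groups_per_sample > 1]
        if len(bad):
            raise CqValidationError(
                f"samples mapped to multiple groups: {list(bad.index)}"
            )

    @property
    def genes(self) -> list:
        return sorted(self.data["gene_id"].unique())

    @property
    def samples(self) -> list:
        return sorted(self.data["sample_id"].unique())

    @property
    def group_map(self) -> pd.Series:
        """sample_id -> group label."""
        return self.data.drop_duplicates("sample_id").set_index("sample_id")["group"]


@dataclass
class AggregatedCq:
    """Per-(gene, sample) mean Cq after the replicate-SD QC rule.

    ``cq``: genes x samples mean-Cq matrix.  ``sd``: replicate SD of the
    retained replicates.  ``flags``: per-cell QC flag.  ``group_map``:
    sample_id -> group label.
    """

    cq: pd.DataFrame
    sd: pd.DataFrame
    flags: pd.DataFrame
    group_map: pd.Series
    n_dropped: int = 0

    def groups(self) -> list:
        return sorted(self.group_map.unique())

    def samples_in_group(self, group) -> list:
        return sorted(self.group_map.index[self.group_map == group])

    def to_csv(self, cq_path, flags_path=None) -> None:
        self.cq.to_csv(cq_path)
        if flags_path is not None:
            self.flags.to_csv(flags_path)


@dataclass
class EfficiencyResult:
    """Standard-curve efficiency: slope (Cq per log10 dilution), E, R^2, QC."""

    slope: float
    e_value: float
    r_squared: float
    pass_qc: bool
    degenerate: bool = False


def read_cq_table(path, columns: dict | None = None, sep: str = ",") -> CqTable:
    """Read a long-format Cq CSV/TSV into a validated :class:`CqTable`.

    ``columns`` maps the canonical names gene/sample/group/replicate/cq to
    the file's column headers.  Rows with an empty cq cell are dropped and
    counted in the log.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=sep)
    canonical = {"gene": "gene_id", "sample": "sample_id", "group": "group",
                 "replicate": "replicate_index", "cq": "cq"}
    rename = {}
    missing = []
    for key, target in canonical.items():
        if colmap[key] in df.columns:
            rename[colmap[key]] = target
        elif target in df.columns:  # already canonical
            pass
        else:
            missing.append(colmap[key])
    if missing:
        raise CqFormatError(f"input file {path} missing required column(s): {missing}")
    df = df.rename(columns=rename)
    df["cq"] = pd.to_numeric(df["cq"], errors="coerce")
    n_blank = int(df["cq"].isna().sum())
    if n_blank:
        logger.info("dropped %d rows with empty cq cells", n_blank)
        df = df.dropna(subset=["cq"])
    table = CqTable(df.reset_index(drop=True))
    table.n_blank_dropped = n_blank
    return table


def _aggregate_one(cq_values: np.ndarray, rep_index: np.ndarray, sd_threshold: float):
    """Apply the replicate QC rule to one (gene, sample) cell.

    Returns (mean, sd, flag).  SD uses the n-1 denominator.  If SD exceeds
    the threshold, the replicate farthest from the median (ties to lowest
    replicate index) is removed; if the remainder is consistent the cell is
    flagged outlier_dropped, otherwise inconsistent and the mean over all
    original replicates is reported.
    """
    sd_all = float(np.std(cq_values, ddof=1))
    mean_all = float(np.mean(cq_values))
    if sd_all <= sd_threshold:
        return mean_all, sd_all, FLAG_OK
    if len(cq_values) <= 2:
        # cannot drop below duplicate values
        return mean_all, sd_all, FLAG_INCONSISTENT
    med = np.median(cq_values)
    dist = np.abs(cq_values - med)
    # farthest from the median; ties broken by the lowest replicate index
    candidates = np.flatnonzero(dist == dist.max())
    drop = candidates[np.argmin(rep_index[candidates])]
    kept = np.delete(cq_values, drop)
    sd_kept = float(np.std(kept, ddof=1))
    if sd_kept < sd_threshold:
        return float(np.mean(kept)), sd_kept, FLAG_OUTLIER_DROPPED
    return mean_all, sd_all, FLAG_INCONSISTENT


def aggregate_replicates(cq: CqTable, sd_threshold: float = 0.20) -> AggregatedCq:
    """Collapse technical replicates to one mean Cq per (gene, sample).

    Implements the consistency rule: replicate SD > ``sd_threshold`` (0.20
    cycles by default) marks the triplet inconsistent and triggers removal
    of one outlier replicate; cells that stay inconsistent are retained
    with a flag for downstream filtering rather than silently dropped.
    """
    genes = cq.genes
    samples = cq.samples
    grouped = cq.data.groupby(["gene_id", "sample_id"])["cq"]
    stats_df = grouped.agg(["mean", "std", "count"])
    if (stats_df["count"] < 2).any():
        bad = stats_df.index[stats_df["count"] < 2][0]
        raise CqValidationError(
            f"(gene={bad[0]}, sample={bad[1]}) has <2 replicates; >=2 required"
        )
    means = stats_df["mean"].unstack().reindex(index=genes, columns=samples)
    sds = stats_df["std"].unstack().reindex(index=genes, columns=samples)
    flags = pd.DataFrame(FLAG_OK, index=genes, columns=samples, dtype=object)
    flags = flags.where(means.notna(), "")
    # only cells breaching the threshold need the per-cell outlier routine
    suspect = stats_df.index[stats_df["std"] > sd_threshold]
    if len(suspect):
        indexed = cq.data.set_index(["gene_id", "sample_id"]).sort_index()
        for g, s in suspect:
            sub = indexed.loc[(g, s)]
            m, sd, flag = _aggregate_one(
                sub["cq"].to_numpy(dtype=float),
                sub["replicate_index"].to_numpy(), sd_threshold,
            )
            means.loc[g, s] = m
            sds.loc[g, s] = sd
            flags.loc[g, s] = flag
    return AggregatedCq(cq=means, sd=sds, flags=flags, group_map=cq.group_map)


def efficiency_from_standard_curve(
    dilution_factors, cq_means, e_bounds=(1.9, 2.1), r2_min=0.99
) -> EfficiencyResult:
    """Amplification efficiency from a serial-dilution standard curve.

    OLS of mean Cq on log10(relative concentration); E = 10^(-1/slope).
    QC passes when 1.9 <= E <= 2.1 (95-105% efficiency) and R^2 >= 0.99.
    A subset mask (e.g. dropping an out-of-range 4th dilution) is applied
    by the caller before invoking this function.
    """
    conc = np.asarray(dilution_factors, dtype=float)
    cqv = np.asarray(cq_means, dtype=float)
    if conc.size < 3:
        raise CqValidationError("standard curve needs >= 3 dilution points")
    if conc.size != cqv.size:
        raise CqValidationError("dilution_factors and cq_means length mismatch")
    x = np.log10(conc)
    if np.ptp(x) == 0:
        raise CqValidationError("zero variance in log10 concentration: degenerate design")
    fit = stats.linregress(x, cqv)
    slope = float(fit.slope)
    r2 = float(fit.rvalue**2)
    if slope == 0:
        return EfficiencyResult(slope=0.0, e_value=float("nan"), r_squared=r2,
                                pass_qc=False, degenerate=True)
    e_value = float(10.0 ** (-1.0 / slope))
    pass_qc = (e_bounds[0] <= e_value <= e_bounds[1]) and (r2 >= r2_min)
    return EfficiencyResult(slope=slope, e_value=e_value, r_squared=r2, pass_qc=pass_qc)
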