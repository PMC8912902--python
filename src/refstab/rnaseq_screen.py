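"""Candidate reference-gene and target-gene selection from RNA-Seq summaries.

Works on a DESeq2-style results table (gene, baseMean, log2FoldChange, padj,
dispersion).  The screening metric CVfromDisp = 100 * sqrt(dispersion) is a
coefficient-of-variation proxy derived from the negative-binomial dispersion.
Reference candidates must look *unchanged and quantifiable*: not
differentially expressed (padj > 0.05), flat (|log2FC| <= 0.1), moderately
variable (CVfromDisp in [10, 20]) and well expressed (baseMean >= 500).  The
surviving pool is ranked by baseMean, split into rank-quartiles and sampled
3/3/3/1 so the panel spans low to high expression.  Targets are the
opposite: significantly DE with |log2FC| > 0.6.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DESEQ_COLUMNS = {
    "gene": "gene",
    "base_mean": "baseMean",
    "log2fc": "log2FoldChange",
    "padj": "padj",
    "dispersion": "dispersion",
}


class ScreenError(ValueError):
    pass


class SelectionError(ScreenError):
    """A quartile or direction cannot satisfy its allocation."""


@dataclass
class CandidatePanel:
    """Genes selected for qPCR validation, with their baseMean quartile."""

    table: pd.DataFrame  # columns: gene_id, quartile (1..4), base_mean, cv_from_disp
    pool: pd.DataFrame
    strategy: str
    seed: int | None

    @property
    def gene_ids(self) -> list:
        return list(self.table["gene_id"])


def read_deseq_results(path, columns: dict | None = None, sep: str = ",") -> pd.DataFrame:
    """Read a DESeq2-style results CSV/TSV into canonical column names."""
    colmap = dict(DESEQ_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=sep)
    missing = [v for k, v in colmap.items() if v not in df.columns and k != "dispersion"]
    if missing:
        raise ScreenError(f"results file {path} missing column(s): {missing}")
    rename = {colmap["gene"]: "gene_id",
              colmap["base_mean"]: "base_mean",
              colmap["log2fc"]: "log2fc",
              colmap["padj"]: "padj"}
    if colmap["dispersion"] in df.columns:
        rename[colmap["dispersion"]] = "dispersion"
    out = df.rename(columns=rename)
    if out["gene_id"].duplicated().any():
        raise ScreenError("duplicate gene_id in results table")
    return out


def compute_cv_from_dispersion(table: pd.DataFrame) -> pd.DataFrame:
    """Add cv_from_disp = 100 * sqrt(dispersion), in percent.

    Missing dispersion propagates to missing cv_from_disp; a negative
    dispersion is a validation error (NB dispersion is nonnegative).
    """
    if "dispersion" not in table.columns:
        raise ScreenError("dispersion column required to compute cv_from_disp")
    disp = table["dispersion"]
    if (disp.dropna() < 0).any():
        raise ScreenError("negative dispersion encountered")
    out = table.copy()
    out["cv_from_disp"] = 100.0 * np.sqrt(disp)
    return out


def filter_reference_candidates(
    table: pd.DataFrame,
    padj_floor: float = 0.05,
    lfc_window: float = 0.1,
    cv_range: tuple[float, float] = (10.0, 20.0),
    basemean_floor: float = 500.0,
) -> pd.DataFrame:
    """Apply the four reference-candidate filters as a conjunction.

    Retains genes with padj > padj_floor (strict; missing padj excluded),
    -lfc_window <= log2FC <= +lfc_window, cv_range[0] <= CVfromDisp <=
    cv_range[1], and baseMean >= basemean_floor.  Order of application is
    irrelevant.  An empty result is a warning, not an error.
    """
    if "cv_from_disp" not in table.columns:
        raise ScreenError("call compute_cv_from_dispersion first")
    keep = (
        (table["padj"] > padj_floor)
        & table["padj"].notna()
        & (table["log2fc"] >= -lfc_window)
        & (table["log2fc"] <= lfc_window)
        & (table["cv_from_disp"] >= cv_range[0])
        & (table["cv_from_disp"] <= cv_range[1])
        & (table["base_mean"] >= basemean_floor)
    )
    out = table.loc[keep.fillna(False)].reset_index(drop=True)
    out.attrs = {}  # drop upstream sidecars (size factors etc.)
    if out.empty:
        warnings.warn("no genes survive the reference-candidate filters", stacklevel=2)
    return out


def _rank_quartiles(pool: pd.DataFrame, ascending: bool = True) -> np.ndarray:
    """Quartile labels 1..4 from baseMean ranks; ties go to the lower quartile.

    Q1 holds the lowest baseMean ranks by default (``ascending=True``); the
    orientation is exposed because "first quartile" is a convention.
    """
    n = len(pool)
    order = pool["base_mean"].rank(method="first", ascending=ascending).to_numpy()
    # rank r in 1..n -> quartile ceil(4r/n)
    return np.ceil(4.0 * order / n).astype(int)


def select_panel(
    pool: pd.DataFrame,
    allocation: tuple[int, int, int, int] = (3, 3, 3, 1),
    strategy: str = "random",
    seed: int | None = None,
    q1_low_expression: bool = True,
) -> CandidatePanel:
    """Draw a candidate panel with a fixed per-quartile allocation.

    The filtered pool is ranked by baseMean and split into four
    rank-quartiles; ``allocation[q]`` genes are drawn from quartile q+1
    either uniformly at random (seeded) or as the lowest-CVfromDisp genes
    (ties by gene_id) for a deterministic panel.
    """
    if len(allocation) != 4:
        raise ScreenError("allocation must have 4 entries (one per quartile)")
    if len(pool) < sum(allocation):
        raise SelectionError(
            f"pool of {len(pool)} genes cannot satisfy allocation {allocation}"
        )
    pool = pool.reset_index(drop=True)
    pool.attrs = {}
    quart = _rank_quartiles(pool, ascending=q1_low_expression)
    rng = np.random.default_rng(seed)
    picked = []
    for q in range(1, 5):
        want = allocation[q - 1]
        members = pool.loc[quart == q]
        if len(members) < want:
            raise SelectionError(
                f"quartile Q{q} has {len(members)} genes, allocation asks for {want}"
            )
        if strategy == "random":
            idx = rng.choice(members.index.to_numpy(), size=want, replace=False)
            chosen = members.loc[np.sort(idx)]
        elif strategy == "lowest_cv":
            chosen = members.sort_values(
                ["cv_from_disp", "gene_id"], kind="mergesort"
            ).head(want)
        else:
            raise ScreenError(f"unknown strategy {strategy!r}")
        sub = chosen[["gene_id", "base_mean", "cv_from_disp"]].copy()
        sub["quartile"] = q
        picked.append(sub)
    panel = pd.concat(picked, ignore_index=True)
    return CandidatePanel(table=panel, pool=pool, strategy=strategy, seed=seed)


def select_targets(
    table: pd.DataFrame,
    padj_ceiling: float = 0.05,
    lfc_cut: float = 0.6,
    n_per_direction: int = 3,
    seed: int | None = None,
) -> tuple[list, list]:
    """Pick differentially expressed target genes, one list per direction.

    Up-candidates: padj < padj_ceiling and log2FC > +lfc_cut (strict);
    down-candidates: log2FC < -lfc_cut.  ``n_per_direction`` genes are
    sampled from each list with the given seed.
    """
    sig = table.loc[table["padj"].notna() & (table["padj"] < padj_ceiling)]
    up_pool = sig.loc[sig["log2fc"] > lfc_cut, "gene_id"].tolist()
    down_pool = sig.loc[sig["log2fc"] < -lfc_cut, "gene_id"].tolist()
    rng = np.random.default_rng(seed)
    lists = []
    for name, pool in (("up", up_pool), ("down", down_pool)):
        if len(pool) < n_per_direction:
            raise SelectionError(
                f"only {len(pool)} {name}-regulated genes pass; need {n_per_direction}"
            )
        lists.append(sorted(rng.choice(pool, size=n_per_direction, replace=False)))
    return lists[0], lists[1]
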