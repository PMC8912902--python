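"""Reference-gene stability: CV screen, intrinsic-variation test, NormFinder.

The validation workflow runs three complementary checks on a candidate
panel measured by qPCR across >= 2 experimental groups:

1. *Intrinsic variation*: the non-normalized expression profile 2^-dCq of
   each candidate (calibrated to one group) is compared between groups with
   an exact Mann-Whitney test.  Significance flags a gene as group-shifted
   but does not by itself exclude it.
2. *CV analysis*: the coefficient of variation of the linearized signal
   2^-Cq over all samples pooled; genes with CV > 50% are excluded because
   high overall variance degrades the model-based estimator downstream.
3. *NormFinder*: a variance-components model on the Cq scale (Cq is
   already log2 abundance, up to sign).  Per group g, gene i, sample j the
   model is y_igj = mu_i + a_ig + b_gj + eps_igj: a gene effect, a
   gene-by-group effect, a sample loading effect shared by all genes, and
   intragroup noise with gene/group-specific variance sigma2_ig.  The
   stability score S_i combines the shrunken intergroup deviation of gene
   i with its intragroup sampling variability; the best *pair* of genes is
   the pair whose average signal minimizes the same score (averaging lets
   opposite group deviations cancel).

Lower S means more stable; the winning pair supplies the normalization
factor for ddCt quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .qpcr_io import AggregatedCq
from .stats import mann_whitney_exact

#: CV gate above which a candidate is excluded from NormFinder, in percent.
DEFAULT_CV_GATE = 50.0

STATUS_ELIGIBLE = "eligible"
STATUS_EXCLUDED_CV = "excluded_cv"


class StabilityError(ValueError):
    pass


@dataclass
class RelativeQuantityMatrix:
    """Gene x sample matrix of relative quantities.

    ``mode`` is ``linearized`` (2^-Cq) or ``calibrated`` (2^-dCq, per-gene
    geometric mean of the calibrator group equal to 1).
    """

    values: pd.DataFrame
    mode: str
    group_map: pd.Series
    calibrator: object | None = None


@dataclass
class NormFinderResult:
    """Variance-components output of the stability estimator.

    Indexing convention: rows are genes, columns are groups for the
    per-group quantities.  ``stability`` maps gene -> S (log2 units,
    lower is more stable).  ``gamma2`` is the shrinkage variance of the
    intergroup deviations.
    """

    intragroup_var: pd.DataFrame      # sigma2_ig >= 0
    intergroup_dev: pd.DataFrame      # d_ig, sums to 0 over groups and over genes
    shrunken_dev: pd.DataFrame        # d_tilde_ig, |d_tilde| <= |d|
    gamma2: float
    stability: pd.Series              # S_i
    ranks: pd.Series
    group_sizes: pd.Series
    best_pair: tuple | None = None
    pair_stability: float | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"stability": self.stability, "rank": self.ranks})


def _cq_matrix(agg) -> tuple[pd.DataFrame, pd.Series]:
    if isinstance(agg, AggregatedCq):
        return agg.cq, agg.group_map
    raise TypeError("expected AggregatedCq; pass groups explicitly for raw matrices")


def linearize(agg: AggregatedCq | pd.DataFrame,
              group_map: pd.Series | None = None) -> RelativeQuantityMatrix:
    """Linearize Cq to expression scale: entry = 2^-Cq."""
    if isinstance(agg, AggregatedCq):
        cq, group_map = agg.cq, agg.group_map
    else:
        cq = agg
        if group_map is None:
            raise StabilityError("group_map required for a raw Cq matrix")
    return RelativeQuantityMatrix(values=2.0 ** (-cq), mode="linearized",
                                  group_map=group_map)


def relative_quantity(agg: AggregatedCq | pd.DataFrame, calibrator,
                      group_map: pd.Series | None = None) -> RelativeQuantityMatrix:
    """Non-normalized relative expression 2^-dCq, calibrated per gene.

    dCq = Cq - mean(Cq over calibrator-group samples); the calibrator
    group's geometric mean is 1 for every gene by construction.
    """
    if isinstance(agg, AggregatedCq):
        cq, group_map = agg.cq, agg.group_map
    else:
        cq = agg
        if group_map is None:
            raise StabilityError("group_map required for a raw Cq matrix")
    if calibrator not in set(group_map):
        raise StabilityError(f"unknown calibrator group {calibrator!r}")
    cal_samples = [s for s in cq.columns if group_map.get(s) == calibrator]
    dcq = cq.sub(cq[cal_samples].mean(axis=1), axis=0)
    return RelativeQuantityMatrix(values=2.0 ** (-dcq), mode="calibrated",
                                  group_map=group_map, calibrator=calibrator)


def intrinsic_variation_test(rq: RelativeQuantityMatrix,
                             alpha: float = 0.05) -> pd.DataFrame:
    """Exact Mann-Whitney test of each gene's expression between two groups.

    Ranks are invariant to the monotone 2^-x transform, so the test is the
    same on Cq, dCq or relative-quantity scale; it is stated on the
    relative quantities to match how the profiles are inspected.
    """
    groups = sorted(rq.group_map.unique())
    if len(groups) != 2:
        raise StabilityError(
            f"intrinsic-variation test is two-group; got {len(groups)} groups "
            "(use kruskal_wallis for more)"
        )
    ga = [s for s in rq.values.columns if rq.group_map.get(s) == groups[0]]
    gb = [s for s in rq.values.columns if rq.group_map.get(s) == groups[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise StabilityError("each group needs >= 2 samples")
    rows = []
    for gene, row in rq.values.iterrows():
        u, p = mann_whitney_exact(row[ga].to_numpy(), row[gb].to_numpy())
        rows.append({"gene_id": gene, "U": u, "p_value": p,
                     "significant": p < alpha})
    return pd.DataFrame(rows).set_index("gene_id")


def cv_analysis(rq: RelativeQuantityMatrix,
                gate: float = DEFAULT_CV_GATE) -> pd.DataFrame:
    """Coefficient of variation of linearized expression, all samples pooled.

    CV% = 100 * SD / mean (sample SD, n-1 denominator).  Genes with
    CV > ``gate`` are flagged ``excluded_cv`` and must not enter
    NormFinder.  Ranks are ascending (1 = least variable).
    """
    if rq.mode != "linearized":
        raise StabilityError("cv_analysis expects the linearized (2^-Cq) matrix")
    if rq.values.shape[1] < 3:
        raise StabilityError("CV needs >= 3 samples")
    mean = rq.values.mean(axis=1)
    if (mean == 0).any():
        bad = list(mean.index[mean == 0])
        raise StabilityError(f"zero mean expression, CV undefined for: {bad}")
    sd = rq.values.std(axis=1, ddof=1)
    cv = 100.0 * sd / mean
    out = pd.DataFrame({
        "cv_percent": cv,
        "cv_rank": cv.rank(method="min").astype(int),
        "status": np.where(cv > gate, STATUS_EXCLUDED_CV, STATUS_ELIGIBLE),
    })
    out.index.name = "gene_id"
    return out


def _shrink(d: np.ndarray, var_over_n: np.ndarray, gamma2: float) -> np.ndarray:
    """Shrinkage factor gamma2/(gamma2 + sigma2/n) applied to deviations d."""
    denom = gamma2 + var_over_n
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom > 0, gamma2 / denom, 0.0)
    return d * f


def normfinder(agg: AggregatedCq | pd.DataFrame,
               group_map: pd.Series | None = None,
               eligible=None,
               find_best_pair: bool = True) -> NormFinderResult:
    """Model-based stability estimation for a candidate reference panel.

    ``agg`` supplies the gene x sample mean-Cq matrix (Cq feeds the model
    directly: it is already a log2-scale signal, and the abundance sign
    flip affects neither variances nor |d|).  ``eligible`` restricts the
    panel, normally to the genes passing the CV gate.  Requires k >= 3
    genes (the k/(k-2) bias factor), >= 2 groups, each with >= 2 samples.
    """
    if isinstance(agg, AggregatedCq):
        cq, group_map = agg.cq, agg.group_map
    else:
        cq = agg
        if group_map is None:
            raise StabilityError("group_map required for a raw Cq matrix")
    if eligible is not None:
        cq = cq.loc[list(eligible)]
    genes = list(cq.index)
    k = len(genes)
    if k < 3:
        raise StabilityError(f"NormFinder needs >= 3 genes, got {k}")
    groups = sorted(pd.Series(group_map).unique())
    g_count = len(groups)
    if g_count < 2:
        raise StabilityError("NormFinder needs >= 2 groups")

    sigma2 = np.zeros((k, g_count))
    a_eff = np.zeros((k, g_count))
    n_g = np.zeros(g_count, dtype=int)
    for gi, grp in enumerate(groups):
        cols = [s for s in cq.columns if group_map.get(s) == grp]
        if len(cols) < 2:
            raise StabilityError(f"group {grp!r} has < 2 samples")
        y = cq[cols].to_numpy(dtype=float)  # k x n_g
        ng = y.shape[1]
        n_g[gi] = ng
        row_mean = y.mean(axis=1, keepdims=True)
        col_mean = y.mean(axis=0, keepdims=True)
        grand = y.mean()
        resid = y - row_mean - col_mean + grand
        s2_naive = (resid**2).sum(axis=1) / (ng - 1)
        s_g = s2_naive.sum()
        sigma2[:, gi] = np.maximum(
            (s2_naive - s_g / (k * (k - 1))) * k / (k - 2), 0.0
        )
        a_eff[:, gi] = row_mean.ravel() - grand

    d = a_eff - a_eff.mean(axis=1, keepdims=True)  # sums to 0 over groups per gene
    var_over_n = sigma2 / n_g  # broadcast over groups
    gamma2 = max(
        float((d**2).sum() / ((g_count - 1) * (k - 1)) - var_over_n.mean()), 0.0
    )
    d_tilde = _shrink(d, var_over_n, gamma2)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_term = np.where(
            gamma2 + var_over_n > 0,
            var_over_n * gamma2 / (gamma2 + var_over_n),
            0.0,
        )
    rho = np.abs(d_tilde) + np.sqrt(var_term)
    s_score = rho.mean(axis=1)

    stability = pd.Series(s_score, index=genes, name="stability")
    ranks = stability.rank(method="min").astype(int)
    result = NormFinderResult(
        intragroup_var=pd.DataFrame(sigma2, index=genes, columns=groups),
        intergroup_dev=pd.DataFrame(d, index=genes, columns=groups),
        shrunken_dev=pd.DataFrame(d_tilde, index=genes, columns=groups),
        gamma2=gamma2,
        stability=stability,
        ranks=ranks,
        group_sizes=pd.Series(n_g, index=groups),
    )
    if find_best_pair and k >= 2:
        pair, s_pair = normfinder_best_pair(result)
        result.best_pair = pair
        result.pair_stability = s_pair
    return result


def normfinder_best_pair(res: NormFinderResult) -> tuple[tuple, float]:
    """Exhaustive search for the pair with the least grouped stability.

    The pair's group deviation is the mean of the two genes' shrunken
    deviations; its sampling variance is (sigma2_a + sigma2_b)/(4 n_g),
    shrunken exactly as in the single-gene score.  Ties are broken
    lexicographically by the gene-id pair.
    """
    genes = list(res.stability.index)
    if len(genes) < 2:
        raise StabilityError("best-pair search needs >= 2 genes")
    n_g = res.group_sizes.to_numpy(dtype=float)
    gamma2 = res.gamma2
    d_tilde = res.shrunken_dev
    sigma2 = res.intragroup_var
    best = None
    for a, b in combinations(sorted(genes, key=str), 2):
        d_pair = (d_tilde.loc[a].to_numpy() + d_tilde.loc[b].to_numpy()) / 2.0
        v_pair = (sigma2.loc[a].to_numpy() + sigma2.loc[b].to_numpy()) / (4.0 * n_g)
        with np.errstate(invalid="ignore", divide="ignore"):
            var_term = np.where(
                gamma2 + v_pair > 0, v_pair * gamma2 / (gamma2 + v_pair), 0.0
            )
        s_pair = float(np.mean(np.abs(d_pair) + np.sqrt(var_term)))
        key = (s_pair, str(a), str(b))
        if best is None or key < best[0]:
            best = (key, (a, b), s_pair)
    return best[1], best[2]


@dataclass
class StabilityReport:
    """Combined CV / intrinsic-variation / NormFinder report for a panel."""

    table: pd.DataFrame
    best_pair: tuple | None
    pair_stability: float | None
    normfinder: NormFinderResult | None
    nf_preview: pd.Series | None = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path)
        if self.best_pair is not None:
            with open(path, "a") as fh:
                fh.write(
                    f"\n# NormFinder best pair: {self.best_pair[0]}/"
                    f"{self.best_pair[1]} - grouped stability: "
                    f"{self.pair_stability:.4f}\n"
                )


def stability_report(agg: AggregatedCq, calibrator,
                     cv_gate: float = DEFAULT_CV_GATE,
                     alpha: float = 0.05) -> StabilityReport:
    """Run the full candidate-validation workflow on an aggregated panel.

    CV analysis on 2^-Cq (all samples pooled) gates the panel at
    ``cv_gate``; the exact Mann-Whitney intrinsic-variation test on the
    2^-dCq profiles flags (but does not exclude) group-shifted genes; the
    NormFinder estimator ranks the CV-eligible genes and picks the best
    pair, whose per-sample mean Cq is previewed as the normalization
    factor.
    """
    cv = cv_analysis(linearize(agg), gate=cv_gate)
    groups = agg.groups()
    mw = None
    if len(groups) == 2:
        mw = intrinsic_variation_test(relative_quantity(agg, calibrator), alpha=alpha)
    eligible = list(cv.index[cv["status"] == STATUS_ELIGIBLE])
    nf_res = None
    best_pair = None
    pair_s = None
    if len(eligible) >= 3:
        nf_res = normfinder(agg, eligible=eligible)
        best_pair, pair_s = nf_res.best_pair, nf_res.pair_stability
    table = cv.copy()
    if mw is not None:
        table["mw_p_value"] = mw["p_value"]
        table["mw_significant"] = mw["significant"]
    if nf_res is not None:
        table["stability"] = nf_res.stability
        table["stability_rank"] = nf_res.ranks
    preview = None
    if best_pair is not None:
        preview = agg.cq.loc[list(best_pair)].mean(axis=0)
        preview.name = "nf_cq"
    return StabilityReport(table=table, best_pair=best_pair,
                           pair_stability=pair_s, normfinder=nf_res,
                           nf_preview=preview)
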