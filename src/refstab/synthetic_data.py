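"""Ground-truth simulators for the qPCR and RNA-Seq stages.

Two generators, both seeded and fully parameterized:

* **Cq simulator** — Gaussian noise on the Cq (log2) scale, matching the
  variance-components model the stability estimator assumes:

      y_igjr = mu_i + delta_ig + b_gj + e_igj + t_igjr

  with gene baseline mu_i (cycles), gene-by-group shift delta_ig (sum to
  zero over groups), per-sample loading effect b ~ N(0, sigma_s^2) shared
  by all genes in a sample, biological noise e ~ N(0, sigma_b_i^2) and
  technical replicate noise t ~ N(0, sigma_t^2).  Stable genes have
  delta = 0 and small sigma_b; planted-unstable genes carry either a
  group shift or inflated biological noise.

* **Count simulator** — negative-binomial counts with mean
  q_i * s_j * 2^theta_ig and gene dispersion alpha_i (alpha = 0 degrades
  to Poisson), plus a results-table builder that reproduces the
  median-of-ratios size factors and fills log2FC / padj / dispersion with
  a transparent Welch-t + Benjamini-Hochberg surrogate.  The DE engine is
  deliberately simple: downstream code consumes the table's schema and
  filters, not the fit.

Defaults mirror the wet-lab study design the package targets: technical
triplicates, 7 biological samples per group, candidate baselines spanning
18-26 cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .qpcr_io import CqTable

#: pseudo-count used for every log2 transform of counts
PSEUDOCOUNT = 0.5


@dataclass
class CqSimConfig:
    """Parameters of the Cq-scale simulation.

    ``group_shift`` gives each gene's *total* intergroup difference in
    cycles; for G groups it is realized as a centered linear profile
    (for G = 2: -shift/2 in the first group, +shift/2 in the second), so
    the per-group effects sum to zero.  All SDs are in cycles.
    """

    gene_ids: list
    baselines: dict            # gene -> mu_i (cycles)
    group_sizes: dict          # group label -> n_g
    group_shift: dict = field(default_factory=dict)   # gene -> total shift
    sigma_b: dict = field(default_factory=dict)       # gene -> biological SD
    sigma_b_default: float = 0.1
    sigma_s: float = 0.2       # sample loading SD, shared across genes
    sigma_t: float = 0.05      # technical replicate SD
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need >= 2 technical replicates")
        if self.sigma_s < 0 or self.sigma_t < 0:
            raise ValueError("SDs must be >= 0")
        for g, s in self.sigma_b.items():
            if s < 0:
                raise ValueError(f"sigma_b[{g!r}] < 0")
        missing = set(self.gene_ids) - set(self.baselines)
        if missing:
            raise ValueError(f"genes without baselines: {sorted(map(str, missing))}")


@dataclass
class CountSimConfig:
    """Parameters of the negative-binomial count simulation."""

    gene_ids: list
    mean_expression: dict      # gene -> q_i (normalized-count units)
    dispersion: dict           # gene -> alpha_i >= 0
    group_sizes: dict          # group label -> n samples
    log2_effects: dict = field(default_factory=dict)  # gene -> theta (2nd group)
    size_factors: list | None = None                  # per sample, > 0
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.gene_ids:
            if self.mean_expression[g] <= 0:
                raise ValueError(f"mean_expression[{g!r}] must be > 0")
            if self.dispersion[g] < 0:
                raise ValueError(f"dispersion[{g!r}] must be >= 0")
        if self.size_factors is not None:
            if any(s <= 0 for s in self.size_factors):
                raise ValueError("size factors must be > 0")


@dataclass
class SimTruth:
    """Ground truth written alongside simulated data."""

    stable_genes: list = field(default_factory=list)
    unstable_genes: dict = field(default_factory=dict)  # gene -> mechanism
    group_shift: dict = field(default_factory=dict)
    sigma_b: dict = field(default_factory=dict)
    log2_effects: dict = field(default_factory=dict)
    dispersion: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        import json
        with open(path, "w") as fh:
            json.dump({k: _jsonable(v) for k, v in self.__dict__.items()}, fh,
                      indent=2)


def _jsonable(v):
    if isinstance(v, dict):
        return {str(k): float(x) if isinstance(x, (int, float, np.floating))
                else x for k, x in v.items()}
    return v


def _centered_profile(total_shift: float, g_count: int) -> np.ndarray:
    """Per-group effects: centered linear ramp with range ``total_shift``."""
    if g_count == 1:
        return np.zeros(1)
    ramp = np.linspace(-0.5, 0.5, g_count)
    return ramp * total_shift


def simulate_cq_dataset(cfg: CqSimConfig) -> tuple[CqTable, SimTruth]:
    """Draw a long-format technical-replicate Cq table from the model."""
    rng = np.random.default_rng(cfg.seed)
    groups = list(cfg.group_sizes)
    g_count = len(groups)
    truth = SimTruth()
    shifts = {g: cfg.group_shift.get(g, 0.0) for g in cfg.gene_ids}
    sigmas = {g: cfg.sigma_b.get(g, cfg.sigma_b_default) for g in cfg.gene_ids}
    for g in cfg.gene_ids:
        if shifts[g] == 0.0 and sigmas[g] <= cfg.sigma_b_default:
            truth.stable_genes.append(g)
        else:
            truth.unstable_genes[g] = "shift" if shifts[g] != 0.0 else "noise"
    truth.group_shift = shifts
    truth.sigma_b = sigmas
    k = len(cfg.gene_ids)
    mu = np.array([cfg.baselines[g] for g in cfg.gene_ids])
    sig_vec = np.array([sigmas[g] for g in cfg.gene_ids])
    delta = np.column_stack(
        [_centered_profile(shifts[g], g_count) for g in cfg.gene_ids]
    ).T  # k x G
    rep = cfg.replicates
    frames = []
    for gi, grp in enumerate(groups):
        n_g = cfg.group_sizes[grp]
        loading = rng.normal(0.0, cfg.sigma_s, size=n_g)
        bio = rng.normal(0.0, 1.0, size=(k, n_g)) * sig_vec[:, None]
        base = mu[:, None] + delta[:, gi:gi + 1] + loading[None, :] + bio
        tech = (rng.normal(0.0, cfg.sigma_t, size=(k, n_g, rep))
                if cfg.sigma_t > 0 else np.zeros((k, n_g, rep)))
        y = base[:, :, None] + tech
        samples = [f"{grp}_s{j + 1}" for j in range(n_g)]
        frames.append(pd.DataFrame({
            "gene_id": np.repeat(cfg.gene_ids, n_g * rep),
            "sample_id": np.tile(np.repeat(samples, rep), k),
            "group": grp,
            "replicate_index": np.tile(np.arange(1, rep + 1), k * n_g),
            "cq": y.ravel(),
        }))
    df = pd.concat(frames, ignore_index=True)
    return CqTable(df), truth


def default_panel_config(n_stable: int = 8, shift_genes: dict | None = None,
                         noise_genes: dict | None = None,
                         group_sizes: dict | None = None,
                         sigma_b_stable: float = 0.1,
                         seed: int = 0, **kwargs) -> CqSimConfig:
    """Candidate-panel configuration in the study's design envelope.

    ``n_stable`` exchangeable stable genes with baselines spread over
    18-26 cycles, plus optional planted-unstable genes given as
    {gene: total shift in cycles} and {gene: biological SD}.
    """
    if group_sizes is None:
        group_sizes = {"WT": 7, "KO": 7}
    shift_genes = shift_genes or {}
    noise_genes = noise_genes or {}
    genes = [f"STB{i + 1}" for i in range(n_stable)]
    genes += list(shift_genes) + list(noise_genes)
    baselines = {g: 18.0 + (26.0 - 18.0) * i / max(len(genes) - 1, 1)
                 for i, g in enumerate(genes)}
    sigma_b = {g: sigma_b_stable for g in genes}
    sigma_b.update(noise_genes)
    return CqSimConfig(gene_ids=genes, baselines=baselines,
                       group_sizes=group_sizes, group_shift=dict(shift_genes),
                       sigma_b=sigma_b, sigma_b_default=sigma_b_stable,
                       seed=seed, **kwargs)


def simulate_counts(cfg: CountSimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Negative-binomial gene x sample count matrix with known truth.

    The second and later groups carry the planted log2 effects theta (the
    first group is the reference); sample means are q_i * s_j * 2^theta.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = list(cfg.group_sizes)
    n_samples = sum(cfg.group_sizes.values())
    sf = (np.ones(n_samples) if cfg.size_factors is None
          else np.asarray(cfg.size_factors, dtype=float))
    if sf.size != n_samples:
        raise ValueError("size_factors length must equal the sample count")
    sample_ids, sample_groups = [], []
    for grp in groups:
        for j in range(cfg.group_sizes[grp]):
            sample_ids.append(f"{grp}_s{j + 1}")
            sample_groups.append(grp)
    mat = np.zeros((len(cfg.gene_ids), n_samples), dtype=int)
    for i, gene in enumerate(cfg.gene_ids):
        q = cfg.mean_expression[gene]
        alpha = cfg.dispersion[gene]
        theta = cfg.log2_effects.get(gene, 0.0)
        for j, (sid, grp) in enumerate(zip(sample_ids, sample_groups)):
            eff = theta if grp != groups[0] else 0.0
            mu = q * sf[j] * 2.0 ** eff
            if alpha == 0.0:
                mat[i, j] = rng.poisson(mu)
            else:
                size = 1.0 / alpha
                mat[i, j] = rng.negative_binomial(size, size / (size + mu))
    counts = pd.DataFrame(mat, index=cfg.gene_ids, columns=sample_ids)
    truth = SimTruth(log2_effects=dict(cfg.log2_effects),
                     dispersion=dict(cfg.dispersion))
    truth.stable_genes = [g for g in cfg.gene_ids
                          if cfg.log2_effects.get(g, 0.0) == 0.0]
    truth.unstable_genes = {g: "shift" for g in cfg.gene_ids
                            if cfg.log2_effects.get(g, 0.0) != 0.0}
    counts.attrs["group_map"] = dict(zip(sample_ids, sample_groups))
    return counts, truth


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: per-sample median of count ratios to the
    per-gene geometric mean, over genes positive in every sample."""
    mat = counts.to_numpy(dtype=float)
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no gene is positive in all samples; size factors undefined")
    ref = np.exp(np.log(mat[all_positive]).mean(axis=1, keepdims=True))
    ratios = mat[all_positive] / ref
    return pd.Series(np.median(ratios, axis=0), index=counts.columns,
                     name="size_factor")


def deseq_like_results(counts: pd.DataFrame, group_map: dict | pd.Series,
                       dispersion_truth: dict | None = None) -> pd.DataFrame:
    """Build a DESeq2-style results table from a count matrix.

    Size factors follow the median-of-ratios formula; base_mean is the
    mean normalized count over all samples; log2FC compares group means of
    normalized counts (pseudo-count 0.5); p-values come from Welch's t on
    log2(normalized count + 0.5) with Benjamini-Hochberg adjustment; the
    dispersion column is a method-of-moments estimate
    max{(var - mean)/mean^2, 0} on normalized counts, overridable with the
    simulation's true alpha for exactness.
    """
    group_map = pd.Series(group_map)
    groups = list(dict.fromkeys(group_map[counts.columns]))
    if len(groups) != 2:
        raise ValueError("results table expects exactly 2 groups")
    for grp in groups:
        if (group_map[counts.columns] == grp).sum() < 2:
            raise ValueError(f"group {grp!r} needs >= 2 samples")
    sf = median_of_ratios_size_factors(counts)
    norm = counts / sf
    cols1 = [s for s in counts.columns if group_map[s] == groups[0]]
    cols2 = [s for s in counts.columns if group_map[s] == groups[1]]
    mean1 = norm[cols1].mean(axis=1)
    mean2 = norm[cols2].mean(axis=1)
    log2fc = np.log2((mean2 + PSEUDOCOUNT) / (mean1 + PSEUDOCOUNT))
    logn = np.log2(norm + PSEUDOCOUNT)
    _, pvals = sps.ttest_ind(logn[cols2], logn[cols1], axis=1, equal_var=False)
    pvals = np.nan_to_num(pvals, nan=1.0)  # zero-variance rows: no evidence
    padj = multipletests(pvals, method="fdr_bh")[1]
    if dispersion_truth is not None:
        disp = pd.Series({g: dispersion_truth.get(g, np.nan) for g in counts.index})
    else:
        m = norm.mean(axis=1)
        v = norm.var(axis=1, ddof=1)
        disp = np.maximum((v - m) / m**2, 0.0)
    out = pd.DataFrame({
        "gene_id": counts.index,
        "base_mean": norm.mean(axis=1),
        "log2fc": log2fc,
        "padj": padj,
        "dispersion": pd.Series(disp, index=counts.index),
    }).reset_index(drop=True)
    out.attrs["size_factors"] = sf
    out.attrs["normalized_counts"] = norm
    return out
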