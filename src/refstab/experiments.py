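"""Seeded simulation studies validating the pipeline end to end.

Each function here is a self-contained computer experiment: it simulates
data with :mod:`refstab.synthetic_data`, runs the estimator under study,
and returns summary numbers.  The studies double as the package's
empirical validation (parameter recovery, ranking recovery, workflow
equivalence, test calibration) and are driven both by the test suite and
by ``scripts/acceptance.py`` and the ``analysis/`` scripts.

Problem sizes follow the study design the package emulates: technical
triplicates, 7 biological samples per group for the workflow-scale runs,
and larger n only where an estimator's sampling bias is the question.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .normalization import ddct_fold_change, normalization_factor
from .qpcr_io import aggregate_replicates
from .stability import (
    STATUS_ELIGIBLE,
    cv_analysis,
    linearize,
    normfinder,
)
from .stats import dunns_posthoc, kruskal_wallis
from .synthetic_data import CqSimConfig, default_panel_config, simulate_cq_dataset


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Independent per-replicate seeds below 2**31 derived from one seed."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def sigma_recovery_study(n_rep: int = 500, k: int = 10, n_g: int = 50,
                         seed: int = 0) -> dict:
    """Intragroup-variance recovery of the stability estimator.

    Simulates k genes in two groups of n_g with known biological SDs, no
    group effects, a shared sample-loading effect, and no technical layer
    (replicates collapse exactly), then compares the mean estimated
    sigma2_ig against the truth per gene and reports the shrinkage
    variance gamma2, which should vanish in the absence of group effects.
    """
    sigmas = np.linspace(0.1, 0.5, k)  # biological SDs, cycles
    genes = [f"G{i + 1}" for i in range(k)]
    truth = {g: s**2 for g, s in zip(genes, sigmas)}
    est_sum = np.zeros((k, 2))
    gamma2s = np.empty(n_rep)
    for r, s in enumerate(_child_seeds(seed, n_rep)):
        cfg = CqSimConfig(
            gene_ids=genes,
            baselines={g: 20.0 + i for i, g in enumerate(genes)},
            group_sizes={"A": n_g, "B": n_g},
            sigma_b={g: float(sg) for g, sg in zip(genes, sigmas)},
            sigma_s=0.2, sigma_t=0.0, replicates=2, seed=int(s),
        )
        table, _ = simulate_cq_dataset(cfg)
        agg = aggregate_replicates(table)
        res = normfinder(agg)
        est_sum += res.intragroup_var.loc[genes].to_numpy()
        gamma2s[r] = res.gamma2
    est_mean = est_sum / n_rep
    true_vec = np.array([truth[g] for g in genes])[:, None]
    rel_err = np.abs(est_mean - true_vec) / true_vec
    return {
        "genes": genes,
        "true_sigma2": {g: truth[g] for g in genes},
        "mean_estimated_sigma2": pd.DataFrame(est_mean, index=genes,
                                              columns=["A", "B"]),
        "max_rel_error": float(rel_err.max()),
        "mean_rel_error": float(rel_err.mean()),
        "mean_gamma2": float(gamma2s.mean()),
        "mean_true_sigma2": float(true_vec.mean()),
        "n_rep": n_rep,
    }


def ranking_recovery_study(n_runs: int = 100, n_g: int = 7, seed: int = 0,
                           shift: float = 0.8, noise_sd: float = 0.6) -> dict:
    """Recovery of planted-unstable genes by the stability ranking.

    Panels of 8 exchangeable stable genes plus one planted group-shift
    gene (total intergroup difference ``shift`` cycles) and one planted
    high-noise gene.  The stability estimator ranks the full panel (the
    CV gate is a separate, earlier screen and is reported alongside):
    counts how often both planted genes fall in the bottom 3 of the
    stability ranking and are excluded from the best pair.
    """
    planted = {"SHIFT", "NOISY"}
    bottom3 = 0
    pair_excluded = 0
    gate_excluded = 0
    for s in _child_seeds(seed, n_runs):
        cfg = default_panel_config(
            n_stable=8, shift_genes={"SHIFT": shift},
            noise_genes={"NOISY": noise_sd},
            group_sizes={"WT": n_g, "KO": n_g}, seed=int(s),
        )
        table, _ = simulate_cq_dataset(cfg)
        agg = aggregate_replicates(table)
        res = normfinder(agg)
        worst3 = set(res.stability.nlargest(3).index)
        if planted <= worst3:
            bottom3 += 1
        if not (planted & set(res.best_pair)):
            pair_excluded += 1
        cv = cv_analysis(linearize(agg))
        if (cv.loc[list(planted), "status"] != STATUS_ELIGIBLE).any():
            gate_excluded += 1
    return {
        "bottom3_rate": bottom3 / n_runs,
        "pair_exclusion_rate": pair_excluded / n_runs,
        "cv_gate_exclusion_rate": gate_excluded / n_runs,
        "n_runs": n_runs,
    }


#: planted target effects for the workflow-equivalence study (log2 FC)
EQUIVALENCE_THETAS = (-2.0, -1.0, -0.7, 0.7, 1.0, 2.0)


def _equivalence_config(seed: int, n_g: int, thetas) -> CqSimConfig:
    """Two disjoint 10-gene candidate panels plus planted-effect targets.

    Panels are all planted-stable; targets carry a group shift of
    -theta cycles so their true fold change in the treated group is
    2^theta.  All genes share each sample's loading effect, as on a real
    plate.
    """
    panel1 = [f"P1_{i + 1}" for i in range(10)]
    panel2 = [f"P2_{i + 1}" for i in range(10)]
    targets = [f"T{i + 1}" for i in range(len(thetas))]
    genes = panel1 + panel2 + targets
    baselines = {g: 18.0 + 8.0 * i / (len(genes) - 1) for i, g in enumerate(genes)}
    # target Cq shift = -theta (lower Cq = higher expression); realized as a
    # centered +/- profile, so the *difference* between groups must be -theta
    shifts = {t: -th for t, th in zip(targets, thetas)}
    return CqSimConfig(
        gene_ids=genes, baselines=baselines,
        group_sizes={"WT": n_g, "KO": n_g},
        group_shift=shifts, sigma_b={g: 0.1 for g in genes},
        sigma_s=0.2, sigma_t=0.05, replicates=3, seed=seed,
    )


def workflow_equivalence_study(n_runs: int = 100, n_g: int = 7, seed: int = 0,
                               thetas=EQUIVALENCE_THETAS,
                               alpha: float = 0.05) -> dict:
    """Do two independent stable panels yield the same target fold changes?

    Each run simulates one plate holding two disjoint 10-gene candidate
    panels and six targets with planted log2 effects.  Both panels run the
    full validation (replicate QC, CV gate, stability ranking, best-pair
    NF) and each target is quantified by 2^-ddCt against each panel's NF.
    Per target, the treated-group fold-change distributions under the two
    NFs are compared with Kruskal-Wallis and Dunn's test (panel-1 NF as
    control).  Reports the mean absolute difference in mean log2 FC
    between the two normalizations, the fraction of runs with no adjusted
    p < alpha, and the recovery of each planted effect.
    """
    panel1 = [f"P1_{i + 1}" for i in range(10)]
    panel2 = [f"P2_{i + 1}" for i in range(10)]
    targets = [f"T{i + 1}" for i in range(len(thetas))]
    diffs = []
    runs_all_null = 0
    log2fc = {t: [] for t in targets}
    for s in _child_seeds(seed, n_runs):
        cfg = _equivalence_config(int(s), n_g, thetas)
        table, _ = simulate_cq_dataset(cfg)
        agg = aggregate_replicates(table)
        nfs = []
        for panel in (panel1, panel2):
            cv = cv_analysis(linearize(agg), gate=50.0)
            eligible = [g for g in panel
                        if cv.loc[g, "status"] == STATUS_ELIGIBLE]
            res = normfinder(agg, eligible=eligible)
            nfs.append(normalization_factor(agg, res.best_pair))
        any_sig = False
        for t in targets:
            fcs = [ddct_fold_change(agg, t, nf, calibrator="WT") for nf in nfs]
            ko = [fc.group_values("KO").to_numpy() for fc in fcs]
            m1, m2 = (np.mean(np.log2(v)) for v in ko)
            diffs.append(abs(m1 - m2))
            log2fc[t].append(m1)
            kruskal_wallis(ko)
            dunn = dunns_posthoc(ko, control=0, adjust="bonferroni")
            if (dunn["p_adjusted"] < alpha).any():
                any_sig = True
        if not any_sig:
            runs_all_null += 1
    recovery = {}
    for t, th in zip(targets, thetas):
        vals = np.asarray(log2fc[t])
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        # Monte-Carlo interval at +/- 3 SE: the six per-target checks share
        # run-level noise, so a joint nominal-95% check would fail a
        # non-negligible fraction of seeds even for an unbiased estimator
        recovery[t] = {
            "theta": th, "mean_log2fc": float(vals.mean()),
            "mc_se": float(se),
            "ci_low": float(vals.mean() - 3 * se),
            "ci_high": float(vals.mean() + 3 * se),
            "recovered": bool(abs(vals.mean() - th) <= 3 * se),
        }
    return {
        "mean_abs_log2fc_diff": float(np.mean(diffs)),
        "max_abs_log2fc_diff": float(np.max(diffs)),
        "no_significant_rate": runs_all_null / n_runs,
        "recovery": recovery,
        "n_runs": n_runs,
    }


def dunn_null_calibration(n_rep: int = 2000, n_groups: int = 3,
                          n_per_group: int = 7, seed: int = 0,
                          alpha: float = 0.05) -> dict:
    """Family-wise type-I error of the adjusted Dunn procedure under the
    global null (all groups drawn from the same distribution)."""
    rng = np.random.default_rng(seed)
    false_pos = 0
    for _ in range(n_rep):
        groups = [rng.normal(size=n_per_group) for _ in range(n_groups)]
        dunn = dunns_posthoc(groups, control=0, adjust="bonferroni")
        if (dunn["p_adjusted"] < alpha).any():
            false_pos += 1
    rate = false_pos / n_rep
    return {"fwer": rate, "alpha": alpha, "n_rep": n_rep,
            "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_rep))}
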