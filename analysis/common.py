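"""Shared synthetic study used by the numbered analysis scripts.

One seeded "experiment in silico": an RNA-Seq screen of ~1500 genes in two
groups (WT vs KO, 6 samples each) feeding candidate selection, and a qPCR
plate measuring two 10-gene candidate panels (RNA-Seq-derived and
conventional) plus 6 targets in technical triplicate on 7 biological
samples per group.  Every script regenerates what it needs from the same
seed, so the scripts can run independently and in any order.
"""

from __future__ import annotations

import numpy as np

from refstab import (
    CountSimConfig,
    CqSimConfig,
    aggregate_replicates,
    compute_cv_from_dispersion,
    deseq_like_results,
    filter_reference_candidates,
    select_panel,
    select_targets,
    simulate_cq_dataset,
    simulate_counts,
)

STUDY_SEED = 11
N_GENES = 1500

#: widely used housekeeping genes measured as the conventional panel
CONVENTIONAL_PANEL = ["ACTB", "GAPDH", "B2M", "HPRT1", "PPIA",
                      "TBP", "UBC", "GUSB", "RPL13A", "PGK1"]

#: planted log2 effects of the qPCR target genes
TARGET_EFFECTS = {"T_UP1": 0.7, "T_UP2": 1.0, "T_UP3": 2.0,
                  "T_DN1": -0.7, "T_DN2": -1.0, "T_DN3": -2.0}


def rnaseq_study(seed: int = STUDY_SEED):
    """Simulated counts + DESeq-like results table with CVfromDisp."""
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:04d}" for i in range(N_GENES)]
    effects = {g: 0.0 for g in genes}
    for i, g in enumerate(genes):
        if i % 15 == 0:
            effects[g] = float(rng.choice([-2.0, -1.2, 1.2, 2.0]))
    cfg = CountSimConfig(
        gene_ids=genes,
        mean_expression={g: float(m) for g, m in
                         zip(genes, rng.lognormal(6.2, 1.6, N_GENES))},
        dispersion={g: float(a) for g, a in
                    zip(genes, rng.uniform(0.004, 0.08, N_GENES))},
        group_sizes={"WT": 6, "KO": 6},
        log2_effects=effects,
        seed=seed,
    )
    counts, truth = simulate_counts(cfg)
    results = compute_cv_from_dispersion(
        deseq_like_results(counts, counts.attrs["group_map"],
                           dispersion_truth=cfg.dispersion))
    return counts, results, truth


def screened_panel(seed: int = STUDY_SEED):
    """Reference-candidate pool, 3/3/3/1 panel, and DE target lists."""
    counts, results, truth = rnaseq_study(seed)
    pool = filter_reference_candidates(results)
    panel = select_panel(pool, allocation=(3, 3, 3, 1), strategy="lowest_cv")
    up, down = select_targets(results, seed=seed)
    return counts, results, truth, pool, panel, up, down


def target_counts(seed: int = STUDY_SEED):
    """Small RNA-Seq count simulation carrying the six targets' effects.

    The six qPCR targets plus 40 background genes (for size factors),
    normalized by median-of-ratios; used for the RNA-Seq fold-change arm
    of the cross-method comparison.
    """
    from refstab import median_of_ratios_size_factors

    rng = np.random.default_rng(seed + 2)
    background = [f"BG{i:02d}" for i in range(40)]
    genes = list(TARGET_EFFECTS) + background
    cfg = CountSimConfig(
        gene_ids=genes,
        mean_expression={g: float(m) for g, m in
                         zip(genes, rng.lognormal(6.5, 1.0, len(genes)))},
        dispersion={g: 0.02 for g in genes},
        group_sizes={"WT": 6, "KO": 6},
        log2_effects=dict(TARGET_EFFECTS),
        seed=seed + 2,
    )
    counts, truth = simulate_counts(cfg)
    sf = median_of_ratios_size_factors(counts)
    norm = counts / sf
    group_map = counts.attrs["group_map"]
    return norm, group_map, truth


def qpcr_plate(seed: int = STUDY_SEED):
    """Simulated Cq plate: both panels plus targets, aggregated.

    The RNA-Seq-derived panel is uniformly stable (that is what the screen
    selects for); the conventional panel contains two genes that are in
    fact condition-dependent (a 0.8-cycle shift and a high-noise gene),
    mirroring the common failure mode of unvalidated housekeeping genes.
    """
    _, _, _, _, panel, _, _ = screened_panel(seed)
    rnaseq_panel = list(panel.gene_ids)
    genes = rnaseq_panel + CONVENTIONAL_PANEL + list(TARGET_EFFECTS)
    rng = np.random.default_rng(seed + 1)
    baselines = {g: float(b) for g, b in
                 zip(genes, rng.uniform(18.0, 26.0, len(genes)))}
    shifts = {t: -th for t, th in TARGET_EFFECTS.items()}
    shifts["GAPDH"] = 0.8          # condition-dependent conventional gene
    sigma_b = {g: 0.1 for g in genes}
    sigma_b["ACTB"] = 0.6          # high-noise conventional gene
    cfg = CqSimConfig(
        gene_ids=genes, baselines=baselines,
        group_sizes={"WT": 7, "KO": 7},
        group_shift=shifts, sigma_b=sigma_b,
        sigma_s=0.2, sigma_t=0.05, replicates=3, seed=seed + 1,
    )
    table, truth = simulate_cq_dataset(cfg)
    agg = aggregate_replicates(table)
    return agg, rnaseq_panel, truth
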