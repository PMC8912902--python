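"""Seeded generators: Cq model, NB counts and the DESeq-like table."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from refstab.qpcr_io import FLAG_INCONSISTENT, aggregate_replicates
from refstab.stability import intrinsic_variation_test, relative_quantity
from refstab.synthetic_data import (
    CountSimConfig,
    CqSimConfig,
    default_panel_config,
    deseq_like_results,
    median_of_ratios_size_factors,
    simulate_cq_dataset,
    simulate_counts,
)


class TestSimulateCq:
    def test_noiseless_limit_is_exact(self):
        cfg = CqSimConfig(
            gene_ids=["A", "B"], baselines={"A": 20.0, "B": 25.0},
            group_sizes={"WT": 3, "KO": 3}, sigma_b={"A": 0.0, "B": 0.0},
            sigma_b_default=0.0, sigma_s=0.0, sigma_t=0.0, replicates=3, seed=0,
        )
        table, _ = simulate_cq_dataset(cfg)
        assert (table.data.loc[table.data["gene_id"] == "A", "cq"] == 20.0).all()
        assert (table.data.loc[table.data["gene_id"] == "B", "cq"] == 25.0).all()

    def test_seed_reproducibility(self):
        cfg = default_panel_config(seed=5)
        t1, _ = simulate_cq_dataset(cfg)
        t2, _ = simulate_cq_dataset(default_panel_config(seed=5))
        pd.testing.assert_frame_equal(t1.data, t2.data)
        t3, _ = simulate_cq_dataset(default_panel_config(seed=6))
        assert not t1.data["cq"].equals(t3.data["cq"])

    def test_low_tech_noise_rarely_inconsistent(self):
        """With sigma_t = 0.05 the replicate SD (chi distribution, 2 df)
        almost never exceeds 0.20, so inconsistent flags are ~0%."""
        n_cells = 0
        n_bad = 0
        for seed in range(10):
            cfg = default_panel_config(seed=seed, sigma_t=0.05)
            table, _ = simulate_cq_dataset(cfg)
            agg = aggregate_replicates(table)
            n_cells += agg.flags.size
            n_bad += (agg.flags == FLAG_INCONSISTENT).sum().sum()
        assert n_bad / n_cells < 0.01

    def test_planted_shift_detected_by_intrinsic_test(self):
        """A +/-0.25-cycle group profile (0.5 total) on one gene is picked
        up by the exact Mann-Whitney test in most runs at n_g = 7."""
        hits = 0
        n_runs = 30
        for seed in range(n_runs):
            cfg = default_panel_config(
                n_stable=5, shift_genes={"SHIFT": 0.5},
                group_sizes={"WT": 7, "KO": 7}, sigma_b_stable=0.15, seed=seed,
            )
            cfg.sigma_b["SHIFT"] = 0.15
            table, _ = simulate_cq_dataset(cfg)
            agg = aggregate_replicates(table)
            rq = relative_quantity(agg, "WT")
            out = intrinsic_variation_test(rq)
            hits += out.loc["SHIFT", "p_value"] < 0.05
        assert hits > n_runs / 2

    def test_truth_partition(self):
        cfg = default_panel_config(n_stable=4, shift_genes={"S": 1.0},
                                   noise_genes={"N": 0.5})
        _, truth = simulate_cq_dataset(cfg)
        assert set(truth.unstable_genes) == {"S", "N"}
        assert truth.unstable_genes["S"] == "shift"
        assert truth.unstable_genes["N"] == "noise"
        assert not set(truth.stable_genes) & set(truth.unstable_genes)


class TestSimulateCounts:
    def _cfg(self, alpha, n=200, seed=0, **kwargs):
        genes = [f"g{i}" for i in range(n)]
        return CountSimConfig(
            gene_ids=genes,
            mean_expression={g: 500.0 for g in genes},
            dispersion={g: alpha for g in genes},
            group_sizes={"WT": 4, "KO": 4},
            seed=seed, **kwargs,
        )

    def test_poisson_limit(self):
        counts, _ = simulate_counts(self._cfg(alpha=0.0))
        vals = counts.to_numpy().ravel()
        # Poisson: variance ~ mean
        assert vals.var() / vals.mean() == pytest.approx(1.0, rel=0.2)

    def test_nb_moment_relationship(self):
        alpha = 0.05
        counts, _ = simulate_counts(self._cfg(alpha=alpha, n=2000))
        vals = counts.to_numpy(dtype=float)
        ratio = vals.var(axis=1, ddof=1).mean() / vals.mean()
        assert ratio == pytest.approx(1 + alpha * vals.mean(), rel=0.1)

    def test_size_factor_scales_totals(self):
        sf = [1.0] * 7 + [2.0]
        counts, _ = simulate_counts(self._cfg(alpha=0.01, size_factors=sf))
        totals = counts.sum(axis=0).to_numpy(dtype=float)
        assert totals[-1] / totals[:-1].mean() == pytest.approx(2.0, rel=0.1)

    def test_seeded_byte_identical(self):
        c1, _ = simulate_counts(self._cfg(alpha=0.02, seed=3))
        c2, _ = simulate_counts(self._cfg(alpha=0.02, seed=3))
        pd.testing.assert_frame_equal(c1, c2)


class TestDeseqLikeResults:
    def test_identical_samples_trivial(self):
        counts = pd.DataFrame(
            np.tile(np.array([[100], [200], [300]]), (1, 4)),
            index=["a", "b", "c"], columns=["w1", "w2", "k1", "k2"],
        )
        gm = {"w1": "WT", "w2": "WT", "k1": "KO", "k2": "KO"}
        res = deseq_like_results(counts, gm)
        assert np.allclose(res.attrs["size_factors"], 1.0)
        assert np.allclose(res["log2fc"], 0.0)

    def test_median_of_ratios_property(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.poisson(300, size=(50, 6)) + 1,
                              index=[f"g{i}" for i in range(50)],
                              columns=[f"s{i}" for i in range(6)])
        sf0 = median_of_ratios_size_factors(counts)
        doubled = counts.copy()
        doubled["s0"] = doubled["s0"] * 2
        sf1 = median_of_ratios_size_factors(doubled)
        # doubling one column doubles its size factor relative to the
        # others (the per-gene geometric means shift by a common 2^(1/n),
        # so only size-factor ratios are identifiable)
        assert (sf1["s0"] / sf1["s1"]) == pytest.approx(
            2 * sf0["s0"] / sf0["s1"], rel=1e-9)
        norm0 = counts["s0"] / sf0["s0"]
        norm1 = doubled["s0"] / sf1["s0"]
        ratio = (norm1 / norm0).to_numpy()
        assert np.allclose(ratio, ratio[0])  # unchanged up to a global factor

    def test_bh_adjustment_step_up(self):
        # independent check of the padj mechanics on a known case:
        # p = (.01,.02,.03,.04), m = 4 -> all adjusted to 0.04
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, 0.04)

    def test_planted_effects_yield_de_calls(self):
        genes = [f"g{i}" for i in range(300)]
        cfg = CountSimConfig(
            gene_ids=genes,
            mean_expression={g: 800.0 for g in genes},
            dispersion={g: 0.01 for g in genes},
            group_sizes={"WT": 6, "KO": 6},
            log2_effects={g: (2.0 if i < 20 else 0.0)
                          for i, g in enumerate(genes)},
            seed=11,
        )
        counts, _ = simulate_counts(cfg)
        res = deseq_like_results(counts, counts.attrs["group_map"])
        called = set(res.loc[(res["padj"] < 0.05) & (res["log2fc"] > 1),
                             "gene_id"])
        planted = {g for i, g in enumerate(genes) if i < 20}
        assert len(called & planted) >= 18
        assert len(called - planted) <= 3

    def test_no_all_positive_gene_rejected(self):
        counts = pd.DataFrame([[0, 5], [5, 0]], index=["a", "b"],
                              columns=["s1", "s2"])
        with pytest.raises(ValueError, match="positive"):
            median_of_ratios_size_factors(counts)
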