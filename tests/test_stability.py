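"""CV screen, intrinsic-variation test and the NormFinder estimator."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from refstab.qpcr_io import aggregate_replicates
from refstab.stability import (
    STATUS_ELIGIBLE,
    STATUS_EXCLUDED_CV,
    StabilityError,
    cv_analysis,
    intrinsic_variation_test,
    linearize,
    normfinder,
    normfinder_best_pair,
    relative_quantity,
    stability_report,
)
from refstab.synthetic_data import CqSimConfig, default_panel_config, simulate_cq_dataset


def _matrix(values, samples, groups):
    cq = pd.DataFrame(values, columns=samples)
    cq.index = [f"G{i + 1}" for i in range(len(values))]
    gm = pd.Series(groups, index=samples)
    return cq, gm


class TestRelativeQuantities:
    def test_linearize_closed_forms(self):
        cq, gm = _matrix([[20.0, 0.0]], ["a", "b"], ["WT", "KO"])
        rq = linearize(cq, gm)
        assert rq.values.iloc[0, 0] == pytest.approx(2.0**-20)
        assert rq.values.iloc[0, 1] == pytest.approx(1.0)

    def test_one_cycle_halves_signal(self):
        cq, gm = _matrix([[20.0, 21.0]], ["a", "b"], ["WT", "KO"])
        rq = linearize(cq, gm)
        assert rq.values.iloc[0, 1] == pytest.approx(rq.values.iloc[0, 0] / 2)

    def test_calibrated_identity(self):
        cq, gm = _matrix([[20.0, 20.0, 19.0]], ["a", "b", "c"],
                         ["WT", "WT", "KO"])
        rq = relative_quantity(cq, "WT", gm)
        assert rq.values.iloc[0, 2] == pytest.approx(2.0)
        assert rq.values.iloc[0, 0] == pytest.approx(1.0)

    def test_calibrator_geometric_mean_is_one(self):
        rng = np.random.default_rng(0)
        cq, gm = _matrix(rng.uniform(18, 26, (5, 8)),
                         [f"s{i}" for i in range(8)],
                         ["WT"] * 4 + ["KO"] * 4)
        rq = relative_quantity(cq, "WT", gm)
        cal = rq.values[[f"s{i}" for i in range(4)]]
        gmean = np.exp(np.log(cal).mean(axis=1))
        assert np.allclose(gmean, 1.0)

    def test_unknown_calibrator(self):
        cq, gm = _matrix([[20.0, 20.0]], ["a", "b"], ["WT", "KO"])
        with pytest.raises(StabilityError, match="calibrator"):
            relative_quantity(cq, "XX", gm)


class TestIntrinsicVariation:
    def test_separated_groups_exact_p(self):
        cq, gm = _matrix([[1, 2, 3, 4, 5, 6]], [f"s{i}" for i in range(6)],
                         ["WT"] * 3 + ["KO"] * 3)
        rq = linearize(cq, gm)
        out = intrinsic_variation_test(rq)
        assert out["p_value"].iloc[0] == pytest.approx(0.100)

    def test_three_groups_rejected(self):
        cq, gm = _matrix([[1, 2, 3, 4, 5, 6]], [f"s{i}" for i in range(6)],
                         ["A", "A", "B", "B", "C", "C"])
        with pytest.raises(StabilityError, match="two-group"):
            intrinsic_variation_test(linearize(cq, gm))


class TestCvAnalysis:
    def test_constant_gene_cv_zero_rank_one(self):
        cq, gm = _matrix([[20, 20, 20, 20], [20, 21, 19, 22]],
                         list("abcd"), ["WT", "WT", "KO", "KO"])
        out = cv_analysis(linearize(cq, gm))
        assert out.loc["G1", "cv_percent"] == pytest.approx(0.0)
        assert out.loc["G1", "cv_rank"] == 1

    def test_hand_computed_cv_and_gate(self):
        # linear values (1,1,1,3): mean 1.5, sample SD 1.0 -> CV 66.7%
        vals = -np.log2(np.array([[1.0, 1.0, 1.0, 3.0]]))
        cq, gm = _matrix(vals, list("abcd"), ["WT", "WT", "KO", "KO"])
        out = cv_analysis(linearize(cq, gm), gate=50.0)
        assert out.loc["G1", "cv_percent"] == pytest.approx(100 / 1.5, rel=1e-9)
        assert out.loc["G1", "status"] == STATUS_EXCLUDED_CV

    def test_cv_scale_invariant(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(18, 22, (1, 6))
        cq1, gm = _matrix(base, [f"s{i}" for i in range(6)],
                          ["WT"] * 3 + ["KO"] * 3)
        cq2 = cq1 + 3.0  # multiplies every linearized value by 2^-3
        out1 = cv_analysis(linearize(cq1, gm))
        out2 = cv_analysis(linearize(cq2, gm))
        assert out1["cv_percent"].iloc[0] == pytest.approx(
            out2["cv_percent"].iloc[0])


class TestNormFinder:
    def _sim_agg(self, seed=0, **kwargs):
        cfg = default_panel_config(seed=seed, **kwargs)
        table, _ = simulate_cq_dataset(cfg)
        return aggregate_replicates(table)

    def test_no_variation_all_scores_zero(self):
        cq, gm = _matrix(np.full((4, 6), 20.0), [f"s{i}" for i in range(6)],
                         ["WT"] * 3 + ["KO"] * 3)
        res = normfinder(cq, gm)
        assert np.allclose(res.stability, 0.0)
        assert res.gamma2 == 0.0
        assert np.allclose(res.intragroup_var, 0.0)

    def test_double_centering_identities(self, panel_agg):
        agg, _ = panel_agg
        res = normfinder(agg)
        d = res.intergroup_dev.to_numpy()
        assert np.allclose(d.sum(axis=1), 0.0, atol=1e-10)  # per gene
        assert np.allclose(d.sum(axis=0), 0.0, atol=1e-10)  # per group

    def test_shrinkage_contracts_deviations(self, panel_agg):
        agg, _ = panel_agg
        res = normfinder(agg)
        assert (res.shrunken_dev.abs().to_numpy()
                <= res.intergroup_dev.abs().to_numpy() + 1e-12).all()
        assert (res.intragroup_var.to_numpy() >= 0).all()
        assert (res.stability >= 0).all()

    def test_invariance_under_sample_and_gene_offsets(self, panel_agg):
        agg, _ = panel_agg
        res0 = normfinder(agg)
        rng = np.random.default_rng(2)
        cq = agg.cq.copy()
        cq = cq + rng.normal(0, 0.5, size=cq.shape[1])[None, :]  # per sample
        cq = cq.add(pd.Series(rng.normal(0, 1.0, size=cq.shape[0]),
                              index=cq.index), axis=0)  # per gene
        res1 = normfinder(cq, agg.group_map)
        assert np.allclose(res0.stability, res1.stability, atol=1e-10)
        assert res1.best_pair == res0.best_pair

    def test_planted_shift_gene_has_largest_score(self):
        hits = 0
        for seed in range(40):
            agg = self._sim_agg(seed=seed, n_stable=9,
                                shift_genes={"SHIFT": 2.0},
                                group_sizes={"WT": 8, "KO": 8})
            res = normfinder(agg)
            hits += res.stability.idxmax() == "SHIFT"
        assert hits >= 38  # >= 95% of seeded replicates

    def test_k_below_three_rejected(self):
        cq, gm = _matrix(np.full((2, 4), 20.0), list("abcd"),
                         ["WT", "WT", "KO", "KO"])
        with pytest.raises(StabilityError, match=">= 3 genes"):
            normfinder(cq, gm)

    def test_singleton_group_rejected(self):
        cq, gm = _matrix(np.full((3, 3), 20.0), list("abc"),
                         ["WT", "WT", "KO"])
        with pytest.raises(StabilityError, match="< 2 samples"):
            normfinder(cq, gm)


class TestBestPair:
    def test_opposite_deviations_cancel(self):
        """Two genes with exactly opposite group deviations: the pair's
        deviation term is zero, leaving the pure variance term."""
        rng = np.random.default_rng(3)
        n_g = 30
        samples = [f"s{i}" for i in range(2 * n_g)]
        gm = pd.Series(["A"] * n_g + ["B"] * n_g, index=samples)
        noise = rng.normal(0, 0.05, size=(6, 2 * n_g))
        cq = pd.DataFrame(20.0 + noise, index=[f"G{i}" for i in range(6)],
                          columns=samples)
        shift = np.r_[np.full(n_g, -0.5), np.full(n_g, 0.5)]
        cq.iloc[0] += shift
        cq.iloc[1] -= shift
        res = normfinder(cq, gm)
        d = res.shrunken_dev
        pair_dev = (d.loc["G0"] + d.loc["G1"]) / 2
        assert np.allclose(pair_dev, 0.0, atol=0.05)

    def test_exhaustive_equals_bruteforce(self, panel_agg):
        agg, _ = panel_agg
        res = normfinder(agg)
        n_g = res.group_sizes.to_numpy(dtype=float)
        best, best_s = None, np.inf
        for a, b in combinations(sorted(res.stability.index, key=str), 2):
            d_pair = (res.shrunken_dev.loc[a].to_numpy()
                      + res.shrunken_dev.loc[b].to_numpy()) / 2
            v_pair = (res.intragroup_var.loc[a].to_numpy()
                      + res.intragroup_var.loc[b].to_numpy()) / (4 * n_g)
            shrink = np.where(res.gamma2 + v_pair > 0,
                              v_pair * res.gamma2 / (res.gamma2 + v_pair), 0.0)
            s = float(np.mean(np.abs(d_pair) + np.sqrt(shrink)))
            if s < best_s:
                best, best_s = (a, b), s
        assert res.best_pair == best
        assert res.pair_stability == pytest.approx(best_s)

    def test_identical_ideal_genes_tie_lexicographic(self):
        cq = pd.DataFrame(np.full((4, 6), 20.0),
                          index=["Z", "Y", "B", "A"],
                          columns=[f"s{i}" for i in range(6)])
        gm = pd.Series(["WT"] * 3 + ["KO"] * 3, index=cq.columns)
        res = normfinder(cq, gm)
        assert res.best_pair == ("A", "B")


class TestStabilityReport:
    def test_excluded_gene_never_in_best_pair(self):
        cfg = default_panel_config(
            n_stable=8, noise_genes={"WILD": 2.5}, shift_genes={},
            group_sizes={"WT": 7, "KO": 7}, seed=9,
        )
        table, _ = simulate_cq_dataset(cfg)
        agg = aggregate_replicates(table)
        rep = stability_report(agg, calibrator="WT")
        excluded = set(rep.table.index[rep.table["status"] == STATUS_EXCLUDED_CV])
        assert "WILD" in excluded  # sigma_b = 2.5 cycles -> CV far above 50%
        assert not (excluded & set(rep.best_pair))

    def test_report_columns_and_footer(self, panel_agg, tmp_path):
        agg, _ = panel_agg
        rep = stability_report(agg, calibrator="WT")
        for col in ["cv_percent", "cv_rank", "status", "mw_p_value",
                    "stability", "stability_rank"]:
            assert col in rep.table.columns
        out = tmp_path / "report.csv"
        rep.to_csv(out)
        text = out.read_text()
        assert "best pair" in text and rep.best_pair[0] in text
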