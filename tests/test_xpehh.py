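import numpy as np
import pandas as pd
import pytest

import selsig
from _oracles import ies_pairs_oracle
from conftest import make_panel
from selsig.xpehh import (DegenerateScanError, bifurcation, fdr_adjust, ies,
                          significant_windows, site_ehh, xpehh)


def records_frame(positions, scores):
    return pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(len(positions))],
        "chrom": "chr1", "position": positions, "standardized": scores})


class TestSiteEhh:
    def test_identical_haplotypes_stay_at_one(self):
        panel = make_panel(np.tile([0, 1, 1, 0, 1], (6, 1)), populations=["P"] * 3)
        curve = site_ehh(panel, "P", 2, "right")
        assert (curve.ehh == 1.0).all()
        assert curve.truncated_at_end

    def test_partition_2_1_1_gives_one_sixth(self):
        # over {core, flank}: prefixes (0,0) x2, (0,1) x1, (1,1) x1
        panel = make_panel(np.array([[0, 0], [0, 0], [0, 1], [1, 1]]),
                           populations=["P"] * 2)
        curve = site_ehh(panel, "P", 0, "right")
        assert curve.ehh[1] == pytest.approx(2 / 12)

    def test_all_distinct_drops_to_zero(self):
        alleles = np.array([[0, 0, 0], [0, 1, 0], [1, 0, 1], [1, 1, 1]])
        panel = make_panel(alleles, populations=["P"] * 2)
        curve = site_ehh(panel, "P", 0, "right", ehh_cutoff=0.0)
        assert curve.ehh[1] == 0.0

    def test_curve_monotone_with_unit_start(self):
        rng = np.random.default_rng(14)
        for seed in range(5):
            cfg = selsig.SimulationConfig(n_individuals_per_pop=(10, 10),
                                          snps_per_chromosome=60, seed=seed)
            panel = selsig.simulate_panel(cfg)
            core = int(rng.integers(0, 60))
            for direction in ("left", "right"):
                c = site_ehh(panel, "SWB", core, direction)
                assert c.ehh[0] == 1.0
                assert (np.diff(c.ehh) <= 1e-12).all()
                assert ((0 <= c.ehh) & (c.ehh <= 1)).all()


class TestIes:
    def test_rectangle_integral(self):
        # EHH = 1 everywhere over +-4 kb
        panel = make_panel(np.tile([1, 0, 1, 0, 1], (8, 1)),
                           pos=[1000, 3000, 5000, 7000, 9000],
                           populations=["P"] * 4)
        assert ies(panel, "P", 2) == pytest.approx(8000)

    def test_hand_built_trapezoid_sum(self):
        # right side decays 1, 1/2, 1/6, 0 and left side 1, 1/3, 0 at 10-kb
        # steps: iES = (7500 + 10000*(1/2+1/6)/2) + 10000*(1+1/3)/2 = 17500
        cols = {
            "l2": [0, 1, 0, 1], "l1": [0, 0, 1, 1], "core": [0, 0, 0, 0],
            "r1": [0, 0, 0, 1], "r2": [0, 1, 0, 1], "r3": [0, 1, 1, 0]}
        alleles = np.array(list(cols.values())).T
        panel = make_panel(alleles, pos=[1000, 11_000, 21_000, 31_000,
                                         41_000, 51_000],
                           populations=["P"] * 2)
        got = ies(panel, "P", 2)
        assert got == pytest.approx(17_500.0, abs=1e-9)
        assert got == pytest.approx(ies_pairs_oracle(panel, "P", 2), abs=1e-9)

    def test_identical_panels_give_equal_ies(self):
        cfg = selsig.SimulationConfig(n_individuals_per_pop=(8, 8),
                                      bn_F=(0.0, 0.0),
                                      snps_per_chromosome=50, seed=3)
        panel = selsig.simulate_panel(cfg)
        a = panel.haplotype_rows("SWB")
        b = panel.haplotype_rows("EXM")
        panel.alleles[b] = panel.alleles[a]
        for core in (5, 25, 44):
            assert ies(panel, "SWB", core) == pytest.approx(
                ies(panel, "EXM", core), abs=1e-9)

    def test_single_snp_chromosome_is_degenerate(self):
        panel = make_panel(np.array([[0], [1]]), populations=["P"])
        with pytest.raises(ValueError, match="degenerate"):
            ies(panel, "P", 0)

    def test_matches_pairwise_oracle_on_random_panels(self):
        rng = np.random.default_rng(55)
        for seed in range(10):
            cfg = selsig.SimulationConfig(n_individuals_per_pop=(6, 4),
                                          snps_per_chromosome=40,
                                          chromosome_length=400_000,
                                          bn_F=(0.15, 0.15), seed=seed)
            panel = selsig.simulate_panel(cfg)
            core = int(rng.integers(0, 40))
            for pop in ("SWB", "EXM"):
                assert ies(panel, pop, core) == pytest.approx(
                    ies_pairs_oracle(panel, pop, core), abs=1e-9)


class TestXpehh:
    def test_identical_panels_flagged_degenerate(self):
        cfg = selsig.SimulationConfig(n_individuals_per_pop=(6, 6),
                                      bn_F=(0.0, 0.0),
                                      snps_per_chromosome=40, seed=2)
        panel = selsig.simulate_panel(cfg)
        panel.alleles[panel.haplotype_rows("EXM")] = \
            panel.alleles[panel.haplotype_rows("SWB")]
        with pytest.raises(DegenerateScanError):
            xpehh(panel, "SWB", "EXM")

    def test_standardisation_and_antisymmetry(self):
        cfg = selsig.SimulationConfig(n_individuals_per_pop=(30, 30),
                                      snps_per_chromosome=400,
                                      chromosome_length=4_000_000,
                                      bn_F=(0.1, 0.1), seed=21)
        panel = selsig.simulate_panel(cfg)
        ab = xpehh(panel, "SWB", "EXM")
        assert ab["standardized"].mean() == pytest.approx(0.0, abs=1e-9)
        assert ab["standardized"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        assert (ab["q_value"] >= ab["p_value"] - 1e-15).all()
        ba = xpehh(panel, "EXM", "SWB")
        np.testing.assert_allclose(ba["raw"], -ab["raw"], atol=1e-12)
        np.testing.assert_allclose(ba["standardized"], -ab["standardized"],
                                   atol=1e-9)


class TestSignificantWindows:
    def test_min_snp_rule(self):
        # 3 extreme SNPs in the first window, 2 in the second, and a body
        # of unremarkable scores
        recs = records_frame(
            [10_000, 20_000, 30_000, 600_000, 700_000]
            + list(range(1_000_001, 1_500_001, 4000)),
            [8.0, 7.5, 9.0, 7.0, 7.2] + [0.001 * k for k in range(125)])
        win = significant_windows(recs)
        spans = set(zip(win["chrom"], win["start_bp"]))
        assert ("chr1", 1) in spans
        assert ("chr1", 500_001) not in spans

    def test_spread_scores_give_no_window(self):
        recs = records_frame(list(range(10_000, 200_000, 10_000)),
                             [0.1 * k for k in range(19)])
        assert len(significant_windows(recs, min_snps=3)) == 0

    def test_window_mean_over_extreme_snps_only(self):
        recs = records_frame([10_000, 20_000, 30_000, 40_000],
                             [6.0, 8.0, 10.0, 0.0])
        win = significant_windows(recs, threshold=4.34, percentile=0.99)
        assert len(win) == 1
        assert win["n_significant_snps"].iloc[0] == 3
        assert win["mean_xpehh"].iloc[0] == pytest.approx(8.0)
        assert win["mean_xpehh_all_snps"].iloc[0] == pytest.approx(6.0)


class TestFdr:
    def test_longhand_three_values(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03], atol=1e-12)

    def test_all_ones_stay_one(self):
        assert (fdr_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(1)
        p = rng.random(100)
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestBifurcation:
    def test_identical_haplotypes_form_path(self):
        panel = make_panel(np.tile([0, 1, 0, 1], (6, 1)), populations=["P"] * 3)
        tree = bifurcation(panel, "P", 0, "right", max_snps=3)
        node, depth = tree, 0
        while node["children"]:
            assert len(node["children"]) == 1
            assert node["count"] == 6
            node = next(iter(node["children"].values()))
            depth += 1
        assert depth == 4                     # core + 3 flanking SNPs

    def test_fully_distinct_by_second_snp(self):
        alleles = np.array([[0, 0, 0], [0, 1, 0], [1, 0, 1], [1, 1, 0]])
        panel = make_panel(alleles, populations=["P"] * 2)
        tree = bifurcation(panel, "P", 0, "right", max_snps=2)

        def leaves(node):
            if not node["children"]:
                return [node["count"]]
            return [c for ch in node["children"].values() for c in leaves(ch)]

        assert sorted(leaves(tree)) == [1, 1, 1, 1]

    def test_counts_conserved_at_every_depth(self):
        cfg = selsig.SimulationConfig(n_individuals_per_pop=(10, 10),
                                      snps_per_chromosome=30, seed=13)
        panel = selsig.simulate_panel(cfg)
        level = [bifurcation(panel, "SWB", 15, "left", max_snps=8)]
        while level:
            assert sum(n["count"] for n in level) == 20
            level = [c for n in level for c in n["children"].values()]

    def test_truncates_at_chromosome_end(self):
        panel = make_panel(np.tile([0, 1, 0], (4, 1)), populations=["P"] * 2)
        tree = bifurcation(panel, "P", 1, "right", max_snps=50)
        depth = 0
        level = [tree]
        while any(n["children"] for n in level):
            level = [c for n in level for c in n["children"].values()]
            depth += 1
        assert depth == 2                     # core + single right flank
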