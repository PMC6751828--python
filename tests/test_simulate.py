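import numpy as np
import pytest

import selsig
from selsig.io import MISSING
from selsig.simulate import _substream


def nei_fst_from_frequencies(p1, p2):
    """Independent frequency-based oracle: ratio-of-sums Nei G_ST."""
    pbar = (p1 + p2) / 2
    ht = 2 * pbar * (1 - pbar)
    hs = p1 * (1 - p1) + p2 * (1 - p2)
    ok = ht > 0
    return (ht[ok] - hs[ok]).sum() / ht[ok].sum()


class TestSimulatePanel:
    def test_same_seed_gives_identical_panels(self):
        cfg = selsig.SimulationConfig(n_individuals_per_pop=(10, 10),
                                      snps_per_chromosome=100, seed=42)
        a = selsig.simulate_panel(cfg)
        b = selsig.simulate_panel(cfg)
        np.testing.assert_array_equal(a.alleles, b.alleles)
        assert a.markers.table.equals(b.markers.table)

    def test_no_drift_means_no_differentiation(self):
        cfg = selsig.SimulationConfig(n_individuals_per_pop=(50, 50),
                                      snps_per_chromosome=1000,
                                      bn_F=(0.0, 0.0), seed=1)
        geno = selsig.collapse_to_genotypes(selsig.simulate_panel(cfg))
        assert selsig.mean_weighted_fst(geno, ("SWB", "EXM")) < 0.02

    def test_sample_frequencies_recover_latent_frequencies(self):
        cfg = selsig.SimulationConfig(n_individuals_per_pop=(5000, 2),
                                      snps_per_chromosome=500,
                                      bn_F=(0.1, 0.1), seed=8)
        panel, latent = selsig.simulate_panel(cfg, return_frequencies=True)
        rows = panel.haplotype_rows("SWB")
        sample = panel.alleles[rows].mean(axis=0)
        se = np.sqrt(latent[0] * (1 - latent[0]) / rows.size)
        within = np.abs(sample - latent[0]) <= 3 * np.maximum(se, 1e-4)
        assert within.mean() >= 0.98        # ~99.7% nominal per SNP

    @pytest.mark.parametrize("bn_f", [0.05, 0.1, 0.2])
    def test_fst_recovery_matches_frequency_oracle(self, bn_f):
        cfg = selsig.SimulationConfig(n_individuals_per_pop=(100, 100),
                                      snps_per_chromosome=5000,
                                      bn_F=(bn_f, bn_f), seed=17)
        panel, latent = selsig.simulate_panel(cfg, return_frequencies=True)
        geno = selsig.collapse_to_genotypes(panel)
        got = selsig.mean_weighted_fst(geno, ("SWB", "EXM"))
        want = nei_fst_from_frequencies(latent[0], latent[1])
        assert got == pytest.approx(want, abs=0.02)

    def test_positions_sorted_unique_within_bounds(self):
        cfg = selsig.SimulationConfig(snps_per_chromosome=500,
                                      chromosome_length=1000, seed=2)
        panel = selsig.simulate_panel(cfg)
        pos = panel.markers.pos
        assert (np.diff(pos) > 0).all()
        assert pos[0] >= 1 and pos[-1] <= 1000

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            selsig.SimulationConfig(bn_F=(1.0, 0.1))
        with pytest.raises(ValueError):
            selsig.SimulationConfig(ancestral_maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            selsig.SimulationConfig(snps_per_chromosome=1)


class TestPlantSweep:
    def _panel(self, seed=0):
        cfg = selsig.SimulationConfig(n_individuals_per_pop=(20, 20),
                                      snps_per_chromosome=200,
                                      chromosome_length=2_000_000, seed=seed)
        return selsig.simulate_panel(cfg)

    def test_full_carrier_fraction_homogenises_span(self):
        panel = self._panel()
        spec = selsig.SweepSpec("SWB", "chr1", 1_000_000, 1.0, 400_000)
        swept = selsig.plant_sweep(panel, spec, _substream(0, 9))
        rows = swept.haplotype_rows("SWB")
        pos = swept.markers.pos
        span = (pos >= 800_000) & (pos <= 1_200_000)
        block = swept.alleles[np.ix_(rows, np.flatnonzero(span))]
        assert (block == block[0]).all()
        # site EHH = 1 across the span interior
        core = int(np.flatnonzero(span)[span.sum() // 2])
        curve = selsig.site_ehh(swept, "SWB", core, "right")
        inside = curve.distances <= 150_000
        assert (curve.ehh[inside] == 1.0).all()

    def test_untouched_outside_span_and_other_population(self):
        panel = self._panel(3)
        spec = selsig.SweepSpec("SWB", "chr1", 1_000_000, 0.8, 400_000)
        swept = selsig.plant_sweep(panel, spec, _substream(3, 9))
        pos = swept.markers.pos
        outside = ~((pos >= 800_000) & (pos <= 1_200_000))
        np.testing.assert_array_equal(swept.alleles[:, outside],
                                      panel.alleles[:, outside])
        exm = panel.haplotype_rows("EXM")
        np.testing.assert_array_equal(swept.alleles[exm], panel.alleles[exm])

    def test_sweep_in_population_b_gives_negative_raw_scores(self):
        cfg = selsig.SimulationConfig(
            n_individuals_per_pop=(50, 50), snps_per_chromosome=1000,
            chromosome_length=10_000_000, bn_F=(0.1, 0.1), seed=5,
            sweep_specs=(selsig.SweepSpec("EXM", "chr1", 5_000_000, 0.9,
                                          400_000),))
        study = selsig.simulate_study(cfg)
        recs = selsig.xpehh(study.panel, "SWB", "EXM")
        core = recs.iloc[(recs["position"] - 5_000_000).abs().argmin()]
        assert core["raw"] < 0

    def test_too_small_carrier_fraction_rejected(self):
        panel = self._panel()
        spec = selsig.SweepSpec("SWB", "chr1", 1_000_000, 0.01, 400_000)
        with pytest.raises(ValueError, match="no haplotype"):
            selsig.plant_sweep(panel, spec, _substream(0, 9))


class TestPlantRoh:
    def test_planted_long_run_recovered_exactly(self):
        # 150 SNPs at regular 4-kb spacing (596 kb) on an otherwise fully
        # heterozygous individual: exactly one long-class segment, with
        # boundaries within one inter-SNP interval of the plant
        from _oracles import roh_runs_oracle
        from conftest import make_panel
        m = 250
        pos = 4000 * np.arange(1, m + 1)
        alleles = np.zeros((8, m), dtype=np.uint8)
        alleles[1::2] = 1                    # every individual all-het
        panel = make_panel(alleles, pos=pos, populations=["SWB"] * 4)
        lo, hi = int(pos[40]), int(pos[189])
        planted = selsig.plant_roh(panel, selsig.RohPlant("SWB", 2, "chr1",
                                                          lo, hi))
        geno = selsig.collapse_to_genotypes(planted)
        segs = [s for s in selsig.detect_roh(geno, selsig.LONG)
                if s.individual == "i2"]
        assert len(segs) == 1
        seg = segs[0]
        assert abs(seg.start_bp - lo) <= 4000
        assert abs(seg.end_bp - hi) <= 4000
        want = roh_runs_oracle(geno.dosages[2], pos, selsig.LONG)
        assert [(int(pos[a]), int(pos[b])) for a, b in want] \
            == [(seg.start_bp, seg.end_bp)]

    def test_genotypes_become_homozygous_only_inside_interval(self):
        cfg = selsig.SimulationConfig(n_individuals_per_pop=(5, 5),
                                      snps_per_chromosome=100, seed=4)
        panel = selsig.simulate_panel(cfg)
        pos = panel.markers.pos
        plant = selsig.RohPlant("EXM", 1, "chr1", int(pos[20]), int(pos[60]))
        planted = selsig.plant_roh(panel, plant)
        i = planted.individual_indices("EXM")[1]
        geno = selsig.collapse_to_genotypes(planted)
        assert not (geno.dosages[i, 20:61] == 1).any()
        touched = planted.alleles != panel.alleles
        assert not touched[:2 * i + 1].any() and not touched[2 * i + 2:].any()
        assert not touched[2 * i + 1, :20].any()
        assert not touched[2 * i + 1, 61:].any()

    def test_two_snp_plant_yields_no_roh_in_any_class(self):
        cfg = selsig.SimulationConfig(n_individuals_per_pop=(4, 4),
                                      snps_per_chromosome=60,
                                      chromosome_length=240_000, seed=6)
        panel = selsig.simulate_panel(cfg)
        pos = panel.markers.pos
        plant = selsig.RohPlant("SWB", 0, "chr1", int(pos[30]), int(pos[31]))
        geno = selsig.collapse_to_genotypes(selsig.plant_roh(panel, plant))
        for params in selsig.DEFAULT_CLASSES.values():
            for s in selsig.detect_roh(geno, params):
                # any detected run must predate the plant, not come from it
                assert not (s.individual == "SWB_0000"
                            and s.start_bp >= pos[28] and s.end_bp <= pos[33])

    def test_out_of_range_individual_rejected(self):
        cfg = selsig.SimulationConfig(n_individuals_per_pop=(3, 3),
                                      snps_per_chromosome=50, seed=0)
        panel = selsig.simulate_panel(cfg)
        with pytest.raises(IndexError):
            selsig.plant_roh(panel, selsig.RohPlant("SWB", 5, "chr1", 1, 9999))


class TestStudy:
    def test_empty_plants_leave_panel_unchanged(self):
        cfg = selsig.SimulationConfig(n_individuals_per_pop=(6, 6),
                                      snps_per_chromosome=80, seed=9)
        study = selsig.simulate_study(cfg)
        np.testing.assert_array_equal(study.panel.alleles,
                                      selsig.simulate_panel(cfg).alleles)
        assert len(study.truth) == 0

    def test_missingness_never_inside_planted_intervals(self):
        cfg = selsig.SimulationConfig(
            n_individuals_per_pop=(10, 10), snps_per_chromosome=300,
            chromosome_length=3_000_000, missing_rate=0.3, seed=12,
            sweep_specs=(selsig.SweepSpec("SWB", "chr1", 1_500_000, 0.8,
                                          500_000),),
            roh_plants=(selsig.RohPlant("EXM", 0, "chr1", 100_000, 400_000),))
        study = selsig.simulate_study(cfg)
        pos = study.genotypes.markers.pos
        protected = (((pos >= 1_250_000) & (pos <= 1_750_000))
                     | ((pos >= 100_000) & (pos <= 400_000)))
        assert not (study.genotypes.dosages[:, protected] == MISSING).any()
        assert (study.genotypes.dosages == MISSING).any()

    def test_config_file_round_trip(self, tmp_path):
        f = tmp_path / "sim.cfg"
        f.write_text(
            "n_individuals_per_pop = 12, 8\n"
            "snps_per_chromosome = 150\n"
            "chromosome_length = 1500000\n"
            "bn_F = 0.05, 0.2\n"
            "seed = 33\n"
            "sweep = SWB, chr1, 750000, 0.8, 200000\n"
            "roh = EXM, 1, chr1, 10000, 60000\n")
        from selsig.simulate import read_config
        cfg = read_config(f)
        assert cfg.n_individuals_per_pop == (12, 8)
        assert cfg.bn_F == (0.05, 0.2)
        assert cfg.sweep_specs[0].carrier_fraction == 0.8
        assert cfg.roh_plants[0].start_bp == 10000
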