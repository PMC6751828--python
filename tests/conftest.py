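import numpy as np
import pandas as pd
import pytest

import selsig
from selsig.io import MISSING, GenotypeMatrix, HaplotypePanel, MarkerMap


def make_map(pos, chrom="chr1"):
    if np.ndim(chrom) == 0:
        chrom = [chrom] * len(pos)
    return MarkerMap(pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "snp_id": [f"s{i}" for i in range(len(pos))],
        "ref": "A", "alt": "G"}))


def make_geno(dosages, pos=None, populations=None, chrom="chr1"):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    pops = np.asarray(populations if populations is not None else ["P"] * n,
                      dtype=object)
    return GenotypeMatrix(dosages, [f"i{k}" for k in range(n)], pops,
                          make_map(pos, chrom))


def make_panel(alleles, pos=None, populations=None, chrom="chr1"):
    alleles = np.asarray(alleles, dtype=np.uint8)
    n2, m = alleles.shape
    n = n2 // 2
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    pops = np.asarray(populations if populations is not None else ["P"] * n,
                      dtype=object)
    return HaplotypePanel(alleles, [f"i{k}" for k in range(n)], pops,
                          make_map(pos, chrom))


def random_roh_geno(rng, n_ind=None, m=None):
    """Random single-chromosome genotype matrix exercising the ROH rules:
    variable het/missing rates plus planted homozygous stretches."""
    n_ind = n_ind or int(rng.integers(2, 13))
    m = m or int(rng.integers(60, 201))
    spacing = rng.choice([300, 500, 2000, 4000])
    pos = np.cumsum(rng.integers(1, 2 * spacing, size=m)) + 1
    p_het = rng.uniform(0.02, 0.6)
    p_mis = rng.choice([0.0, 0.02, 0.08])
    u = rng.random((n_ind, m))
    dos = np.where(u < p_het, 1, np.where(rng.random((n_ind, m)) < 0.5, 0, 2))
    dos[rng.random((n_ind, m)) < p_mis] = MISSING
    # plant homozygous runs in a few individuals
    for _ in range(int(rng.integers(0, 6))):
        i = int(rng.integers(n_ind))
        a = int(rng.integers(0, m - 10))
        b = min(m, a + int(rng.integers(10, 200)))
        dos[i, a:b] = rng.choice([0, 2])
    return make_geno(dos, pos=pos)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One end-to-end pipeline study, run twice for determinism checks.

    The study plants a strong founder sweep (94% carrier haplotypes) so
    that the same truth region must surface in the ROH-consensus branch
    and in both differentiation tests.
    """
    sim = selsig.SimulationConfig(
        n_individuals_per_pop=(40, 40), n_chromosomes=5,
        snps_per_chromosome=2000, chromosome_length=1_000_000,
        bn_F=(0.1, 0.1), missing_rate=0.02, seed=7,
        sweep_specs=(selsig.SweepSpec("SWB", "chr2", 500_000, 0.94, 600_000),))
    config = selsig.PipelineConfig(sim=sim)
    out1 = tmp_path_factory.mktemp("pipe1")
    out2 = tmp_path_factory.mktemp("pipe2")
    results = selsig.run_pipeline(config, out1)
    selsig.run_pipeline(config, out2)
    return {"config": config, "out1": out1, "out2": out2, "results": results}
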