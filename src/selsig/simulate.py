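"""Two-population synthetic genotype panels with plantable truth.

The neutral backbone is the Balding-Nichols model: per SNP an ancestral
frequency p is drawn uniformly from a configurable range (randomly
polarised so neither allele is systematically minor) and each
population's frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), where the
drift parameter F equals the population's expected divergence from the
ancestral pool.  Haplotype alleles are then independent Bernoulli draws,
so sites are exchangeable: haplotype structure is supplied explicitly by
the two planting operators, not by a recombination process.

``plant_sweep`` copies one founder haplotype over a chosen fraction of a
population's haplotypes across a window - the footprint of a hard sweep,
giving the extended haplotype homozygosity that XP-EHH detects.
``plant_roh`` overwrites one individual's second haplotype with its
first across an interval, creating an autozygous segment for ROH
detection.  Missingness is i.i.d. per genotype, applied after planting
and never inside planted intervals, so the planted truth stays exact.

All randomness flows from one master seed through named spawned
substreams, so identical configs give identical panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (MISSING, GenotypeMatrix, HaplotypePanel, MarkerMap,
                 collapse_to_genotypes, write_phased_vcf,
                 write_population_file)


@dataclass(frozen=True)
class SweepSpec:
    """A planted hard sweep: founder haplotype shared by ``carrier_fraction``
    of ``population``'s haplotypes over ``span_bp`` centred on ``core_bp``."""

    population: str
    chromosome: str
    core_bp: int
    carrier_fraction: float
    span_bp: int

    def __post_init__(self):
        if not 0 < self.carrier_fraction <= 1:
            raise ValueError("carrier_fraction must be in (0,1]")
        if self.core_bp < 1:
            raise ValueError("core_bp must be >= 1")
        if self.span_bp <= 0:
            raise ValueError("span_bp must be positive")


@dataclass(frozen=True)
class RohPlant:
    """A planted autozygous segment for one individual (index within its
    population) spanning [start_bp, end_bp] on ``chromosome``."""

    population: str
    individual_index: int
    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self):
        if self.start_bp >= self.end_bp:
            raise ValueError("start_bp must be < end_bp")
        if self.individual_index < 0:
            raise ValueError("individual_index must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    n_individuals_per_pop: tuple[int, int] = (100, 100)
    pop_labels: tuple[str, str] = ("SWB", "EXM")
    n_chromosomes: int = 1
    snps_per_chromosome: int = 1000
    chromosome_length: int = 10_000_000
    bn_F: tuple[float, float] = (0.1, 0.1)
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    sweep_specs: tuple[SweepSpec, ...] = ()
    roh_plants: tuple[RohPlant, ...] = ()
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.chromosome_length <= 0:
            raise ValueError("chromosome_length must be positive")
        if self.snps_per_chromosome < 2:
            raise ValueError("snps_per_chromosome must be >= 2")
        lo, hi = self.ancestral_maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("ancestral_maf_range must satisfy 0 < lo <= hi <= 0.5")
        for f in self.bn_F:
            if not 0 <= f < 1:
                raise ValueError("bn_F must be in [0,1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0,1)")
        if self.snps_per_chromosome > self.chromosome_length:
            raise ValueError("more SNPs requested than distinct positions")


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _draw_positions(rng: np.random.Generator, m: int, length: int) -> np.ndarray:
    """Uniform distinct 1-based positions; redraws collisions, budget 100*m."""
    pos = np.unique(rng.integers(1, length + 1, size=m))
    budget = 100 * m
    while pos.size < m and budget > 0:
        extra = rng.integers(1, length + 1, size=m - pos.size)
        budget -= extra.size
        pos = np.unique(np.concatenate([pos, extra]))
    if pos.size < m:
        raise RuntimeError("could not draw distinct SNP positions within budget")
    return pos


def simulate_panel(config: SimulationConfig, return_frequencies: bool = False):
    """Neutral Balding-Nichols panel (sweeps/plants NOT applied here).

    Deterministic in ``config.seed``; per-chromosome substreams keep the
    panel stable under changes to unrelated configuration.  With
    ``return_frequencies`` also returns the latent (2, M) per-population
    frequency matrix the haplotypes were drawn from, for use as an
    independent frequency-based oracle.
    """
    n_a, n_b = config.n_individuals_per_pop
    hap_counts = (2 * n_a, 2 * n_b)
    maps, blocks, freq_blocks = [], [], []
    for c in range(config.n_chromosomes):
        rng = _substream(config.seed, 0, c)
        m = config.snps_per_chromosome
        pos = _draw_positions(rng, m, config.chromosome_length)
        p_anc = rng.uniform(*config.ancestral_maf_range, size=m)
        flip = rng.random(m) < 0.5
        p_anc = np.where(flip, 1.0 - p_anc, p_anc)
        chrom_alleles, chrom_freqs = [], []
        for f, n_hap in zip(config.bn_F, hap_counts):
            if f == 0:
                p_pop = p_anc
            else:
                a = p_anc * (1 - f) / f
                b = (1 - p_anc) * (1 - f) / f
                p_pop = rng.beta(a, b)
            draws = rng.random((n_hap, m))
            chrom_alleles.append((draws < p_pop).astype(np.uint8))
            chrom_freqs.append(p_pop)
        blocks.append(np.vstack(chrom_alleles))
        freq_blocks.append(np.vstack(chrom_freqs))
        maps.append(pd.DataFrame({
            "chrom": f"chr{c + 1}",
            "pos": pos,
            "snp_id": [f"chr{c + 1}_snp{j}" for j in range(m)],
            "ref": "A",
            "alt": "G",
        }))
    alleles = np.hstack(blocks)
    sample_ids = ([f"{config.pop_labels[0]}_{i:04d}" for i in range(n_a)]
                  + [f"{config.pop_labels[1]}_{i:04d}" for i in range(n_b)])
    populations = np.array([config.pop_labels[0]] * n_a
                           + [config.pop_labels[1]] * n_b, dtype=object)
    panel = HaplotypePanel(alleles, sample_ids, populations,
                           MarkerMap(pd.concat(maps, ignore_index=True)))
    if return_frequencies:
        return panel, np.hstack(freq_blocks)
    return panel


def _span_columns(markers: MarkerMap, chrom: str, lo: int, hi: int) -> np.ndarray:
    sl = markers.chrom_slice(chrom)
    pos = markers.pos[sl]
    j = np.flatnonzero((pos >= lo) & (pos <= hi))
    return j + sl.start


def plant_sweep(panel: HaplotypePanel, spec: SweepSpec,
                rng: np.random.Generator) -> HaplotypePanel:
    """Overwrite a carrier share of one population with a founder haplotype.

    The founder is copied from one randomly chosen haplotype of the
    population; carriers are drawn without replacement.  Only the
    interval [core_bp - span_bp/2, core_bp + span_bp/2] on the spec's
    chromosome is touched.
    """
    panel = panel.copy()
    rows = panel.haplotype_rows(spec.population)
    n_carriers = int(round(spec.carrier_fraction * rows.size))
    if n_carriers < 1:
        raise ValueError("carrier_fraction leaves no haplotype to modify")
    cols = _span_columns(panel.markers, spec.chromosome,
                         spec.core_bp - spec.span_bp // 2,
                         spec.core_bp + spec.span_bp // 2)
    if cols.size == 0:
        raise ValueError("sweep span contains no SNPs")
    founder = rows[rng.integers(rows.size)]
    carriers = rng.choice(rows, size=n_carriers, replace=False)
    panel.alleles[np.ix_(carriers, cols)] = panel.alleles[founder, cols]
    return panel


def plant_roh(panel: HaplotypePanel, plant: RohPlant) -> HaplotypePanel:
    """Copy haplotype 1 over haplotype 2 for one individual across an interval."""
    panel = panel.copy()
    ind = panel.individual_indices(plant.population)
    if plant.individual_index >= ind.size:
        raise IndexError(f"individual_index {plant.individual_index} out of range "
                         f"for population {plant.population}")
    i = ind[plant.individual_index]
    cols = _span_columns(panel.markers, plant.chromosome,
                         plant.start_bp, plant.end_bp)
    if cols.size == 0:
        raise ValueError("ROH plant interval overlaps no SNPs")
    panel.alleles[2 * i + 1, cols] = panel.alleles[2 * i, cols]
    return panel


def _protected_mask(markers: MarkerMap, config: SimulationConfig) -> np.ndarray:
    """Boolean per-SNP mask of columns inside any planted interval."""
    mask = np.zeros(markers.n_snps, dtype=bool)
    for s in config.sweep_specs:
        mask[_span_columns(markers, s.chromosome,
                           s.core_bp - s.span_bp // 2,
                           s.core_bp + s.span_bp // 2)] = True
    for p in config.roh_plants:
        mask[_span_columns(markers, p.chromosome, p.start_bp, p.end_bp)] = True
    return mask


@dataclass
class StudyData:
    """One simulated study: phased truth, genotypes with missingness, and
    a ground-truth table of every planted interval."""

    panel: HaplotypePanel
    genotypes: GenotypeMatrix
    truth: pd.DataFrame
    config: SimulationConfig = field(repr=False)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_phased_vcf(self.panel, outdir / "panel.vcf",
                         {c: self.config.chromosome_length
                          for c in self.panel.markers.chromosomes})
        write_population_file(outdir / "populations.tsv",
                              self.panel.sample_ids, self.panel.populations)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def simulate_study(config: SimulationConfig) -> StudyData:
    """Full generator: neutral panel + planted sweeps/ROH + missingness."""
    panel = simulate_panel(config)
    truth_rows = []
    for k, spec in enumerate(config.sweep_specs):
        panel = plant_sweep(panel, spec, _substream(config.seed, 1, k))
        truth_rows.append(("sweep", spec.population, "", spec.chromosome,
                           spec.core_bp - spec.span_bp // 2,
                           spec.core_bp + spec.span_bp // 2,
                           spec.core_bp, spec.carrier_fraction))
    for plant in config.roh_plants:
        panel = plant_roh(panel, plant)
        truth_rows.append(("roh", plant.population,
                           f"{plant.population}_{plant.individual_index:04d}",
                           plant.chromosome, plant.start_bp, plant.end_bp,
                           "", ""))
    geno = collapse_to_genotypes(panel)
    if config.missing_rate > 0:
        rng = _substream(config.seed, 2)
        hit = rng.random(geno.dosages.shape) < config.missing_rate
        hit[:, _protected_mask(panel.markers, config)] = False
        geno.dosages[hit] = MISSING
    truth = pd.DataFrame(truth_rows, columns=[
        "kind", "population", "individual", "chrom", "start_bp", "end_bp",
        "core_bp", "carrier_fraction"])
    return StudyData(panel, geno, truth, config)


# ---------------------------------------------------------------------------
# flat key=value config files
# ---------------------------------------------------------------------------

_SCALARS = {
    "n_chromosomes": int, "snps_per_chromosome": int, "chromosome_length": int,
    "missing_rate": float, "seed": int,
}


def apply_config_key(cfg: SimulationConfig, key: str, val: str
                     ) -> SimulationConfig:
    """Apply one flat ``key = value`` assignment; KeyError on unknown key."""
    parts = [v.strip() for v in val.split(",")]
    if key in _SCALARS:
        return replace(cfg, **{key: _SCALARS[key](val)})
    if key == "n_individuals_per_pop":
        return replace(cfg, n_individuals_per_pop=(int(parts[0]), int(parts[1])))
    if key == "pop_labels":
        return replace(cfg, pop_labels=(parts[0], parts[1]))
    if key == "bn_F":
        return replace(cfg, bn_F=(float(parts[0]), float(parts[1])))
    if key == "ancestral_maf_range":
        return replace(cfg, ancestral_maf_range=(float(parts[0]), float(parts[1])))
    if key == "sweep":
        spec = SweepSpec(parts[0], parts[1], int(parts[2]),
                         float(parts[3]), int(parts[4]))
        return replace(cfg, sweep_specs=cfg.sweep_specs + (spec,))
    if key == "roh":
        plant = RohPlant(parts[0], int(parts[1]), parts[2],
                         int(parts[3]), int(parts[4]))
        return replace(cfg, roh_plants=cfg.roh_plants + (plant,))
    raise KeyError(key)


def read_config(path) -> SimulationConfig:
    """Parse a flat ``key = value`` file mirroring SimulationConfig.

    Pairs use comma syntax (``bn_F = 0.1,0.1``); sweeps/plants use one
    line per plant: ``sweep = POP,chrom,core_bp,carrier_fraction,span_bp``
    and ``roh = POP,index,chrom,start_bp,end_bp``.
    """
    cfg = SimulationConfig()
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected key = value")
        key, val = (s.strip() for s in line.split("=", 1))
        try:
            cfg = apply_config_key(cfg, key, val)
        except KeyError:
            raise ValueError(f"{path}:{ln}: unknown key {key!r}") from None
    return cfg
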