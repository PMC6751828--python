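"""Genotype/haplotype data model and file I/O.

The central containers are :class:`MarkerMap` (per-SNP chromosome, bp
position and alleles), :class:`HaplotypePanel` (phased binary allele
matrix, two rows per diploid individual) and :class:`GenotypeMatrix`
(alt-allele dosages 0/1/2 with -1 for missing).  Positions are 1-based
inclusive bp throughout (VCF convention); BED output converts to
0-based half-open at the writing boundary.

Supported formats: phased VCF 4.2 (read via cyvcf2, written as plain
text), PLINK text PED/MAP, a two-column population file (sample_id,
population) and TSV reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype call in a GenotypeMatrix
MISSING = -1


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerMap:
    """Per-SNP genomic coordinates and allele labels.

    Wraps a DataFrame with columns ``chrom, pos, snp_id, ref, alt``.
    Chromosomes must be grouped contiguously and positions strictly
    increasing within each chromosome.
    """

    table: pd.DataFrame

    REQUIRED = ("chrom", "pos", "snp_id", "ref", "alt")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"marker map lacks columns {missing}")
        t = self.table.reset_index(drop=True)
        t["chrom"] = t["chrom"].astype(str)
        t["pos"] = t["pos"].astype(np.int64)
        object.__setattr__(self, "table", t)
        seen: set[str] = set()
        prev = None
        for chrom in t["chrom"]:
            if chrom != prev:
                if chrom in seen:
                    raise ValueError(f"chromosome {chrom} not contiguous in map")
                seen.add(chrom)
                prev = chrom
        for chrom, sub in t.groupby("chrom", sort=False):
            d = np.diff(sub["pos"].to_numpy())
            if (d <= 0).any():
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    @property
    def snp_id(self) -> np.ndarray:
        return self.table["snp_id"].to_numpy()

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in map order."""
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous column slice holding ``chrom``'s SNPs."""
        idx = np.flatnonzero(self.chrom == str(chrom))
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom} not in map")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def iter_chromosomes(self):
        for chrom in self.chromosomes:
            yield chrom, self.chrom_slice(chrom)

    def subset(self, indices: np.ndarray) -> "MarkerMap":
        indices = np.asarray(indices)
        return MarkerMap(self.table.iloc[indices].reset_index(drop=True))


def _check_samples(n: int, sample_ids: Sequence[str], populations: Sequence[str]):
    if len(sample_ids) != n or len(populations) != n:
        raise ValueError("sample_ids/populations length mismatch")
    if len(set(sample_ids)) != n:
        raise ValueError("duplicate sample ids")


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes: rows ``2i`` and ``2i+1`` belong to individual ``i``.

    Phased input is a contract: no missing values are representable.
    """

    alleles: np.ndarray           # (2N, M) uint8 in {0,1}
    sample_ids: list[str]
    populations: np.ndarray       # (N,) population label per individual
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] % 2:
            raise ValueError("allele matrix must be (2N, M)")
        if self.alleles.shape[1] != self.markers.n_snps:
            raise ValueError("allele matrix / marker map size mismatch")
        if self.alleles.max(initial=0) > 1:
            raise ValueError("haplotype alleles must be 0/1")
        self.populations = np.asarray(self.populations, dtype=object)
        _check_samples(self.n_individuals, self.sample_ids, self.populations)

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0] // 2

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def individual_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(self.populations == population)
        if idx.size == 0:
            raise KeyError(f"population {population!r} not in panel")
        return idx

    def haplotype_rows(self, population: str) -> np.ndarray:
        """Row indices of all haplotypes belonging to ``population``."""
        ind = self.individual_indices(population)
        return np.sort(np.concatenate([2 * ind, 2 * ind + 1]))

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(self.alleles.copy(), list(self.sample_ids),
                              self.populations.copy(), self.markers)


@dataclass
class GenotypeMatrix:
    """Diploid alt-allele dosages, ``MISSING`` (-1) marking no-calls."""

    dosages: np.ndarray           # (N, M) int8 in {0,1,2,MISSING}
    sample_ids: list[str]
    populations: np.ndarray
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.dosages = np.ascontiguousarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-D")
        if self.dosages.shape[1] != self.markers.n_snps:
            raise ValueError("dosage matrix / marker map size mismatch")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2,-1}")
        self.populations = np.asarray(self.populations, dtype=object)
        _check_samples(self.n_individuals, self.sample_ids, self.populations)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def individual_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(self.populations == population)
        if idx.size == 0:
            raise KeyError(f"population {population!r} not in matrix")
        return idx

    def allele_frequencies(self, population: str | None = None) -> np.ndarray:
        """Sample alt-allele frequency per SNP (NaN where all calls missing)."""
        rows = (self.dosages if population is None
                else self.dosages[self.individual_indices(population)])
        called = rows != MISSING
        n_alleles = 2 * called.sum(axis=0)
        alt = np.where(called, rows, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / n_alleles, np.nan)

    def subset_snps(self, indices: np.ndarray) -> "GenotypeMatrix":
        indices = np.asarray(indices)
        return GenotypeMatrix(self.dosages[:, indices], list(self.sample_ids),
                              self.populations.copy(), self.markers.subset(indices))

    def subset_individuals(self, indices: np.ndarray) -> "GenotypeMatrix":
        indices = np.asarray(indices)
        return GenotypeMatrix(self.dosages[indices],
                              [self.sample_ids[i] for i in indices],
                              self.populations[indices], self.markers)


def collapse_to_genotypes(panel: HaplotypePanel) -> GenotypeMatrix:
    """Sum the two haplotypes of each individual into dosages (no missing)."""
    dos = (panel.alleles[0::2].astype(np.int8) + panel.alleles[1::2].astype(np.int8))
    return GenotypeMatrix(dos, list(panel.sample_ids), panel.populations.copy(),
                          panel.markers)


# ---------------------------------------------------------------------------
# population file
# ---------------------------------------------------------------------------

def read_population_file(path) -> dict[str, str]:
    """Two-column TSV ``sample_id<TAB>population`` -> mapping."""
    out: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
        if parts[0] in out:
            raise ValueError(f"{path}:{ln}: duplicate sample {parts[0]}")
        out[parts[0]] = parts[1]
    return out


def write_population_file(path, sample_ids: Sequence[str], populations: Sequence[str]):
    with open(path, "w") as fh:
        for s, p in zip(sample_ids, populations):
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(vcf_path, pop_path) -> HaplotypePanel:
    """Read a phased, biallelic-SNP VCF into a :class:`HaplotypePanel`.

    Any unphased ("/") or half-missing GT aborts with the offending record
    and sample named; multiallelic or non-SNP records are skipped and
    counted.  ``pop_path`` maps every sample to its population.
    """
    from cyvcf2 import VCF

    pops = read_population_file(pop_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in pops]
    if absent:
        raise ValueError(f"samples missing from population file: {absent[:5]}")

    rows, recs = [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = v.genotypes
        if gts is None:
            raise ValueError(f"{v.CHROM}:{v.POS}: no GT field")
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for i, gt in enumerate(gts):
            a, b, phased = gt[0], gt[1], gt[-1]
            if a < 0 or b < 0:
                raise ValueError(
                    f"{v.CHROM}:{v.POS}: missing allele for sample {samples[i]}")
            if not phased:
                raise ValueError(
                    f"{v.CHROM}:{v.POS}: unphased genotype for sample {samples[i]}")
            col[2 * i], col[2 * i + 1] = a, b
        rows.append(col)
        recs.append((v.CHROM, v.POS, v.ID or f"{v.CHROM}_{v.POS}", v.REF, v.ALT[0]))
    if n_skipped:
        logger.info("skipped %d multiallelic/non-SNP records", n_skipped)
    if not recs:
        raise ValueError("no biallelic SNP records in VCF")
    mmap = MarkerMap(pd.DataFrame(recs, columns=["chrom", "pos", "snp_id", "ref", "alt"]))
    alleles = np.stack(rows, axis=1)
    populations = np.array([pops[s] for s in samples], dtype=object)
    return HaplotypePanel(alleles, samples, populations, mmap)


def write_phased_vcf(panel: HaplotypePanel, path,
                     contig_lengths: dict[str, int] | None = None) -> None:
    """Write a panel as a minimal phased VCF 4.2 text file."""
    m = panel.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in m.chromosomes:
            sl = m.chrom_slice(chrom)
            length = (contig_lengths or {}).get(chrom, int(m.pos[sl.stop - 1]))
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        a = panel.alleles
        for j in range(m.n_snps):
            gts = "\t".join(f"{a[2 * i, j]}|{a[2 * i + 1, j]}"
                            for i in range(panel.n_individuals))
            row = m.table.iloc[j]
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# PLINK text PED/MAP
# ---------------------------------------------------------------------------

def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read white-space delimited PLINK PED/MAP into dosages.

    The MAP's declared alleles define the dosage orientation: the first
    allele listed per SNP (column 5, when present) is REF, the second ALT;
    dosage counts ALT alleles.  ``0 0`` encodes a missing genotype.
    """
    map_rows = []
    for ln, line in enumerate(Path(map_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        p = line.split()
        if len(p) not in (4, 6):
            raise ValueError(f"{map_path}:{ln}: expected 4 or 6 columns")
        ref, alt = (p[4], p[5]) if len(p) == 6 else ("A", "B")
        map_rows.append((p[0], int(p[3]), p[1], ref, alt))
    mmap = MarkerMap(pd.DataFrame(map_rows, columns=["chrom", "pos", "snp_id",
                                                     "ref", "alt"]))
    m = mmap.n_snps
    ref = mmap.table["ref"].to_numpy()
    alt = mmap.table["alt"].to_numpy()

    sample_ids, populations, rows = [], [], []
    for ln, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        p = line.split()
        if len(p) != 6 + 2 * m:
            raise ValueError(f"{ped_path}:{ln}: expected {6 + 2 * m} columns, "
                             f"got {len(p)}")
        populations.append(p[0])
        sample_ids.append(p[1])
        dos = np.empty(m, dtype=np.int8)
        for j in range(m):
            a1, a2 = p[6 + 2 * j], p[7 + 2 * j]
            if a1 == "0" or a2 == "0":
                if a1 != a2:
                    raise ValueError(f"{ped_path}:{ln}: half-missing genotype "
                                     f"at SNP {mmap.snp_id[j]}")
                dos[j] = MISSING
                continue
            d = 0
            for a in (a1, a2):
                if a == alt[j]:
                    d += 1
                elif a != ref[j]:
                    raise ValueError(f"{ped_path}:{ln}: allele {a!r} not among "
                                     f"declared alleles of SNP {mmap.snp_id[j]}")
            dos[j] = d
        rows.append(dos)
    if not rows:
        raise ValueError(f"{ped_path}: no individuals")
    return GenotypeMatrix(np.stack(rows), sample_ids,
                          np.array(populations, dtype=object), mmap)


def write_ped_map(geno: GenotypeMatrix, ped_path, map_path) -> None:
    t = geno.markers.table
    with open(map_path, "w") as fh:
        for row in t.itertuples():
            fh.write(f"{row.chrom}\t{row.snp_id}\t0\t{row.pos}\t{row.ref}\t{row.alt}\n")
    ref = t["ref"].to_numpy()
    alt = t["alt"].to_numpy()
    with open(ped_path, "w") as fh:
        for i in range(geno.n_individuals):
            lead = [str(geno.populations[i]), geno.sample_ids[i], "0", "0", "0", "-9"]
            pairs = []
            for j, d in enumerate(geno.dosages[i]):
                if d == MISSING:
                    pairs.append("0 0")
                elif d == 0:
                    pairs.append(f"{ref[j]} {ref[j]}")
                elif d == 1:
                    pairs.append(f"{ref[j]} {alt[j]}")
                else:
                    pairs.append(f"{alt[j]} {alt[j]}")
            fh.write(" ".join(lead) + " " + " ".join(pairs) + "\n")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QcThresholds:
    """Marker/individual quality-control cutoffs.

    Defaults follow common SNP-array practice for breed-level scans:
    MAF < 0.01, per-SNP missingness > 0.10, per-individual missingness
    > 0.10, HWE exact p < 1e-4, and exclusion of individuals whose
    heterozygosity-based inbreeding coefficient exceeds 0.05.
    """

    maf_min: float = 0.01
    snp_missing_max: float = 0.10
    ind_missing_max: float = 0.10
    hwe_p_min: float = 1e-4
    f_i_max: float = 0.05

    def __post_init__(self):
        for name in ("maf_min", "snp_missing_max", "ind_missing_max", "hwe_p_min"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0,1]")


@dataclass
class QcReport:
    """Per-step removal bookkeeping for :func:`apply_qc`.

    The filter order is fixed (individual missingness, SNP missingness,
    MAF, HWE); every removed individual/SNP is named with the step that
    removed it, so order sensitivity is visible, never silent.
    """

    removed_individuals: list[tuple[str, str]] = field(default_factory=list)
    removed_snps: list[tuple[str, str]] = field(default_factory=list)

    STEPS = ("ind_missing", "snp_missing", "maf", "hwe")

    def counts(self) -> dict[str, int]:
        c = {s: 0 for s in self.STEPS}
        for _, step in self.removed_individuals:
            c[step] += 1
        for _, step in self.removed_snps:
            c[step] += 1
        return c

    def to_frame(self) -> pd.DataFrame:
        rows = ([(s, "individual", step) for s, step in self.removed_individuals]
                + [(s, "snp", step) for s, step in self.removed_snps])
        return pd.DataFrame(rows, columns=["id", "kind", "step"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def apply_qc(geno: GenotypeMatrix, thr: QcThresholds | None = None
             ) -> tuple[GenotypeMatrix, QcReport]:
    """Filter a genotype matrix in the fixed order MIND, GENO, MAF, HWE.

    Per-SNP statistics (missingness, MAF, the HWE exact test) are
    evaluated within each population separately; a SNP failing in any
    population is removed, leaving one marker set shared by all
    populations.  Raises if any step empties the matrix.
    """
    from .diversity import hwe_exact_test

    thr = thr or QcThresholds()
    report = QcReport()

    # step 1: individual missingness
    miss_frac = (geno.dosages == MISSING).mean(axis=1)
    keep_ind = miss_frac <= thr.ind_missing_max
    for i in np.flatnonzero(~keep_ind):
        report.removed_individuals.append((geno.sample_ids[i], "ind_missing"))
    if not keep_ind.any():
        raise ValueError("QC step ind_missing removed every individual")
    geno = geno.subset_individuals(np.flatnonzero(keep_ind))

    pops = list(dict.fromkeys(geno.populations))
    pop_rows = {p: geno.individual_indices(p) for p in pops}

    # step 2: per-SNP missingness within each population
    keep_snp = np.ones(geno.n_snps, dtype=bool)
    for p in pops:
        sub = geno.dosages[pop_rows[p]]
        keep_snp &= (sub == MISSING).mean(axis=0) <= thr.snp_missing_max
    _drop_snps(geno, keep_snp, "snp_missing", report)
    geno = geno.subset_snps(np.flatnonzero(keep_snp))

    # step 3: MAF within each population
    keep_snp = np.ones(geno.n_snps, dtype=bool)
    for p in pops:
        f = geno.allele_frequencies(p)
        maf = np.minimum(f, 1 - f)
        keep_snp &= ~(np.nan_to_num(maf, nan=0.0) < thr.maf_min)
    _drop_snps(geno, keep_snp, "maf", report)
    geno = geno.subset_snps(np.flatnonzero(keep_snp))

    # step 4: HWE exact test within each population
    keep_snp = np.ones(geno.n_snps, dtype=bool)
    for p in pops:
        sub = geno.dosages[pop_rows[p]]
        for j in range(geno.n_snps):
            col = sub[:, j]
            col = col[col != MISSING]
            if col.size == 0:
                continue
            n_aa = int((col == 0).sum())
            n_ab = int((col == 1).sum())
            n_bb = int((col == 2).sum())
            if hwe_exact_test(n_aa, n_ab, n_bb) < thr.hwe_p_min:
                keep_snp[j] = False
    _drop_snps(geno, keep_snp, "hwe", report)
    geno = geno.subset_snps(np.flatnonzero(keep_snp))
    return geno, report


def _drop_snps(geno: GenotypeMatrix, keep: np.ndarray, step: str, report: QcReport):
    for j in np.flatnonzero(~keep):
        report.removed_snps.append((geno.markers.snp_id[j], step))
    if not keep.any():
        raise ValueError(f"QC step {step} removed every SNP")
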