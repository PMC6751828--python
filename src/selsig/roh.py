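"""Sliding-window runs-of-homozygosity detection and population consensus.

ROH are called per individual and chromosome with the scanning-window
procedure of PLINK's ``--homozyg`` family: every contiguous window of
``window_snps`` SNPs qualifies iff it contains at most
``window_het_max`` heterozygous and ``window_missing_max`` missing
calls; a SNP is ROH-eligible iff at least ``window_hit_threshold`` of
the windows containing it qualify; maximal runs of eligible SNPs are
trimmed so both ends sit on homozygous non-missing calls, split at any
inter-SNP gap above ``max_gap_bp``, and finally kept iff they carry at
least ``min_snps`` SNPs, span a length inside the class's kb bounds
(half-open: 125 kb is medium, 500 kb is long) and average at most
``density_kb_per_snp`` kb per SNP.  Segment length is
(end_bp - start_bp)/1000 kb.

Three length classes are scanned as independent passes:

    class    min SNPs  density      max gap  length (kb)  window  het  miss
    short       3      1 SNP/100kb  5000 kb   50 - 125       5     0    0
    medium     10      1 SNP/100kb  5000 kb  125 - 500      12     0    0
    long       30      1 SNP/100kb  5000 kb  > 500          50     1    1

The maximum-gap ceiling follows the kb denomination of the scanning
tool's gap option (5000 kb); at SNP-array density a literal 5-kb
ceiling would split candidate runs at nearly every inter-SNP gap and no
ROH could ever be called.

The long class tolerates one heterozygous and one missing call per
window; the het/missing allowance acts at window level only, while
segment endpoints are always forced to homozygous non-missing SNPs.

Consensus regions are maximal runs of consecutive SNPs whose long-ROH
incidence (fraction of individuals with a covering long segment)
reaches the consensus threshold, default 0.85.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class RohClassParams:
    name: str
    min_snps: int
    density_kb_per_snp: float      # segment may average at most this many kb/SNP
    max_gap_bp: int
    min_length_kb: float
    max_length_kb: float           # math.inf for the open-ended long class
    window_snps: int
    window_het_max: int
    window_missing_max: int
    window_hit_threshold: float = 0.05

    def __post_init__(self):
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")
        if self.max_gap_bp <= 0:
            raise ValueError("max_gap_bp must be positive")
        if self.min_length_kb >= self.max_length_kb:
            raise ValueError("min_length_kb must be below max_length_kb")


_MAX_GAP = 5_000_000          # 5000 kb
SHORT = RohClassParams("short", 3, 100.0, _MAX_GAP, 50.0, 125.0, 5, 0, 0)
MEDIUM = RohClassParams("medium", 10, 100.0, _MAX_GAP, 125.0, 500.0, 12, 0, 0)
LONG = RohClassParams("long", 30, 100.0, _MAX_GAP, 500.0, math.inf, 50, 1, 1)
DEFAULT_CLASSES = {"short": SHORT, "medium": MEDIUM, "long": LONG}


@dataclass(frozen=True)
class ROHSegment:
    individual: str
    population: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    length_kb: float
    label: str


def _eligible_snps(g: np.ndarray, params: RohClassParams) -> np.ndarray:
    """Window-qualification vote: True where a SNP is ROH-eligible."""
    m = g.size
    w = params.window_snps
    het = np.concatenate([[0], np.cumsum(g == 1)])
    mis = np.concatenate([[0], np.cumsum(g == MISSING)])
    win_het = het[w:] - het[:-w]
    win_mis = mis[w:] - mis[:-w]
    qualify = (win_het <= params.window_het_max) & (win_mis <= params.window_missing_max)
    cq = np.concatenate([[0], np.cumsum(qualify)])
    j = np.arange(m)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, m - w)
    hits = cq[hi + 1] - cq[lo]
    return hits / (hi - lo + 1) >= params.window_hit_threshold


def _runs(mask: np.ndarray):
    """(start, end) inclusive index pairs of maximal True runs."""
    if not mask.any():
        return
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [mask.size - 1]])
    yield from zip(starts, ends)


def detect_roh(geno: GenotypeMatrix, params: RohClassParams) -> list[ROHSegment]:
    """Scan every individual and chromosome for one ROH length class."""
    segments: list[ROHSegment] = []
    hom = (geno.dosages == 0) | (geno.dosages == 2)
    for chrom, sl in geno.markers.iter_chromosomes():
        pos = geno.markers.pos[sl]
        if pos.size < params.window_snps:
            warnings.warn(f"chromosome {chrom}: fewer SNPs than the "
                          f"{params.name}-class window; no calls made")
            continue
        gap_break = np.diff(pos) > params.max_gap_bp
        for i in range(geno.n_individuals):
            g = geno.dosages[i, sl]
            eligible = _eligible_snps(g, params)
            h = hom[i, sl]
            for s0, e0 in _runs(eligible):
                # trim endpoints to homozygous non-missing calls
                inside = np.flatnonzero(h[s0:e0 + 1])
                if inside.size == 0:
                    continue
                s, e = s0 + inside[0], s0 + inside[-1]
                # split at oversized gaps
                cut = s + np.flatnonzero(gap_break[s:e])
                bounds = np.concatenate([[s - 1], cut, [e]])
                for a, b in zip(bounds[:-1] + 1, bounds[1:]):
                    seg = _qualify_segment(int(a), int(b), pos, params)
                    if seg is not None:
                        segments.append(ROHSegment(
                            geno.sample_ids[i], str(geno.populations[i]),
                            chrom, *seg, params.name))
    return segments


def _qualify_segment(s: int, e: int, pos: np.ndarray, params: RohClassParams):
    n = e - s + 1
    if n < params.min_snps:
        return None
    length_kb = (pos[e] - pos[s]) / 1000.0
    if not params.min_length_kb <= length_kb < params.max_length_kb:
        return None
    if length_kb / n > params.density_kb_per_snp:
        return None
    return int(pos[s]), int(pos[e]), n, float(length_kb)


def scan_all_classes(geno: GenotypeMatrix,
                     classes: dict[str, RohClassParams] = DEFAULT_CLASSES
                     ) -> list[ROHSegment]:
    out: list[ROHSegment] = []
    for params in classes.values():
        out.extend(detect_roh(geno, params))
    return out


def segments_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.individual, s.population, s.chromosome, s.start_bp, s.end_bp,
          s.n_snps, s.length_kb, s.label) for s in segments],
        columns=["individual", "population", "chrom", "start_bp", "end_bp",
                 "n_snps", "length_kb", "class"])


def roh_summary(segments: list[ROHSegment],
                n_individuals: dict[str, int]) -> pd.DataFrame:
    """Population x class descriptive table.

    ``total_n`` counts segments, ``mean_n`` = total/n individuals,
    ``mean_length_kb`` averages segment lengths and ``coverage_mb``
    is the summed segment length per individual in Mb.
    """
    df = segments_frame(segments)
    rows = []
    for pop, n in n_individuals.items():
        for cls in ("short", "medium", "long"):
            sub = df[(df["population"] == pop) & (df["class"] == cls)]
            total = len(sub)
            rows.append((pop, cls, total, total / n,
                         float(sub["length_kb"].mean()) if total else 0.0,
                         float(sub["length_kb"].sum()) / n / 1000.0))
    return pd.DataFrame(rows, columns=["population", "class", "total_n",
                                       "mean_n", "mean_length_kb",
                                       "coverage_mb_per_ind"])


def snp_coverage(segments: list[ROHSegment], geno: GenotypeMatrix,
                 label: str = "long") -> np.ndarray:
    """Boolean (N, M): individual i has a ``label``-class segment covering SNP j."""
    cov = np.zeros((geno.n_individuals, geno.n_snps), dtype=bool)
    row_of = {s: i for i, s in enumerate(geno.sample_ids)}
    for seg in segments:
        if seg.label != label:
            continue
        sl = geno.markers.chrom_slice(seg.chromosome)
        pos = geno.markers.pos[sl]
        a = int(np.searchsorted(pos, seg.start_bp, side="left"))
        b = int(np.searchsorted(pos, seg.end_bp, side="right"))
        cov[row_of[seg.individual], sl.start + a:sl.start + b] = True
    return cov


def snp_incidence(segments: list[ROHSegment], geno: GenotypeMatrix,
                  label: str = "long") -> np.ndarray:
    """Per-SNP share of individuals carrying a covering ``label``-class ROH."""
    return snp_coverage(segments, geno, label).mean(axis=0)


@dataclass(frozen=True)
class ConsensusRegion:
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    share: float      # fraction of individuals whose ROH cover EVERY SNP


def consensus_regions(coverage: np.ndarray, geno: GenotypeMatrix,
                      threshold: float = 0.85) -> list[ConsensusRegion]:
    """Maximal runs of SNPs with ROH incidence >= ``threshold``.

    ``coverage`` is the (N, M) boolean matrix from :func:`snp_coverage`.
    The reported ``share`` is the stricter exact-overlap fraction: the
    proportion of individuals whose segments cover every SNP of the
    region.  A single-SNP run yields a region with start == end.
    """
    share = coverage.mean(axis=0)
    out = []
    for chrom, sl in geno.markers.iter_chromosomes():
        pos = geno.markers.pos[sl]
        for s, e in _runs(share[sl] >= threshold):
            exact = coverage[:, sl.start + s:sl.start + e + 1].all(axis=1).mean()
            out.append(ConsensusRegion(chrom, int(pos[s]), int(pos[e]),
                                       int(e - s + 1), float(exact)))
    return out


def consensus_frame(regions: list[ConsensusRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.chromosome, r.start_bp, r.end_bp, r.n_snps, r.share)
         for r in regions],
        columns=["chrom", "start_bp", "end_bp", "n_snps", "share"])
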