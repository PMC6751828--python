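"""Independent brute-force oracles used to cross-check the package.

Each oracle is a deliberately naive, loop-level transcription of the
statistic's definition, sharing no code with the implementation it
checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd

from selsig.io import MISSING
from selsig.roh import RohClassParams


# ---------------------------------------------------------------------------
# ROH: direct enumeration of the sliding-window criteria
# ---------------------------------------------------------------------------

def roh_runs_oracle(g, pos, params: RohClassParams) -> list[tuple[int, int]]:
    """All (start, end) SNP-index runs satisfying the class criteria."""
    g = list(g)
    pos = list(pos)
    m = len(g)
    w = params.window_snps
    if m < w:
        return []
    qual = []
    for s in range(m - w + 1):
        win = g[s:s + w]
        het = sum(1 for x in win if x == 1)
        mis = sum(1 for x in win if x == MISSING)
        qual.append(het <= params.window_het_max
                    and mis <= params.window_missing_max)
    elig = []
    for j in range(m):
        lo = max(0, j - w + 1)
        hi = min(j, m - w)
        hits = sum(qual[lo:hi + 1])
        elig.append(hits / (hi - lo + 1) >= params.window_hit_threshold)

    out = []
    j = 0
    while j < m:
        if not elig[j]:
            j += 1
            continue
        k = j
        while k + 1 < m and elig[k + 1]:
            k += 1
        s, e = j, k
        while s <= e and g[s] not in (0, 2):
            s += 1
        while e >= s and g[e] not in (0, 2):
            e -= 1
        if s <= e:
            bounds = [s]
            for t in range(s, e):
                if pos[t + 1] - pos[t] > params.max_gap_bp:
                    bounds.extend([t, t + 1])
            bounds.append(e)
            for a, b in zip(bounds[::2], bounds[1::2]):
                n = b - a + 1
                length_kb = (pos[b] - pos[a]) / 1000.0
                if (n >= params.min_snps
                        and params.min_length_kb <= length_kb < params.max_length_kb
                        and length_kb / n <= params.density_kb_per_snp):
                    out.append((a, b))
        j = k + 1
    return out


# ---------------------------------------------------------------------------
# HWE: exact-fraction enumeration over heterozygote counts
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> Fraction:
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if min(n_a, n_b) == 0:
        return Fraction(1)

    def prob(h: int) -> Fraction:
        a = (n_a - h) // 2
        b = (n_b - h) // 2
        return Fraction(
            factorial(n) * 2 ** h * factorial(n_a) * factorial(n_b),
            factorial(a) * factorial(h) * factorial(b) * factorial(2 * n))

    table = {h: prob(h) for h in range(min(n_a, n_b) % 2, min(n_a, n_b) + 1, 2)}
    p_obs = table[n_ab]
    return sum(p for p in table.values() if p <= p_obs)


# ---------------------------------------------------------------------------
# EHH / iES: O(n^2) pairwise-identity scan
# ---------------------------------------------------------------------------

def ehh_pairs_oracle(h: np.ndarray, pos, core: int, step: int,
                     cutoff: float) -> tuple[list, list]:
    """One-sided EHH by direct pair counting; mirrors the stop rule
    (first below-cutoff value kept, then stop)."""
    n = h.shape[0]
    dists, ehhs = [0], [1.0]
    cols = [core]
    j = core + step
    while 0 <= j < h.shape[1]:
        cols.append(j)
        same = 0
        for a in range(n):
            for b in range(a + 1, n):
                if all(h[a, c] == h[b, c] for c in cols):
                    same += 1
        e = 2 * same / (n * (n - 1))
        dists.append(abs(int(pos[j]) - int(pos[core])))
        ehhs.append(e)
        if e < cutoff:
            break
        j += step
    return dists, ehhs


def ies_pairs_oracle(panel, population: str, core: int,
                     cutoff: float = 0.05) -> float:
    m = panel.markers
    sl = m.chrom_slice(m.chrom[core])
    rows = panel.haplotype_rows(population)
    h = panel.alleles[rows, sl.start:sl.stop]
    pos = m.pos[sl]
    total = 0.0
    for step in (-1, 1):
        dists, ehhs = ehh_pairs_oracle(h, pos, core - sl.start, step, cutoff)
        k = len(ehhs)
        for i, e in enumerate(ehhs):
            if e < cutoff:
                k = i
                break
        if k >= 2:
            total += float(np.trapezoid(ehhs[:k], dists[:k]))
    return total


# ---------------------------------------------------------------------------
# windows and intervals
# ---------------------------------------------------------------------------

def window_means_oracle(values, chrom, pos, width: int) -> dict:
    """Naive per-window recomputation: {(chrom, k): mean of defined values}."""
    acc: dict = {}
    for v, c, p in zip(values, chrom, pos):
        if np.isnan(v):
            continue
        key = (c, (p - 1) // width)
        acc.setdefault(key, []).append(v)
    return {k: sum(vs) / len(vs) for k, vs in acc.items()}


def overlap_oracle(regions: pd.DataFrame, annotation: pd.DataFrame) -> list[set]:
    """All-pairs >=1 bp overlap on 1-based inclusive intervals."""
    out = []
    for r in regions.itertuples():
        hits = set()
        for a in annotation.itertuples():
            if a.chrom == r.chrom and a.start_bp <= r.end_bp and a.end_bp >= r.start_bp:
                hits.add(a.name)
        out.append(hits)
    return out


def incidence_stab_oracle(segments, geno, label: str) -> np.ndarray:
    """Per-SNP incidence by naive per-individual interval stabbing."""
    share = np.zeros(geno.n_snps)
    for j in range(geno.n_snps):
        chrom = geno.markers.chrom[j]
        p = geno.markers.pos[j]
        covered = set()
        for s in segments:
            if (s.label == label and s.chromosome == chrom
                    and s.start_bp <= p <= s.end_bp):
                covered.add(s.individual)
        share[j] = len(covered) / geno.n_individuals
    return share
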