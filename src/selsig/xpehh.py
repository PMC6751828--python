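"""Cross-population extended haplotype homozygosity (XP-EHH) scan.

Site EHH at a core SNP and outward SNP set S is the probability that
two haplotypes drawn without replacement are identical over {core} u S:

    EHH = sum_h n_h (n_h - 1) / (n (n - 1))

computed over ALL haplotypes at the site (the site-EHH/iES formulation
on which XP-EHH is defined), SNP by SNP outward, with EHH = 1 at
distance zero.  iES integrates the two-sided EHH curve over physical bp
by the trapezoid rule, for as long as EHH stays at or above
``ehh_cutoff`` (default 0.05); curves hitting a chromosome end keep
their partial integral and are flagged truncated.

For each eligible core (pooled MAF >= ``maf_min``, default 0.05) the raw
score is ln(iES_A / iES_B); positive values mean longer haplotypes -
more recent positive selection - in population A.  Raw scores are
standardised genome-wide to mean 0 / sd 1, given two-sided normal
p-values and Benjamini-Hochberg q-values.  Candidate windows are 500-kb
tiles holding at least ``min_snps`` (default 3) extreme SNPs, where
extreme means |standardised score| in the upper 1% of the empirical
distribution or beyond the fixed +-4.34 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fst import WINDOW_BP, tile_windows
from .io import HaplotypePanel

XPEHH_THRESHOLD = 4.34


class DegenerateScanError(ValueError):
    """Raised when raw XP-EHH scores have zero variance (identical panels)."""


@dataclass
class EhhCurve:
    core_snp: str
    direction: str                 # "left" or "right"
    distances: np.ndarray          # bp offsets, increasing from 0
    ehh: np.ndarray                # values in [0,1], ehh[0] == 1
    truncated_at_end: bool


def _hap_block(panel: HaplotypePanel, population: str, chrom_slice: slice
               ) -> np.ndarray:
    rows = panel.haplotype_rows(population)
    return np.asfortranarray(panel.alleles[rows, chrom_slice.start:chrom_slice.stop])


def _ehh_outward(h: np.ndarray, pos: np.ndarray, core: int, step: int,
                 ehh_cutoff: float) -> tuple[list[int], list[float], bool]:
    """March outward from ``core`` refining haplotype groups.

    Returns (distances, ehh values, truncated_at_end).  Stops after the
    first value below ``ehh_cutoff`` (which is kept so the curve shows
    the crossing) or at the chromosome end.
    """
    n = h.shape[0]
    denom = n * (n - 1)
    codes = h[:, core].astype(np.int64)
    dists, ehhs = [0], [1.0]
    j = core + step
    while 0 <= j < h.shape[1]:
        codes = np.unique(codes * 2 + h[:, j], return_inverse=True)[1]
        counts = np.bincount(codes)
        e = float((counts * (counts - 1)).sum() / denom)
        dists.append(int(abs(pos[j] - pos[core])))
        ehhs.append(e)
        if e < ehh_cutoff:
            return dists, ehhs, False
        j += step
    return dists, ehhs, True


def site_ehh(panel: HaplotypePanel, population: str, core_snp: int,
             direction: str, ehh_cutoff: float = 0.05) -> EhhCurve:
    """One-sided EHH decay curve for the haplotypes of one population.

    ``core_snp`` is a global SNP index; the curve never crosses a
    chromosome boundary.
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    m = panel.markers
    chrom = m.chrom[core_snp]
    sl = m.chrom_slice(chrom)
    h = _hap_block(panel, population, sl)
    if h.shape[0] < 2:
        raise ValueError("need at least 2 haplotypes")
    pos = m.pos[sl]
    step = 1 if direction == "right" else -1
    d, e, trunc = _ehh_outward(h, pos, core_snp - sl.start, step, ehh_cutoff)
    return EhhCurve(str(m.snp_id[core_snp]), direction,
                    np.asarray(d), np.asarray(e), trunc)


def _integrate(dists: list[int], ehhs: list[float], cutoff: float) -> float:
    """Trapezoid integral over the prefix of the curve with EHH >= cutoff."""
    k = len(ehhs)
    for i, e in enumerate(ehhs):
        if e < cutoff:
            k = i
            break
    if k < 2:
        return 0.0
    return float(np.trapezoid(np.asarray(ehhs[:k]), np.asarray(dists[:k])))


def ies(panel: HaplotypePanel, population: str, core_snp: int,
        ehh_cutoff: float = 0.05) -> float:
    """Two-sided integrated site EHH (bp units) at one core SNP."""
    m = panel.markers
    sl = m.chrom_slice(m.chrom[core_snp])
    if sl.stop - sl.start < 2:
        raise ValueError("degenerate EHH curve: single-SNP chromosome")
    h = _hap_block(panel, population, sl)
    if h.shape[0] < 2:
        raise ValueError("need at least 2 haplotypes")
    pos = m.pos[sl]
    total = 0.0
    for step in (-1, 1):
        d, e, _ = _ehh_outward(h, pos, core_snp - sl.start, step, ehh_cutoff)
        total += _integrate(d, e, ehh_cutoff)
    return total


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    from statsmodels.stats.multitest import multipletests
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def xpehh(panel: HaplotypePanel, pop_a: str, pop_b: str,
          ehh_cutoff: float = 0.05, maf_min: float = 0.05) -> pd.DataFrame:
    """Genome-wide XP-EHH records between two populations.

    Columns: snp_id, chrom, position, ies_a, ies_b, raw, standardized,
    p_value, q_value.  Cores below the pooled MAF floor or with a zero
    iES on either side are skipped (counted in ``df.attrs['n_skipped']``).
    Raises :class:`DegenerateScanError` when every raw score is equal.
    """
    m = panel.markers
    freq = panel.alleles.mean(axis=0)
    eligible = np.minimum(freq, 1 - freq) >= maf_min

    rows = []
    n_skipped = int((~eligible).sum())
    for chrom, sl in m.iter_chromosomes():
        if sl.stop - sl.start < 2:
            n_skipped += sl.stop - sl.start
            continue
        pos = m.pos[sl]
        ha = _hap_block(panel, pop_a, sl)
        hb = _hap_block(panel, pop_b, sl)
        for local in np.flatnonzero(eligible[sl]):
            ies_a = sum(_integrate(*_ehh_outward(ha, pos, local, s, ehh_cutoff)[:2],
                                   ehh_cutoff) for s in (-1, 1))
            ies_b = sum(_integrate(*_ehh_outward(hb, pos, local, s, ehh_cutoff)[:2],
                                   ehh_cutoff) for s in (-1, 1))
            if ies_a <= 0 or ies_b <= 0:
                n_skipped += 1
                continue
            rows.append((str(m.snp_id[sl.start + local]), chrom, int(pos[local]),
                         ies_a, ies_b, float(np.log(ies_a / ies_b))))
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "position",
                                     "ies_a", "ies_b", "raw"])
    df.attrs["n_skipped"] = n_skipped
    if len(df) == 0:
        raise ValueError("no eligible core SNPs")
    sd = df["raw"].std(ddof=0)
    if sd == 0:
        raise DegenerateScanError("raw XP-EHH scores have zero variance "
                                  "(identical haplotype panels?)")
    df["standardized"] = (df["raw"] - df["raw"].mean()) / sd
    df["p_value"] = 2.0 * stats.norm.sf(np.abs(df["standardized"]))
    df["q_value"] = fdr_adjust(df["p_value"].to_numpy())
    return df


def significant_windows(records: pd.DataFrame, width_bp: int = WINDOW_BP,
                        min_snps: int = 3, percentile: float = 0.99,
                        threshold: float = XPEHH_THRESHOLD) -> pd.DataFrame:
    """500-kb windows holding >= ``min_snps`` extreme SNPs.

    A SNP is extreme if |standardised| reaches the upper (1-percentile)
    tail of the empirical |score| distribution (``extreme_tail``) or
    exceeds the fixed threshold (``extreme_threshold``); the window mean
    is taken over its extreme SNPs (signed scores).
    """
    if len(records) == 0:
        return pd.DataFrame(columns=["chrom", "start_bp", "end_bp",
                                     "n_significant_snps", "mean_xpehh"])
    ab = records["standardized"].abs().to_numpy()
    tail_cut = float(np.quantile(ab, percentile, method="higher"))
    rec = records.copy()
    rec["extreme_tail"] = ab >= tail_cut
    rec["extreme_threshold"] = ab > threshold
    rec["extreme"] = rec["extreme_tail"] | rec["extreme_threshold"]
    rec["window"] = tile_windows(rec["position"].to_numpy(), width_bp)
    rows = []
    for (chrom, w), sub in rec.groupby(["chrom", "window"], sort=True):
        ext = sub[sub["extreme"]]
        if len(ext) < min_snps:
            continue
        rows.append((chrom, int(w) * width_bp + 1, (int(w) + 1) * width_bp,
                     len(ext), float(ext["standardized"].mean()),
                     float(sub["standardized"].mean())))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp",
                                       "n_significant_snps", "mean_xpehh",
                                       "mean_xpehh_all_snps"])


def bifurcation(panel: HaplotypePanel, population: str, core_snp: int,
                direction: str, max_snps: int) -> dict:
    """Haplotype bifurcation tree outward from a core SNP.

    Nested dict: ``{"count": n, "snp": id|None, "children": {allele:
    subtree}}``; depth 1 splits on the core allele, each further level on
    the next SNP outward.  Truncates silently at the chromosome end.
    Node counts at every depth sum to the number of haplotypes.
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    m = panel.markers
    sl = m.chrom_slice(m.chrom[core_snp])
    h = _hap_block(panel, population, sl)
    step = 1 if direction == "right" else -1
    local = core_snp - sl.start
    snps = [local]
    for _ in range(max_snps):
        nxt = snps[-1] + step
        if not 0 <= nxt < h.shape[1]:
            break
        snps.append(nxt)

    def build(rows: np.ndarray, depth: int) -> dict:
        node = {"count": int(rows.size),
                "snp": str(m.snp_id[sl.start + snps[depth - 1]]) if depth else None,
                "children": {}}
        if depth < len(snps) and rows.size:
            alleles = h[rows, snps[depth]]
            for a in (0, 1):
                sub = rows[alleles == a]
                if sub.size:
                    node["children"][str(a)] = build(sub, depth + 1)
        return node

    return build(np.arange(h.shape[0]), 0)
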