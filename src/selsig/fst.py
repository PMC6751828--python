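"""Windowed Nei fixation-index genome scan between two populations.

Per SNP, with p1 and p2 the sample alt-allele frequencies of the two
populations and p_bar their unweighted mean,

    H_T = 2 p_bar (1 - p_bar)
    H_S = (2 p1 (1 - p1) + 2 p2 (1 - p2)) / 2
    F_ST = (H_T - H_S) / H_T        (undefined where H_T = 0)

i.e. Nei's G_ST for two demes with no sample-size correction, so
estimates lie in [0, 1] wherever defined.  Values are averaged over
non-overlapping 500-kb windows anchored at bp 1 of each chromosome, and
windows in the highest ``top_fraction`` (default 1%) of the empirical
distribution of window means are flagged as candidate regions; ties at
the cutoff are included.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

WINDOW_BP = 500_000


def per_snp_fst(geno: GenotypeMatrix, pops: tuple[str, str],
                weighted: bool = False) -> np.ndarray:
    """Per-SNP Nei F_ST; NaN where undefined (H_T = 0 or a population
    entirely missing).

    ``weighted=True`` weights the total-population frequency by sample
    size instead of the default unweighted two-deme mean.
    """
    p1 = geno.allele_frequencies(pops[0])
    p2 = geno.allele_frequencies(pops[1])
    if weighted:
        n1 = 2 * (geno.dosages[geno.individual_indices(pops[0])] != -1).sum(axis=0)
        n2 = 2 * (geno.dosages[geno.individual_indices(pops[1])] != -1).sum(axis=0)
        with np.errstate(invalid="ignore"):
            pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    else:
        pbar = (p1 + p2) / 2.0
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = (2.0 * p1 * (1.0 - p1) + 2.0 * p2 * (1.0 - p2)) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = (ht - hs) / ht
    fst[~(ht > 0)] = np.nan          # also catches NaN frequencies
    return fst


def mean_weighted_fst(geno: GenotypeMatrix, pops: tuple[str, str]) -> float:
    """Ratio-of-sums genome average: sum(H_T - H_S) / sum(H_T) over SNPs
    where H_T > 0.  This is the standard multi-locus G_ST summary."""
    p1 = geno.allele_frequencies(pops[0])
    p2 = geno.allele_frequencies(pops[1])
    pbar = (p1 + p2) / 2.0
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = p1 * (1.0 - p1) + p2 * (1.0 - p2)
    ok = ht > 0
    if not ok.any():
        raise ValueError("no SNP with defined F_ST")
    return float((ht[ok] - hs[ok]).sum() / ht[ok].sum())


def tile_windows(pos: np.ndarray, width_bp: int = WINDOW_BP) -> np.ndarray:
    """0-based window index of each 1-based position for tiling
    [k*width+1, (k+1)*width]."""
    return (pos - 1) // width_bp


def window_average(values: np.ndarray, geno: GenotypeMatrix,
                   width_bp: int = WINDOW_BP) -> pd.DataFrame:
    """Average a per-SNP statistic over non-overlapping windows.

    Windows with no defined (non-NaN) SNP value are dropped, so they
    never enter the empirical distribution.  Columns: chrom, start_bp,
    end_bp, n_snps, mean.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (geno.n_snps,):
        raise ValueError("per-SNP values / map size mismatch")
    rows = []
    for chrom, sl in geno.markers.iter_chromosomes():
        pos = geno.markers.pos[sl]
        v = values[sl]
        ok = ~np.isnan(v)
        if not ok.any():
            continue
        win = tile_windows(pos[ok], width_bp)
        df = pd.DataFrame({"w": win, "v": v[ok]})
        g = df.groupby("w")["v"].agg(["size", "mean"])
        for w, row in g.iterrows():
            rows.append((chrom, int(w) * width_bp + 1, (int(w) + 1) * width_bp,
                         int(row["size"]), float(row["mean"])))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp",
                                       "n_snps", "mean"])


def empirical_cutoff(windows: pd.DataFrame, top_fraction: float = 0.01
                     ) -> tuple[float, pd.DataFrame]:
    """Flag windows in the top tail of the empirical window-mean
    distribution.

    The cutoff is the (1 - top_fraction) order-statistic quantile
    (method "higher"); a window is significant iff mean >= cutoff, so
    cutoff ties are included.  With all means equal every window is
    flagged (degenerate-tie behaviour, documented).
    """
    if len(windows) == 0:
        raise ValueError("no windows with a defined mean")
    means = windows["mean"].to_numpy()
    cutoff = float(np.quantile(means, 1.0 - top_fraction, method="higher"))
    out = windows.copy()
    out["significant"] = out["mean"] >= cutoff
    return cutoff, out


def fst_windows(geno: GenotypeMatrix, pops: tuple[str, str],
                width_bp: int = WINDOW_BP, top_fraction: float = 0.01
                ) -> tuple[float, pd.DataFrame]:
    """Per-SNP Nei F_ST -> 500-kb window means -> top-1% flags."""
    fst = per_snp_fst(geno, pops)
    windows = window_average(fst, geno, width_bp)
    windows = windows.rename(columns={"mean": "mean_fst"})
    cutoff, flagged = empirical_cutoff(windows.rename(columns={"mean_fst": "mean"}),
                                       top_fraction)
    flagged = flagged.rename(columns={"mean": "mean_fst"})
    return cutoff, flagged
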