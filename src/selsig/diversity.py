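"""Within-population diversity statistics.

Covers the heterozygosity-based method-of-moments inbreeding coefficient
f_i, the two-sided Hardy-Weinberg exact test, composite (dosage-based)
LD r-squared, and greedy windowed LD pruning.

f_i for individual i is

    f_i = (O_i - E_i) / (n_i - E_i)

where O_i is the observed homozygous-call count over i's non-missing
SNPs, n_i that SNP count, and E_i = sum_j [1 - 2 p_j (1 - p_j) n_j/(n_j - 1)]
the expected homozygote count under Hardy-Weinberg at the sample allele
frequencies p_j, with the small-sample correction n_j/(n_j - 1) on the
heterozygosity term (n_j = number of called alleles at SNP j).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class InbreedingResult:
    sample_id: str
    observed_hom: int
    expected_hom: float
    n_nonmissing: int
    f_i: float


def inbreeding_coefficients(geno: GenotypeMatrix) -> list[InbreedingResult]:
    """Per-individual excess-homozygosity inbreeding coefficients.

    Allele frequencies are the sample frequencies of the matrix passed
    in, so call this per population when populations differ.  Raises if
    the panel carries no polymorphic SNP (every denominator zero).
    """
    dos = geno.dosages
    called = dos != MISSING
    n_alleles = 2 * called.sum(axis=0).astype(float)          # n_j
    freq = geno.allele_frequencies()                           # p_j
    # per-SNP expected homozygosity with n/(n-1) correction; SNPs with a
    # single called allele carry no information and are excluded
    informative = n_alleles >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        exp_hom_j = 1.0 - 2.0 * freq * (1.0 - freq) * n_alleles / (n_alleles - 1.0)
    exp_hom_j = np.where(informative, exp_hom_j, 0.0)

    use = called & informative
    obs = ((dos == 0) | (dos == 2)) & use
    n_i = use.sum(axis=1)
    o_i = obs.sum(axis=1)
    e_i = use @ exp_hom_j

    out = []
    any_poly = False
    for i in range(geno.n_individuals):
        denom = n_i[i] - e_i[i]
        if denom <= 0:
            f = math.nan
        else:
            f = (o_i[i] - e_i[i]) / denom
            any_poly = True
        out.append(InbreedingResult(geno.sample_ids[i], int(o_i[i]),
                                    float(e_i[i]), int(n_i[i]), float(f)))
    if not any_poly:
        raise ValueError("no polymorphic SNPs: f_i undefined for every individual")
    return out


def flag_inbred(results: list[InbreedingResult], f_i_max: float = 0.05) -> list[str]:
    """Sample ids whose f_i exceeds the exclusion bound."""
    return [r.sample_id for r in results if r.f_i > f_i_max]


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Conditional on the observed allele counts, the number of
    heterozygotes follows the hypergeometric-type HWE null

        P(h) = n! / (a! h! b!) * 2^h * nA! nB! / (2n)!

    with a = (nA - h)/2 homozygotes for the rarer allele and b the rest.
    The p-value sums P over all heterozygote counts whose probability
    does not exceed that of the observed count (no mid-p adjustment).
    """
    for v in (n_aa, n_ab, n_bb):
        if v < 0:
            raise ValueError("negative genotype count")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("empty genotype sample")
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0

    hets = np.arange(rare % 2, rare + 1, 2)
    lg = math.lgamma
    logp = np.array([
        lg(n + 1) - lg((n_a - h) // 2 + 1) - lg(h + 1) - lg((n_b - h) // 2 + 1)
        + h * math.log(2.0) + lg(n_a + 1) + lg(n_b + 1) - lg(2 * n + 1)
        for h in hets
    ])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.flatnonzero(hets == n_ab)[0]]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def ld_r2(geno: GenotypeMatrix, snp_a: int, snp_b: int) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete calls.

    Returns NaN (distinct from 0) when fewer than two complete pairs
    remain or either SNP has zero variance among them.
    """
    x = geno.dosages[:, snp_a].astype(float)
    y = geno.dosages[:, snp_b].astype(float)
    ok = (geno.dosages[:, snp_a] != MISSING) & (geno.dosages[:, snp_b] != MISSING)
    x, y = x[ok], y[ok]
    if x.size < 2:
        return math.nan
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return math.nan
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def _pairwise_r2_block(block: np.ndarray) -> np.ndarray:
    """r^2 matrix for a (N, W) dosage block, pairwise-complete over missing."""
    miss = block == MISSING
    x = np.where(miss, 0.0, block.astype(float))
    c = (~miss).astype(float)
    n = c.T @ c
    sx = x.T @ c                    # sum of x_i over pairs complete with j
    sxx = (x * x).T @ c
    sxy = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = sx / n
        mean_y = mean_x.T
        cov = sxy / n - mean_x * mean_y
        var_x = sxx / n - mean_x ** 2
        var_y = var_x.T
        r2 = cov * cov / (var_x * var_y)
    r2[(n < 2) | (var_x <= 0) | (var_y <= 0)] = np.nan
    return r2


@dataclass(frozen=True)
class LdPruneParams:
    window_snps: int = 50
    step_snps: int = 5
    r2_max: float = 0.5

    def __post_init__(self):
        if self.step_snps > self.window_snps:
            raise ValueError("step_snps must not exceed window_snps")
        if not 0 < self.r2_max <= 1:
            raise ValueError("r2_max must be in (0,1]")


def ld_prune(geno: GenotypeMatrix, params: LdPruneParams | None = None
             ) -> np.ndarray:
    """Greedy windowed LD pruning; returns kept SNP indices.

    Per chromosome, windows of ``window_snps`` SNPs advance by
    ``step_snps``; within a window every surviving pair with
    r^2 > ``r2_max`` loses its lower-MAF member (tie: the later map
    position goes).  A SNP removed in one window stays removed.
    """
    params = params or LdPruneParams()
    freq = geno.allele_frequencies()
    maf = np.minimum(freq, 1 - freq)
    maf = np.nan_to_num(maf, nan=0.0)
    removed = np.zeros(geno.n_snps, dtype=bool)

    for _, sl in geno.markers.iter_chromosomes():
        idx = np.arange(sl.start, sl.stop)
        mc = idx.size
        w = min(params.window_snps, mc)
        starts = list(range(0, mc - w + 1, params.step_snps))
        if starts[-1] != mc - w:
            starts.append(mc - w)
        for s in starts:
            win = idx[s:s + w]
            alive = win[~removed[win]]
            if alive.size < 2:
                continue
            r2 = _pairwise_r2_block(geno.dosages[:, alive])
            local_dead = np.zeros(alive.size, dtype=bool)
            for a in range(alive.size):
                if local_dead[a]:
                    continue
                for b in range(a + 1, alive.size):
                    if local_dead[a]:
                        break
                    if local_dead[b]:
                        continue
                    v = r2[a, b]
                    if np.isnan(v) or v <= params.r2_max:
                        continue
                    ia, ib = alive[a], alive[b]
                    # drop the lower-MAF member; tie -> later map position
                    if maf[ia] < maf[ib]:
                        local_dead[a] = True
                    else:
                        local_dead[b] = True
            removed[alive[local_dead]] = True
    return np.flatnonzero(~removed)
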