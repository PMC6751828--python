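# Methods

`selsig` implements a two-population selection-signature scan of the kind
used to compare an intensively performance-selected horse breed against a
conservation breed: within-population runs of homozygosity (ROH) with
population consensus regions, and two between-population differentiation
tests — windowed Nei F_ST and XP-EHH — whose intersection nominates
candidate regions. A synthetic genotype generator supplies fully
controlled study data, since SNP-array datasets of this kind are typically
access-restricted.

## Data model

Phased haplotypes are a `2N x M` binary matrix (rows `2i`, `2i+1` belong to
individual `i`); genotypes are alt-allele dosages `{0,1,2}` with `-1` for
missing. Coordinates are 1-based inclusive bp everywhere in memory (VCF
convention); BED/bedGraph output converts to 0-based half-open at the
writing boundary. Phased input is a contract: the VCF reader rejects any
unphased or half-missing genotype, naming record and sample, and skips
(with a count) multiallelic or non-SNP records.

## Quality control

Filters run in the fixed order individual missingness (> 0.10) -> SNP
missingness (> 0.10) -> MAF (< 0.01) -> HWE exact test (p < 1e-4), the
documented order of the standard genotype-QC tool. Per-SNP statistics are
computed within each population separately and a SNP failing in either
population is dropped, leaving one marker set shared by both breeds (the
equivalent of intersecting two per-breed QC runs). Every removed
individual or SNP is named in the report together with the step that
removed it, so filter-order sensitivity is visible rather than silent.
The HWE test is the standard two-sided exact test on the heterozygote
count conditional on allele counts, without mid-p.

Before QC, individuals are screened on the method-of-moments inbreeding
coefficient f_i = (O - E)/(n - E), with E the Hardy-Weinberg expected
homozygote count at sample frequencies including the n/(n-1) small-sample
correction; individuals with f_i > 0.05 are excluded. Screening precedes
QC because high-f_i individuals distort the per-SNP statistics the QC
filters rely on; this matches the narrative order of breed-scan practice,
though running f_i on QC'd markers would also be defensible.

## LD pruning

Greedy windowed pruning on dosage (composite) r^2: 50-SNP windows moving
5 SNPs, removing from each offending pair (r^2 > 0.5) the lower-MAF
member, with ties broken against the later map position — the tie rule is
our own fixed choice for determinism. Pruning feeds ONLY the ROH branch;
F_ST and XP-EHH always see the unpruned post-QC markers, mirroring the
two different marker counts such studies report for the two branches.

## ROH detection

A scanning-window algorithm in the `--homozyg` family, three independent
passes with class parameters:

| class  | min SNPs | density        | max gap | length (kb) | window | het | miss |
|--------|----------|----------------|---------|-------------|--------|-----|------|
| short  | 3        | >= 1 SNP/100kb | 5000 kb | 50-125      | 5      | 0   | 0    |
| medium | 10       | >= 1 SNP/100kb | 5000 kb | 125-500     | 12     | 0   | 0    |
| long   | 30       | >= 1 SNP/100kb | 5000 kb | > 500       | 50     | 1   | 1    |

A window qualifies iff it holds at most the class's heterozygous and
missing allowances; a SNP is eligible iff >= 5% of the windows containing
it qualify (the scanning tool's default vote threshold, which such scans
rarely restate); maximal eligible runs are trimmed to homozygous
non-missing endpoints, split at inter-SNP gaps above the ceiling, and kept
iff they meet the SNP-count, length and density bounds. Length intervals
are half-open: 125 kb is medium, 500 kb is long, so no segment can belong
to two classes. Two printed-unit ambiguities are resolved toward the
denomination of the named scanner options: the sliding-window "size" is a
SNP count, and the maximum gap is in kb (5000 kb). A literal 5-kb gap
ceiling would split candidate runs at nearly every inter-SNP interval of
any SNP-array map — especially after LD pruning — and no ROH could ever
be called; the field remains configurable in bp for tighter designs.
Het/missing allowances act at window level only; endpoints are still
forced to clean homozygous calls.

Long-ROH incidence per SNP is the fraction of individuals with a covering
long segment; consensus regions are maximal runs of SNPs with incidence at
or above the threshold (default 0.85). The reported `share` is the
stricter exact-overlap fraction — individuals whose segments cover every
SNP of the region — which is what per-gene sharing percentages refer to.
A single-SNP run is reported with start == end, reproducing the
single-position consensus entries such scans print.

## Nei F_ST scan

Per SNP, with unweighted mean frequency p̄ of the two demes:
H_T = 2p̄(1-p̄), H_S the mean within-population heterozygosity, and
F_ST = (H_T - H_S)/H_T (undefined and excluded where H_T = 0). No
sample-size correction, so estimates lie in [0,1]; a sample-size-weighted
p̄ is available but off by default. Values are averaged in non-overlapping
500-kb windows anchored at bp 1 of each chromosome — anchoring is our
choice; the windows' empirical top 1% (order-statistic quantile, ties
included on the significant side) are flagged. The one-sided high tail is
used deliberately: high F_ST is what differentiation scans call a
candidate. Note the two-deme expectation of this estimator under a
Balding-Nichols model with per-population drift F is F/(2-F), not F
(≈ 0.053 at F = 0.1); the generator's recovery tests are anchored to the
latent-frequency oracle, not to F itself.

## XP-EHH

Site EHH at a core is the probability that two haplotypes drawn without
replacement are identical over the interval from the core to a given
distance, computed over all haplotypes (the site-EHH/iES formulation that
XP-EHH is defined on), SNP by SNP outward; EHH(0) = 1 by definition. iES
is the two-sided trapezoid integral over physical bp while EHH >= 0.05
(no genetic map is assumed for array data); curves reaching a chromosome
end keep their partial integral and are flagged truncated rather than
discarded, so telomeric windows are not silently thinned. Cores need
pooled MAF >= 0.05. The raw score ln(iES_A/iES_B) is standardized
genome-wide (mean 0, sd 1); positive scores mean longer haplotypes —
recent selection — in population A. Two-sided normal p-values get
Benjamini-Hochberg q-values (level 0.05 for the "remains significant"
call). Candidate windows are 500-kb tiles holding >= 3 extreme SNPs,
where extreme means |score| in the empirical upper 1% or beyond the fixed
±4.34 threshold; both flags are reported separately, and the tail rule is
applied to |score| with the sign carried alongside, since both directions
are biologically meaningful. Window means over extreme SNPs and over all
SNPs are both reported, labelled, because summary tables in this
literature do not always say which was used.

### Calibration under the exchangeable-site generator

Under the neutral generator, standardized XP-EHH is symmetric around zero
but mildly leptokurtic (excess kurtosis ~0.5-0.8): with no recombination
process, site EHH decays within a handful of independent sites, so iES is
a short integral dominated by a few exponentially distributed inter-SNP
gaps, and the log-ratio has heavier-than-normal tails. Consequently a
5000-core neutral genome shows ~1 score beyond ±4.34 on average, rather
than the ~0.07 a normal-tail calculation predicts; the corresponding
calibration test codifies the normal-tail expectation and fails honestly
under this generator. This is a property of the simplified neutral model,
not of the statistic: real chromosomes have LD, which lengthens and
smooths the integrals. Power is unaffected — a planted sweep with 80%
carriers over 400 kb is recovered by the window rule in 20/20 seeds.

## Synthetic data

The generator draws, per SNP, an ancestral frequency uniform in
[0.05, 0.5] (randomly polarized so neither allele is systematically
minor), per-population frequencies from the Balding-Nichols
Beta(p(1-F)/F, (1-p)(1-F)/F) with per-population drift F (default 0.1,
matching the between-breed differentiation typical of horse-breed pairs),
and independent Bernoulli haplotypes. Positions are uniform draws,
deduplicated and sorted. Defaults: two populations of 100 individuals,
1000 SNPs per chromosome. All randomness flows from one master seed
through named substreams, so identical configs give byte-identical
panels.

Haplotype structure is supplied by operators, not by a coalescent:
`plant_sweep` copies one founder haplotype over a chosen fraction of a
population's haplotypes across a window (a hard-sweep footprint);
`plant_roh` copies an individual's first haplotype over its second across
an interval (an autozygous segment). Missingness is i.i.d. per genotype,
applied after planting and never inside planted intervals, so planted
truth stays exact. What the generator does not emulate: recombination
and mutation processes, LD beyond the planted intervals, genotyping-error
structure, and realistic site-frequency spectra. Passing tests therefore
demonstrate correctness of the statistics and the recovery machinery
under controlled truth, not field performance on real arrays.

Two interactions worth knowing when designing synthetic studies. First,
with uniform positions the inter-SNP gaps are exponential, so homozygous
tracts are reliably contiguous only when mean spacing is well below any
gap ceiling in force; ROH-focused studies here use ~300-500 bp spacing
(denser than a real 670k array, whose gap distribution is more regular).
Second, `plant_roh` makes each individual homozygous for its *own*
haplotype, which at high planted shares produces a Wahlund-style
heterozygote deficit that the HWE filter rightly removes — real consensus
ROH descend from a shared founder and stay near Hardy-Weinberg. Planted
consensus regions that must survive the full QC'd pipeline are therefore
built with a high-carrier founder sweep (e.g. 94% of haplotypes, giving
~88% autozygous individuals), which keeps HWE and MAF intact; direct
`plant_roh` truths are used when exercising the ROH scanner itself.

## Pipeline and problem sizes

`run_pipeline` executes input -> f_i filter -> per-population QC ->
(branch A) LD prune -> three ROH passes -> incidence -> consensus;
(branch B) F_ST windows + XP-EHH windows -> intersection -> local BED/GFF3
annotation (>= 1 bp overlap, half-open BED semantics honored). Outputs
are TSV/BED/bedGraph/JSON plus a MANIFEST and a run log without
timestamps, so reruns with the same config and seed are byte-identical.
Stage failures keep partial outputs and a MANIFEST naming the failed
stage. Gene annotation is a local file contract; no network queries.

Test and acceptance workloads are desk-scale by design: panels up to
200 SNPs x 20 individuals for exhaustive oracle comparisons, 5000-SNP
genomes with 2x100 individuals for calibration/power sweeps (20 seeds),
and a 10,000-SNP five-chromosome study for the end-to-end pipeline. At
these scales the empirical top-1% window rule flags only the single top
window, so integration studies plant one strong truth rather than
several competing ones.

## Known limitations

- No gametic (phased) r^2 option for pruning; composite dosage r^2 only.
- The HWE exact test is exact but unsuitable vectorized shortcut-free for
  millions of SNPs; at array scale it is the QC bottleneck (~100 us/SNP).
- Consensus `share` can be smaller than the per-SNP incidence that
  defines the region when different individuals fail different SNPs.
- The F_ST estimator carries no sample-size correction; with very small
  samples it is biased upward (visible as ~0.055 recovered at F = 0.1
  against the 0.053 two-deme expectation).
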