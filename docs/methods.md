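# Methods

This note documents the models, estimators, numerical choices and known
limitations of `sweepscan`. It is the package's own account of its science;
every empirical statement here is one the test suite or
`scripts/acceptance.py` actually computes.

## Scope and data model

The pipeline operates on phased, biallelic autosomal SNPs. Internally all
coordinates are 1-based inclusive (the native VCF/GFF3 convention); BED
output is converted to 0-based half-open at the writing boundary only.
Multiallelic and non-SNP records are dropped on input (counted, logged),
never split. Haplotypes are stored as a (2N × M) 0/1 matrix per population;
genotypes as N × M dosage matrices with −1 for missing calls. Chromosomes
sort natural-numerically where the name is numeric, lexicographically
otherwise.

## Synthetic panels (simdata)

The generator exists so every downstream stage is testable without
sequencing data. Its defaults are the study conditions the rest of the
package assumes: 2–3 populations of ~30 diploids, pairwise divergence in
the 0.09–0.17 range, thousands of SNPs with a uniform ancestral-frequency
spectrum bounded away from 0 and 1 (`maf_floor` = 0.05), one chromosome of
5 Mb at ~1 SNP/kb unless configured otherwise.

**Neutral model.** Balding–Nichols: ancestral frequency
p ~ Uniform(maf_floor, 1−maf_floor); each population i draws its frequency
from Beta(p(1−F_i)/F_i, (1−p)(1−F_i)/F_i); haplotype alleles are independent
Bernoulli draws. F_i = 0 degenerates to the ancestral frequency exactly (no
division by zero). Under this model the expected pairwise F<sub>ST</sub>
between populations i and j is approximately (F_i + F_j)/2, which is how a
pairwise target matrix is mapped to per-population divergences (exactly
solvable for three populations, least squares otherwise; clipped to
[0, 0.95]). Only realized values are asserted in tests: nominal
F ∈ {0.05, 0.10, 0.17} is recovered within ±0.02 by the genome-wide
ratio-of-sums estimator at 20k SNPs and 30 diploids/pop in ≥19/20 seeds.

**Sweeps.** A sweep homogenizes haplotypes rather than only shifting
frequencies, because XP-EHH requires extended haplotype identity. For a
sweep with carrier fraction c and final frequency f: a random fraction c of
the target population's haplotypes is overwritten over the sweep span with
one shared core haplotype (core allele per site chosen alt with probability
0.5, so the sweep is not reference-biased); the remaining haplotypes draw
the core allele with probability q′ = clip((f − c)/(1 − c), 0, 1), so the
realized core-allele frequency lands near f at every site in the span.

**What the simulator does not emulate.** No recombination graph, no
demography, no LD decay away from sweeps (neutral sites are independent), no
allele-frequency spectrum skew, no genotyping error, no sex chromosomes.
Passing tests therefore demonstrate correctness of the estimators and the
calling logic under the stated statistical structure, not performance on
real resequencing data; in particular the background LD of real genomes will
make XP-EHH noisier and the LD weighting of XP-CLR more consequential than
in these panels. An optional missingness rate masks genotype calls (for QC
filter testing) while leaving the haplotype panel complete, since the
haplotype statistics require full data.

## Per-SNP statistics (popstats)

* **Weir–Cockerham F<sub>ST</sub>** from variance components a, b, c with
  per-site sample sizes (complete-case per population). Monomorphic sites
  and sites with fewer than two populations carrying data are NA and
  excluded from rankings and from both sums of the genome-wide ratio
  Σa/Σ(a+b+c). Negative estimates are kept as computed; with literal
  duplicate populations the estimator sits at its finite-sample floor
  ≈ −1/(2n−1), which is expected behaviour, not error.
* **Fisher exact test** on the 2×2 table of allele counts, two-sided by the
  point-probability rule (sum of hypergeometric probabilities not exceeding
  the observed table's, with the same 1e-7 tie guard standard library
  implementations use). Implemented as a vectorized log-gamma computation;
  zero-margin tables return p = 1. Bonferroni: p_adj = min(1, m·p) with m
  the number of SNPs in the comparison.
* **HWE exact test**: exact conditional test given allele counts, p = total
  probability of heterozygote counts no more probable than observed.
  Degenerate (empty or monomorphic) inputs return 1.
* **Diversity**: observed heterozygosity is the unweighted mean over
  individuals of het calls / non-missing calls; gene diversity is the
  per-locus Nei 1 − p² − q², averaged over callable loci, with the
  2n/(2n−1) small-sample correction by default (both variants available,
  since conventions differ between tools). IBS distance is
  1 − mean(shared alleles)/2 with het/het counting as 2 shared.
* **QC filters** apply in the fixed order MAF ≥ threshold, HWE p ≥ alpha,
  missingness ≤ threshold, with first-failing-filter attribution in the
  report. The HWE alpha (default 1e-6) and missingness cap (default 0.1)
  are configurable; defaults follow common practice for panels of this
  size.

## XP-EHH (haploscan)

EHH at distance x from the core is the pair-identity probability
Σ C(c_h,2)/C(n,2) over all haplotypes jointly (the cross-population
variant), so EHH(0) = 1 and the core's own alleles do not partition the
sample. The decay curve truncates when EHH < 0.05, when an inter-SNP gap
exceeds 200 kb, or at the chromosome end; cutoff and gap are configurable
and follow common haplotype-scanner defaults. iHH integrates the curve by
trapezoid over physical distance (no genetic map is assumed), linearly
interpolated to the exact cutoff crossing; at a hard stop the integral ends
at the last SNP. Raw XP-EHH is computed as log(iHH_A) − log(iHH_B) rather
than log(iHH_A/iHH_B) so population swap negates scores bit-exactly. Sites
where either iHH is undefined or zero are NA. Normalization is a genome-wide
z-score over finite scores (per-chromosome moments are unstable on small
simulated genomes); it errors on fewer than two finite values or zero
variance rather than emitting NaNs.

Two code paths exist on purpose: `ehh`/`ihh` are a direct, readable
implementation of the definitions, and `_ihh_scan` is the numba kernel the
scan uses; the test suite holds them equal to 1e-9 and checks both against
brute-force pair counting and hand trapezoid integration on small panels.

## Windowed composite likelihood (xpclrscan)

Windows tile each chromosome from position 1 in non-overlapping 25-kb
blocks; a final partial window is kept if it holds ≥1 SNP; windows carry at
most 500 SNPs (deterministic every-k-th thinning by position). Within a
window, the object population's allele count k of m at a SNP with reference
frequency p contributes

* neutral: L₀ = ∫ Binom(k; m, q) f(q | p, ω) dq, with f a
  Normal(p, ω·p(1−p)) density truncated to [0,1] whose tail mass becomes
  point masses at the boundaries, and ω = F/(1−F) from the genome-wide
  F<sub>ST</sub> of the two populations;
* sweep: each lineage hitchhikes with probability c = e^(−αd) (d = bp to the
  window center), carrying the swept allele; which allele was swept gets an
  equal 0.5/0.5 prior; so the binomial success probability becomes
  c + (1−c)q or (1−c)q.

The window's raw score is 2·max(0, max_α Σ w·(log L₁(α) − log L₀)) over a
log-spaced α grid (10⁻⁶…10⁻² per bp, 20 points) whose c → 0 limit recovers
the neutral model, making the score non-negative and deterministic. The
integral over q uses 64 equal cells plus the two boundary masses; binomial
probabilities are clipped at 1e-12 from the boundaries and site likelihoods
floored at 1e-300 before logs. SNP weights are 1/(cluster size) from
single-linkage clustering of reference-population r² > 0.95; monomorphic
reference columns have undefined r² and count as singletons; sites
monomorphic in the reference carry no drift information and are dropped
(an all-monomorphic window is NA). Numeric parity with the original
XP-CLR program is not a goal; the contract is the window geometry,
weighting, normalization, and rank behaviour (a swept window outscores its
own neutral null, verified by paired simulation).

`xpclr_norm` is the genome-wide z-score of raw scores over finite windows;
candidate windows are those at or above the (1 − 0.01) quantile, ties
included, so ~1% of finite windows are called by construction.

## Region calling (regioncall)

Tiers per comparison and method: FST extreme = top 0.01% of finite θ̂ AND
adjusted p < 0.01 (a conjunction — a neutral panel can therefore yield zero
FST regions); FST significant = θ̂ ≥ 0.4 AND adjusted p < 0.01; XP-EHH
extreme = top 0.1% of |z| (a pure quantile, so the XP-EHH track always has
extreme SNPs, even on neutral panels); XP-EHH significant = |z| ≥ 1.
Quantiles are genome-wide over finite scores; boundary ties are included;
NA sites are non-significant and excluded from quantiles.

Growing: extension from an extreme seed crosses runs of one or two
non-significant SNPs and stops at the first run of three (or the chromosome
end); any significant/extreme SNP resets the counter; boundaries sit on the
outermost significant-or-extreme member SNP, never on a non-significant
one. A maximal stretch (same ≥3-run delimiters) with more than five
significant SNPs and no extreme seed is also a region. These two sentences
have a closed form — split the tier sequence at runs of ≥3 non-significant
SNPs; each segment becomes the interval [first, last] of its non-N members
iff it holds an extreme SNP or more than five significant ones — which is
what the implementation uses; the test suite proves equivalence to a
literal walking transcription of the rule on every tier string of length
≤ 12 (all 797,160 of them). Adjacent called XP-CLR windows
(end + 1 = start) merge into one region.

## Genes (geneset)

A gene is assigned to a region iff its gene body overlaps the region by ≥1
bp (1-based inclusive both sides); no exon requirement, no promoter flank
(a `flank` parameter exists, default 0). Identity is keyed on the stable
gene id (any `gene:` prefix stripped), display name secondary; strand is
ignored. The final candidate set per comparison is genes present in ≥2 of
the three method sets; the cross-comparison overlap is a set intersection.

## Pipeline, determinism, problem sizes

`run_pipeline` is deterministic given its inputs: the only RNG in the
package is the simulator's, seeded from config. The manifest records
version, parameters and input checksums; every threshold is echoed into
output headers; every number in the report is re-derivable from the TSVs
(tested by recount).

Tests and the acceptance script run at deliberately desk-scale problem
sizes — 5k–20k SNPs on a 5-Mb chromosome, 30 diploids per population,
12–20 replicate seeds — chosen so the whole suite completes in about a
minute while keeping the quantile machinery meaningful (at 5k SNPs the
top-0.01% FST tier is a single SNP plus ties). The acceptance script uses
12 replicate seeds for the sweep-recovery fraction; the test suite uses 20.

## Known limitations

* No genetic map: all integrals and distances are physical (bp).
* The XP-CLR drift model is a normal approximation; very small ω with
  extreme p can concentrate nearly all prior mass in one grid cell.
* Gene diversity and heterozygosity are computed on whatever site set is
  passed; applying a MAF filter first (as diversity studies typically do)
  materially raises both, so subsets must be chosen explicitly.
* The Fisher test assumes alleles are independent draws (2N per
  population), as allele-count tests conventionally do; family structure
  would invalidate that.
* With unphased input the reader can still load genotypes
  (`allow_unphased`), but all haplotype statistics refuse to run.
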