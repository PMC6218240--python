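# Methods

## The analysis in one paragraph

Two related panels of inbred lines — an ancestral group (A, ~41 lines)
and a derived group (B, ~21 lines) shaped by decades of selection — are
scanned with cross-population selection statistics.  Per-SNP scores are
binned into nonoverlapping 10 kb windows by most extreme value, and the
windows containing a-priori trait-associated SNPs are tested for
enrichment of selection signals against two genome-wide nulls.  The
package also carries the quantitative-genetic machinery that produced
the candidate associations in the first place: balanced-design variance
components and heritabilities, and a resampling GWAS that assigns each
SNP a model-inclusion probability.

## Selection statistics

**FST.**  The haploid two-population variance-components estimator with
r = 2: with sample sizes n_A, n_B and allele frequencies p_A, p_B,

    n̄  = (n_A + n_B)/2
    n_c = (r·n̄ − (n_A² + n_B²)/(r·n̄)) / (r − 1)
    p̄  = (n_A·p_A + n_B·p_B)/(r·n̄)
    s²  = Σ n_i (p_i − p̄)² / ((r − 1)·n̄)
    T₁ = s² − (p̄(1 − p̄) − s²(r − 1)/r) / (n̄ − 1)
    T₂ = ((n_c − 1)/(n̄ − 1))·p̄(1 − p̄) + (1 + (r − 1)(n̄ − n_c)/(n̄ − 1))·s²/r
    θ  = T₁/T₂

θ = 1 exactly at a fixed difference; slightly negative values (possible
when between-population variance is small relative to within-population
heterozygosity) are retained, not truncated.  Sites monomorphic across
the union (T₂ = 0) are excluded with a logged count.

**EHH and XP-EHH.**  EHH is site-level and unconditioned on the core
allele: EHH(x) = Σ_h C(c_h, 2) / C(n, 2), where c_h counts haplotypes
sharing each distinct sequence from the site adjacent to the core
through x.  It starts at 1 by definition and is non-increasing with
distance.  iES integrates EHH against physical distance by the
trapezoidal rule in both directions; each inter-SNP interval contributes
min(gap, S)·(EHH₀ + EHH₁)/2 with scale S = 20 000 bp (long gaps in
sparse regions are down-weighted to the scale), and integration stops
before the first point with EHH below the 0.05 cutoff.  The raw XP-EHH
score is ln iES_A − ln iES_B (computed as a difference of logs so a
population swap negates it exactly); sites with iES = 0 in either panel
are unscored and omitted.  Scores are standardized by the genome-wide
mean and sd of the raw scores — normalization is not per-frequency-bin,
and is genome-wide rather than per chromosome — with the constants kept
as track metadata.

The production scan uses an exactly equivalent reformulation: identity
between two haplotypes over an interval is monitored through each pair's
nearest mismatch on either side of the core, making EHH at distance x an
order statistic of the pairwise next-mismatch positions.  One sort per
site replaces one matrix pass per (site, distance); tests assert
equality with the direct curve integration and with exhaustive pair
enumeration.

## Windows and covariates

A SNP at 1-based position p belongs to the 0-based half-open window
starting at ((p − 1) // 10 000)·10 000.  "Most extreme" binning keeps
the member score of largest absolute value with sign preserved (both
XP-EHH tails are meaningful); ties between +a and −a keep +a.  Windows
are annotated with: gene count (any overlap counts, so a gene spanning
two windows counts in both), recombination rate (cM at window end minus
cM at window start, per Mb; the genetic map is piecewise-linear with
terminal-rate extrapolation floored at 0 cM), and the mean minor-allele
frequency of the window's scored SNPs per population.  The
frequency-matching granularity is a window-level summary with an
absolute ±0.15 band — the tolerance is configurable.

## Null distributions and tests

**Circular permutation** operates on each chromosome's ordered list of
scored windows (not raw bp, so every rotated candidate lands on a scored
window): one uniform offset per chromosome per iteration shifts all
candidate window indices modulo the list length, preserving cyclic
spacing and multiplicity.  10 000 iterations by default; the pooled null
is all iterations' scores.

**Matched-window resampling** draws, per candidate window, 50 scored
non-candidate windows satisfying gene count ±1, recombination rate ±20%
(relative), and both population frequency bands ±0.15 (absolute); if
fewer than 50 windows qualify the frequency criteria are dropped and the
pool rebuilt; a pool still short of 50 is used whole with a warning.
Sampling is without replacement within a candidate's pool (the same
window may serve different candidates), and sampled scores are
replicated per association count of the candidate window so the null
has the same granularity as the observed sample.

**Tests.**  Observed vs pooled null uses the two-sample KS statistic
with the asymptotic two-sided p.  That p treats the observed scores as
exchangeable draws; when several associations share one window the
observed sample contains exact ties and the asymptotic p is
anticonservative.  For that regime the circular null also reports a
permutation p — the fraction of iterations whose own KS D against the
pooled null reaches the observed D — which inherits the candidates'
multiplicity structure and stays calibrated.  The branchiness-vs-length
contrast is a one-sided rank-sum test (H₁: branchiness scores
stochastically smaller), normal approximation with tie correction at
analysis sizes and exact enumeration for tiny tie-free groups.  Results
are reported per statistic × null method without multiplicity
adjustment.

## Synthetic data

The generator produces the signals the statistics measure without
forward-time simulation.  K = 16 founder haplotypes are Bernoulli draws
from per-site frequencies ~ U(0.05, 0.95); each sample haplotype is a
recombinant founder mosaic whose crossover count is Poisson with mean
(effective meioses) × (map length in Morgans).  The effective-meioses
depth (default 150) compresses a breeding history's accumulated
recombination into one draw and sets the physical scale of haplotype
sharing (~0.5–1 Mb segments at the default 10 cM map), which in turn
sets how fast EHH decays.  The derived panel redraws a fraction d = 0.10
of its allele copies toward derived-specific founder frequencies
(Dirichlet-weighted founder mixture), creating baseline differentiation;
sweeps replace a carrier fraction f of derived haplotypes with one fixed
founder's segment inside the sweep region, producing extended
homozygosity plus a frequency shift.  Defaults mirror the study regime:
41 vs 21 lines, one 10 Mb chromosome, 5 000 SNPs, 20 genes/Mb
(Poisson-placed, exponential lengths, mean 3 kb), piecewise map rates
(0.5, 1.5, 1.0) cM/Mb.  All generators are pure functions of
(config, seed), with the ancestral panel on its own random stream so its
realization is identical across sweep fractions.

What the generator does *not* emulate: realistic site-frequency spectra,
linkage structure from a true pedigree or coalescent, population
structure within panels, genotyping error, or missingness patterns.
Passing tests therefore demonstrate correctness and statistical behavior
of the *methods* under a controlled haplotype-sharing model, not
performance guarantees on real maize data.

RCBD phenotypes follow y = μ + g + e + g:e + b(e) + ε with independent
normal effects at the stated variances; mapping-population genotypes use
a first-order Markov copy process (switch probability 0.1 between
adjacent SNPs) around 50/50 frequencies, with noise scaled to a target
h².

## Mapping procedure

Entry thresholds are the 5% quantile of genome-wide minimum
single-marker p-values over phenotype permutations.  Stepwise selection
adds the smallest-partial-p SNP while p < α_entry and removes any term
whose drop-one p exceeds 2·α_entry, iterating to a fixed point
(ties break to the lowest SNP index; collinear duplicates are skipped).
Residuals are computed per chromosome with that chromosome's model SNPs
excluded.  Resampling draws ⌊0.8·n⌋ lines without replacement and runs
forward regression with entry p < 1e-4 and no exit — the exit step
belongs only to the initial stepwise stage — 100 times; RMIP is the
inclusion fraction.  The RMIP cutoff is the smallest value on the 0.01
grid whose mean number of passing SNPs per permutation stays within the
false-positive budget (default target_fp/n_perm = 1 per permutation
genome-wide; the accounting rule is configurable).  This is the
single-population version: family structure is assumed pre-adjusted
(e.g. phenotypes centered per family) before mapping.

## Quantitative genetics

Balanced-design method-of-moments replaces REML: σ²ε = MS_error,
σ²gxe = (MS_GxE − MS_error)/b, σ²g = (MS_G − MS_GxE)/(b·e); negative
estimates truncate to 0 with a flag.  Entry-mean heritability and
repeatability follow the formulas in the README; e = 1 designs are
accepted, where the interaction is not estimable, σ²gxe is fixed at 0
and h² reduces to r (the single-environment, image-trait case).  In the
balanced design the genotype BLUE is the genotype mean and the BLUP is
h²·(mean − grand mean).  BN, BD, PR, SK and TW can be square-root
transformed before analysis (a flag; never silently back-transformed).

## Numerical choices and edge cases

* Heterozygous VCF genotypes in these inbred panels default to missing
  (configurable to random-allele); multiallelic and non-SNP records are
  skipped with logged counts; unsorted VCFs are an error.
* The complete-data filter keeps sites fully called in both focal
  populations and polymorphic across their union (minimum MAF 0); it is
  idempotent.
* A core SNP with no integrable EHH interval in either direction
  (isolated site, or immediate sub-cutoff drop) has iES 0 and is
  unscored rather than given an arbitrary value.
* KS tests require ≥ 3 observed scores; the contrast requires ≥ 3
  scores per trait class.
* Identical populations make the XP-EHH sd zero; this raises a
  "degenerate score distribution" error instead of returning NaNs.
* Problem sizes in the test suite (10 Mb / 5 000 SNPs, 20-seed power
  runs, 200-seed calibration at 2 000 circular iterations) were chosen
  as the smallest sizes at which the statistical properties under test
  are stable.

## Known limitations

* EHH is the site-level, allele-unconditioned variant used by the
  cross-population statistic; the within-population allele-conditioned
  EHH (iHS-style) is out of scope.
* XP-CLR is consumed as an external score track, never computed.
* No REML or unbalanced mixed models; no kinship or PC correction in
  the mapping module.
* The asymptotic KS p is only calibrated when observed associations
  occupy distinct windows; with shared windows, use the permutation p
  (see above).
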