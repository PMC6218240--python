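# sweepenrich

Selection-signature enrichment analysis for trait-associated genomic
windows, built around the contrast between an ancestral and a derived
panel of inbred lines (the maize BSSSC0 vs ex-PVP setting: ~41 early
Stiff Stalk lines against ~21 modern commercial inbreds).  The question
the package answers: are the genomic windows containing a-priori
trait-associated SNPs enriched for signals of recent selection, relative
to what the rest of the genome offers?

## What it computes

**Selection statistics** (per SNP, between populations A = ancestral and
B = derived):

* Haploid Weir-style F<sub>ST</sub> with the two-population (r = 2)
  correction for few populations and uneven sample sizes:
  θ = T₁/T₂ from the variance-components mean squares; negative estimates
  are retained.
* XP-EHH: for each core SNP, EHH(x) is the probability two random
  haplotypes are identical at all sites from the core through x;
  iES is the trapezoidal integral of EHH over physical distance (both
  directions, gap weight min(1, 20 000 bp / gap), cutoff 0.05), and the
  score is ln iES_A − ln iES_B, standardized genome-wide.  Negative
  scores mean extended haplotypes — candidate sweeps — in the derived
  panel.
* Externally computed statistics (e.g. XP-CLR) attach as score tracks
  through the same interface.

**Window enrichment**: scores are binned into nonoverlapping 10 kb
windows by most extreme value; each candidate SNP-trait association gets
its window's score, and the observed distribution is tested (two-sample
KS) against two nulls: **circular permutation** (rigid rotation of
candidate positions around each chromosome's scored windows, preserving
spacing and multiplicity) and **matched-window resampling** (50 windows
per candidate matching gene count ±1, recombination rate ±20%, and
per-population allele frequencies ±0.15, frequencies dropped when fewer
than 50 windows match).  A one-sided rank-sum contrast asks whether
branchiness-trait associations score lower (more derived-panel sweeps)
than length-trait associations.

**Resampling GWAS (RMIP)**: permutation entry thresholds, stepwise
forward-backward SNP selection (exit at twice the entry threshold),
per-chromosome residuals, forward regression on 100 random 80%
subsamples (entry p < 1e-4), and a permutation-derived RMIP cutoff
keeping false positives ≤ ~1 per permutation genome-wide.

**Quantitative genetics**: derived tassel traits (BZ = TL − SL,
BD = BN/BZ, SP = SL/TL), balanced RCBD variance components, entry-mean
heritability h² = σ²g/(σ²g + σ²gxe/e + σ²ε/(be)), repeatability
r = σ²g/(σ²g + σ²ε/b), and balanced BLUE/BLUP summaries.

A synthetic-data module generates everything the pipeline consumes: a
two-population founder-mosaic panel with injected sweeps, a
piecewise-linear genetic map, Poisson-placed gene intervals, balanced
RCBD phenotypes with chosen variance components, and biparental-style
mapping populations.

## Worked example

```bash
python examples/01_sweep_scan.py
```

```
panel: 4698 complete-data SNPs x 62 lines
    FST: median inside sweeps +0.211, outside -0.020
 XP-EHH: median inside sweeps -3.483, outside +0.157
```

Three f = 0.9 sweeps injected into the derived panel push XP-EHH deeply
negative (long derived haplotypes) and F<sub>ST</sub> up inside the swept
windows.  `examples/02_enrichment.py` then tests candidates placed in
those windows:

```
statistic null_method  n_retained     ks_d         ks_p  perm_p
      FST    circular          40 0.865710 2.870370e-35  0.0012
      FST     matched          40 0.848000 2.966406e-32     NaN
   XP-EHH    circular          40 0.937018 1.861343e-48  0.0018
   XP-EHH     matched          40 0.916000 2.228961e-42     NaN
```

`ks_p` is the asymptotic two-sided KS p-value against the pooled null;
`perm_p` is the fraction of circular iterations at least as extreme as
the observed KS D.  `examples/03_rmip_mapping.py` and
`examples/04_heritability.py` walk the mapping and phenotype components.

A thin CLI mirrors the stages (`sweepenrich simulate | stats | bin |
enrich | rmip | quantgen`); see `sweepenrich --help`.

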