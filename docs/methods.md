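# Methods

## Model and assumptions

`aeiscan` detects allelic expression imbalance (AEI) from per-sample
allele depths at heterozygous transcribed SNPs. The underlying assumptions
are those of count-based allele-specific expression analysis:

* at a het SNP with no cis-regulation, alternative reads are a noisy
  fraction ~0.5 of the total depth, so the log allelic ratio
  `x = ln(alt/ref)` is approximately normal around 0;
* a cis-regulatory variant shifts the expressed fraction of one haplotype,
  moving `x` away from 0 at *every* transcribed SNP of the affected gene,
  with a direction set by the phase between the measured SNP and the
  regulatory allele;
* sequencing and sampling noise dominate within the balance band; biological
  imbalance shows up as outliers relative to an empirical reference
  distribution.

The detection rule is deliberately empirical rather than test-based: log
ratios are assumed normal within a reference population and values strictly
outside `mean ± k·SD` (k = 2 by default, a ~4.6% two-sided tail) are
outliers. No binomial/beta-binomial hypothesis test, phasing, or
mapping-bias correction is applied; those are out of scope by design, and
the empirical rule is what the report semantics are built on.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_qual` | 225 | site QUAL, strict `>` (a site at exactly 225 fails) |
| `min_depth` | 20 | total reads per record, `>=` |
| `min_allele_reads` | 2 | reads supporting each allele, `>=` |
| `require_rsid` | true | keep only sites with a dbSNP identifier (VCF ID column non-missing; an allowlist can be emulated upstream) |
| `ratio_low`, `ratio_high` | 0.666, 1.5 | balance band on `alt/ref`; strictly outside = moderate imbalance; equivalent to <40% / >60% allele contribution |
| `outlier_scope` | `per_sample` | reference population for `mean ± k·SD`: all passing variants of one sample; `per_variant` (across samples at one site) available |
| `k_sd` | 2 | number of SDs defining an outlier |
| `min_cohort_freq` | 10 (%) | strict `>` cut on cohort AEI frequency at report time |
| `cohort_size` | n. samples | explicit denominator for cohort frequencies, so partially genotyped cohorts are handled predictably |

Choices worth flagging:

* **Outlier scope.** The reference population is per sample by default:
  variant selection asks "does at least one sample stand out among its own
  variants", which is the natural reading when variants are subsequently
  selected by having outliers *in at least one sample*. The per-variant
  alternative is implemented and exposed because the choice is genuinely
  open; summaries record identical columns either way.
* **Log base.** Natural log. The `mean ± k·SD` rule is equivariant under
  any affine transform of the log ratios, so the base cannot change any
  flag; it is fixed only for reproducibility of reported model parameters.
* **Boundary strictness.** The balance band is open (0.666 and 1.5
  themselves are balanced); the QUAL threshold is strict; the frequency cut
  is strict. Report headers that print `<0.66` are display rounding of
  0.666 (the bound is configurable).
* **Single-hit exclusion.** `retained_multi` implements the rule that a
  variant with exactly one outlier sample needs at least one further
  moderately imbalanced sample to survive; with two or more outlier
  samples it survives outright.
* **Per-sample counting vs selection.** Report columns count imbalanced
  samples by the moderate band (the two directional columns sum exactly to
  the imbalanced total); the outlier rule drives variant *selection* only.
  Ratio statistics (oriented mean, SEM, kurtosis, SEK) are computed over
  the imbalanced samples only — the SD/SEM and SEK sample sizes are then
  mutually consistent (SEM = SD/√n with n the imbalanced count, and SEK is
  a function of that same n).
* **Kurtosis convention.** Bias-corrected excess kurtosis G2 (scipy's
  `kurtosis(..., fisher=True, bias=False)`), the convention whose standard
  error is `SEK = 2·SES·sqrt((n²−1)/((n−3)(n+5)))`. G2 needs n ≥ 4 and a
  nonzero SD; SEK needs n ≥ 6; otherwise the columns are reported missing
  (`NA`) with a warning rather than silently computed under another
  convention.
* **Sex chromosomes.** Processed like autosomes (ratios are
  strand-independent and the statistics are per-site); X-inactivation makes
  chrX interpretation biologically delicate, which is left to the reader of
  the report rather than to special-cased statistics.

## Synthetic cohorts

The generator emulates the cohort structure the screen expects — not reads,
not alignment. Defaults describe a 52-donor cohort: marker allele frequency
0.3 under Hardy–Weinberg, negative-binomial depth with mean 80 (dispersion
10) resampled to stay ≥ 20, beta-binomial allele counts with intra-class
correlation ρ = 0.01, and cis-regulated variants whose repressed haplotype
contributes 30% of transcripts (oriented ratio 3/7 ≈ 0.43, mid-range for
real AEI SNPs). The regulatory locus is a single biallelic allele at the
marker's own frequency; haplotype frequencies follow from a target r²
(default 1.0) with the repressive allele coupled to the alternative marker
allele, so imbalance direction tracks phase. ρ has no empirical estimate
from real retina cohorts and is documented as a free parameter; 0.01 keeps
balanced variants mostly inside the 40–60% band at depth ≥ 20.

What the simulation does *not* contain — mapping bias toward the reference
allele, positionally correlated errors, degraded-RNA depth profiles,
multi-SNP haplotypes within one gene — bounds what passing tests show:
they validate the statistics and the pipeline plumbing, not robustness to
alignment artefacts. On real data the moderate band will also capture
reference-bias shifts, which is exactly why a region blacklist and
orthogonal pyrosequencing validation are part of the workflow.

Randomness: one seed feeds a counter-derived substream per variant
(`SeedSequence(seed, spawn_key=(variant_index,))`), so enlarging a cohort
never perturbs previously generated variants and all outputs are
bit-identical under a fixed seed.

## Pyrosequencing comparator

Technical replicates (typically 3 PCRs at DNA level, 4 cDNA syntheses at
RNA level, though any n ≥ 1 is accepted and recorded) are aggregated to
mean ± SEM of the allele-A percentage. A level is balanced when its mean
lies in the inclusive 40–60% band; AEI is confirmed when DNA is balanced
and RNA is not. An imbalanced DNA level (e.g. segmental variation or assay
artefact) invalidates the comparison and is flagged, never confirmed. No
DNA-vs-RNA significance test is applied: the decision is band membership,
matching how such validations are read in practice.

## Numerical choices and degenerate inputs

* Outlier bounds are compared with a relative/absolute tolerance
  (1e-9/1e-12) so that values numerically indistinguishable from a bound —
  including every member of a constant population, whose SD is snapped to
  exactly 0 — are never flagged by rounding noise.
* SEM is 0 by convention (with a warning) for a single value; frequency
  denominators of zero raise.
* Samples (or sites, under per-variant scope) with fewer than two passing
  records cannot support an outlier model; their records are left unflagged
  and a message is logged.
* Multi-allelic and non-SNV records are dropped at VCF read time (count
  logged) or rejected when `drop_nonbiallelic=false`; genotypes come from
  GT only, and records without usable AD become missing-genotype records
  that no filter passes.
* Report rounding: one decimal for percentages, three decimals for ratios
  and SEM, four significant figures for kurtosis and SEK.

## Calibration and known limitations

The per-record outlier rate of the `mean ± 2·SD` rule is well calibrated:
on balanced beta-binomial cohorts it sits near the ~4.6% normal tail
(measured 3.6–5.9% per sample across seeds in the test suite). At the
*variant* level, however, the selection rule is intentionally permissive:
with ~20 heterozygous samples per variant, the chance that at least one is
an outlier by noise alone is `1 − 0.954^20 ≈ 0.61`, and the single-hit
rescue clause (one outlier plus one further moderate sample) fires often at
typical depths. Measured on default null-only cohorts, roughly 60–65% of
balanced variants survive selection, and the multi-hit rule barely reduces
this. This multiplicity is a property of the published empirical rule
itself, not of this implementation; it is why the screen is a *candidate
generator* whose output is then restricted by gene panel, cohort-frequency
threshold (> 10%), directionality/kurtosis reading, and orthogonal
validation. Users wanting a calibrated per-variant error rate should raise
`k_sd`, use `--multi-only` with a stricter frequency cut, or follow up with
a dedicated count-based test outside this package's scope.

Problem sizes used in the test suite (chosen to exercise the statistics at
cohort scale while keeping the default run fast): calibration uses 10 seeds
of 2,000 balanced variants over 12 samples (~1,000 passing records per
sample); parameter recovery uses the default 52-sample, 200 + 50-variant
cohort; monotonicity checks use 100 + 40 variants at three effect sizes and
three depths.
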