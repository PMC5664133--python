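# aeiscan

Allelic expression imbalance (AEI) screening from RNA-seq allele counts.

## The problem

In a heterozygous individual, the two alleles of a gene are usually
transcribed at similar levels. A *cis*-acting regulatory variant (a
cis-eQTL) breaks this symmetry: one chromosome copy produces more mRNA than
the other, which shows up at every transcribed heterozygous SNP of the gene
as an imbalance between reference- and alternative-allele read counts.
Tracking such allelic expression imbalance across a cohort identifies genes
under common cis-regulation — of particular interest for disease genes with
incomplete penetrance or variable expressivity, where expression of the
wild-type allele can modulate the phenotype (well documented for several
inherited-retinal-disease genes such as *BEST1*, *PROM1*, *RP1* and
*PRPH2*).

`aeiscan` takes the output of an upstream RNA-seq variant-calling pipeline
(a multi-sample VCF with per-sample `GT:AD:DP`, or an equivalent
tab-separated count table) and produces a per-SNP cohort report of AEI. It
also ships a pyrosequencing-validation comparator and a synthetic-cohort
generator with ground truth, so every stage is testable without external
data.

## Method

For each sample *s* and biallelic transcribed SNP *v*, let `a` and `r` be
the alternative and reference read counts. Records are kept when the sample
is heterozygous, site QUAL > 225 (strict), total depth ≥ 20, each allele is
supported by ≥ 2 reads, and the site has an rsID. Then:

* **linear ratio** `R = a / r`, **log ratio** `x = ln R`;
* **outlier rule**: within a reference population of log ratios (by default
  all of a sample's passing variants), values strictly outside
  `mean ± 2·SD` are outliers. A variant is retained if at least one sample
  is an outlier; the stricter *multi-hit* rule additionally requires a
  second outlier, or one outlier plus one further moderately imbalanced
  sample;
* **moderate imbalance**: `R` strictly outside `[0.666, 1.5]`, i.e. one
  allele contributing < 40% or > 60% of reads
  (`percent = 100·R / (1 + R)`);
* **cohort summary** per variant: imbalanced samples counted by direction
  (`R < 0.666` vs `R > 1.5`), AEI frequency among heterozygotes and in the
  whole cohort, the **oriented** mean ratio `min(R, 1/R)` ± SEM over the
  imbalanced samples, and their bias-corrected excess kurtosis G2 with its
  standard error `SEK = 2·SES·sqrt((n²−1)/((n−3)(n+5)))`,
  `SES = sqrt(6n(n−1)/((n−2)(n+1)(n+3)))`. High kurtosis and a
  one-directional split indicate a single regulatory variant in linkage
  disequilibrium with the SNP;
* optional restriction to a disease-gene panel, removal of
  mapping-conflictive regions (BED), and a strict > 10% cohort-frequency
  cut.

## Worked example

Simulate a 52-donor cohort with 30 balanced variants and 5 cis-regulated
variants (the repressed haplotype contributes 30% of transcripts), fit the
screen, and report variants with cohort AEI frequency above 10%:

```python
from aeiscan import AllelicImbalanceModel, SimConfig, simulate_cohort

table, truth = simulate_cohort(SimConfig(n_null_variants=30, n_aei_variants=5, seed=42))
results = AllelicImbalanceModel(table, cohort_size=52).fit()
df = results.summary()
print(df[df.freq_cohort_pct > 10].round(3).to_string(index=False))
metrics = results.evaluate(truth)
print(metrics.sensitivity, metrics.tp, metrics.fn)
```

Output (columns abridged):

```
           gene_snp  n_het  n_ratio_below  n_ratio_above  n_imbalanced  freq_het_pct  freq_cohort_pct  abs_mean_ratio  sem_ratio  kurtosis   sek
SIMG0024_rs90000024     25              3              3             6        24.000           11.538           0.529      0.039    -2.373 1.741
SIMG0031_rs90000031     22             20              0            20        90.909           38.462           0.471      0.022     0.211 0.992
SIMG0032_rs90000032     17             15              0            15        88.235           28.846           0.410      0.025    -0.970 1.121
SIMG0033_rs90000033     20             18              0            18        90.000           34.615           0.447      0.025    -0.760 1.038
SIMG0034_rs90000034     15             15              0            15       100.000           28.846           0.395      0.026    -0.946 1.121
SIMG0035_rs90000035     23             20              0            20        86.957           38.462           0.400      0.020    -0.459 0.992
```

The five simulated cis-regulated variants (`SIMG0031`–`SIMG0035`) are
unmistakable: nearly every heterozygote is imbalanced, all in the same
direction (only `n_ratio_below` populated, because the repressive allele is
in complete LD with the alternative marker allele), with oriented mean
ratios near the simulated 3/7 ≈ 0.43. Occasional balanced variants such as
`SIMG0024` also pass the frequency cut — scattered in both directions, the
signature of noise rather than cis-regulation — which is why direction and
kurtosis matter when reading the report. `evaluate` confirms sensitivity
1.0 (5 true positives, 0 false negatives) on this cohort.

The same pipeline runs from the shell:

```bash
aeiscan simulate --seed 42 --n-null 30 --n-aei 5 --out sim/
aeiscan scan sim/cohort.vcf --cohort-size 52 --min-cohort-freq 10 --out scan/
aeiscan pyro measurements.tsv --out pyro/
```

`scan` accepts `--panel` (gene list, optional inheritance column),
`--blacklist` (BED; an approximate example ships in
`src/aeiscan/data/blacklist_example.bed`), `--multi-only` to exclude single
AEI hits, and all thresholds as flags or via a YAML config.

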