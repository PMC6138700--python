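# ervrates

Context-dependent germline mutation rate estimation from singleton
variants (ERVs — extremely rare variants).

## The problem

Germline mutation rates vary enormously with the local sequence context —
a methylated CpG cytosine deaminates orders of magnitude faster than the
average site — and with the genomic landscape (replication timing,
recombination, chromatin state). Common SNVs are a biased window on this
process: older variants have been filtered by selection and GC-biased
gene conversion. Singletons, seen exactly once in a large cohort, are
near-pristine samples of recent mutation. `ervrates` implements the full
analysis cycle around this idea, for population geneticists and method
developers who need an expected-mutation-rate map:

1. **Subtype taxonomy and rates** — every biallelic SNV is classified into
   a K-mer *mutation subtype*: a centred motif plus the substituted allele,
   strand-collapsed so the central reference base is A or C (so `T>G` in a
   motif is the same subtype as `A>C` in its reverse complement). With
   K ∈ {1,3,5,7} there are 6, 96, 1536 and 24,576 subtypes. The *relative
   mutation rate* of a subtype is

   `rate = (# singletons at the motif's central base) / (# motif occurrences in the reference)`

   — a proportion, not a per-generation rate. Rates nest exactly: each
   K-mer rate is the motif-count-weighted mean of its 16 (K+2)-mer
   constituents, and a 15-df chi-squared test quantifies heterogeneity
   among them.
2. **Sample QC** — each sample's private 3-mer spectrum (96 rates) enters a
   rank-3 non-negative matrix factorization; samples whose signature
   contribution sits more than 2 SD from the cohort mean are flagged as
   likely error/batch artifacts.
3. **De novo validation** — candidate rate tables are compared by how well
   they predict held-out de novo mutations against a random nonmutated
   background, via single-covariate logistic regression
   `logit Pr(d_i = 1) = α₀ + α₁ r_iM`, ranked by `AIC = 2 − 2 ln L` and
   Nagelkerke's pseudo-R².
4. **Feature effects** — per 7-mer subtype (with ≥ 20 observed singletons),
   a multiple logistic regression of per-site mutation status on 11 binary
   features, 3 continuous features (10-kb window means) and read depth;
   Benjamini–Hochberg FDR per feature across subtypes.
5. **Rate map** — per-site predicted probabilities for all three
   alternative alleles via the inverse-logit of the fitted models, with
   marginal-rate fallback, exported as TSV/bedGraph, plus VCF annotation.
6. **Synthetic data** — a forward-model generator (genome, feature tracks,
   per-sample singletons, de novo sets, QC spike-ins) with serialized
   ground truth, so every stage has parameter-recovery tests without any
   external download.

## Worked example

```python
import numpy as np
from ervrates.simulate import gen_genome, make_truth, gen_singletons, gen_denovo
from ervrates.rates import estimate_rates, aggregate_rates, heterogeneity_tests
from ervrates.validation import (sample_background, build_testing_sites,
                                 annotate_covariate, fit_validation_model,
                                 compare_models)

genome = gen_genome(1_000_000, gc_fraction=0.4, seed=42)
truth = make_truth(seed=43)
singletons = gen_singletons(genome, truth, n_samples=100, seed=44)

t7 = estimate_rates(singletons, genome, 7)
t5, t3 = aggregate_rates(t7), aggregate_rates(aggregate_rates(t7))
print(t3.to_frame().sort_values("rate", ascending=False).head(3))
```

prints (42,727 singletons in this cohort):

```
motif alt  erv_count  motif_count     rate
  ACG   T       3429        24022 0.142744
  GCG   T       2219        15929 0.139306
  TCG   T       3304        23747 0.139133
```

The three fastest 3-mer subtypes are all CpG transitions, at rates ~0.14 —
the hypermutability the generator plants and the estimator recovers.
Heterogeneity testing reports 30/96 3-mer subtypes with significantly
non-uniform 5-mer constituent rates (p < 0.05). Validating the estimated
tables against 2,000 synthetic de novo mutations plus 40,000 background
sites:

```
3-mer: AIC=14694.1  dAIC=0.0    R2=0.1023
5-mer: AIC=14740.8  dAIC=46.6   R2=0.0989
1-mer: AIC=14829.3  dAIC=135.2  R2=0.0925
7-mer: AIC=14926.9  dAIC=232.8  R2=0.0854
```

Note the instructive inversion: at this desk scale each 7-mer motif occurs
only ~120 times, so the *estimated* 7-mer table is mostly sampling noise
and the smoother 3-mer table predicts de novos best. Fed the *generative*
7-mer rates as covariates instead (as the acceptance suite does), the
7-mer strategy attains ΔAIC = 0 and 1-mer ranks last — longer contexts
win exactly when their rates are estimated from enough data.

A CLI wraps the common entry points:

```bash
ervrates simulate --length 1000000 --samples 100 --seed 42 --out-prefix toy
ervrates map --fasta toy.fa --vcf toy.singletons.vcf --out toy.map.tsv
ervrates annotate --fasta toy.fa --vcf toy.singletons.vcf \
    --rates toy.rates.tsv --out toy.annotated.vcf
```

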