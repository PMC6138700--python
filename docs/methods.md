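# Methods

## Mutation subtypes and relative rates

A *mutation subtype* is a pair (motif, alt): a K-mer of reference sequence
(K odd, K ∈ {1,3,5,7}) and the substitution of its central base. Subtypes
are strand-collapsed: when the central base is G or T, the motif is
reverse-complemented and the alleles complemented, so every subtype's
central reference base is A or C and a mutation and its minus-strand
mirror are one subtype. Enumeration order is lexicographic by (motif,
alt), fixed across all tables and outputs so files are diffable.

The *relative mutation rate* of a subtype is the count of singletons
(cohort allele count exactly 1; the allele-count window is configurable,
e.g. `min_ac=10, max_ac=None` for a common-variant table) observed at the
central base of the motif, divided by the number of occurrences of the
motif in the reference, counted by a 1-bp sliding window (a run of 4 As
contains two AAA 3-mers). It is a proportion conditioned on cohort size
and calling pipeline, not an absolute per-generation rate, and no such
calibration is attempted.

Coordinates follow the named standards bit-exactly: VCF positions 1-based,
BED/bedGraph intervals 0-based half-open. Windows containing an N are
excluded from counting and context extraction; accessibility masks filter
on the central base only, matching per-site accessibility semantics. The
reference base is treated as ancestral; a variant whose REF disagrees with
the genome is a hard error, not a silent skip.

### Nesting and its edge caveat

Summing a (K+2)-mer table's counts over the 16 children of each K-mer
parent reproduces the K-mer table, making each parent rate the
motif-count-weighted mean of its constituents. On a finite *unmasked*
genome the identity is exact for singleton counts classified at both K
but off by edge windows for motif counts: a K-window 1 bp from a contig
end has no enclosing (K+2)-window. Whenever the accessibility mask
excludes positions within (K_max−1)/2 bases of contig ends and Ns — as
strict masks do in practice — the identity is exact at every K, and the
test suite asserts it in exactly that setting.

### Heterogeneity test

For each parent subtype, rate uniformity across its 16 constituents is a
Pearson chi-squared on the 16×2 table of (singleton, non-singleton)
occurrences, always reported at 15 degrees of freedom; children with zero
motif occurrences contribute nothing. The contingency form was chosen (the
alternative — a test on the 16 rates directly — is underdetermined)
because it respects unequal motif counts and yields the canonical 15 df.
A parent with zero singletons is returned as explicitly untestable rather
than p = NaN. Under a simulated homogeneous null the p-values are uniform
(KS-tested in the suite).

### Table comparison

Two same-K tables are compared after dividing each subtype's rate by its
table-wide sum (the normalization scheme is declared in the comparison's
summary metadata, as the convention is not standardized): overall and
per-basic-type Spearman correlations, per-subtype normalized ratios, and
the fraction of comparable subtypes whose normalized rates differ by 50%
or more. The GC-strata test classifies each 7-mer motif by the G/C count
of its six flanking bases (high: 4–6, low: 0–3) and t-tests
log(normalized ratio) between strata per basic type, which detects
GC-correlated biases such as gene-conversion enrichment among older
variants.

## Sample QC by NMF

Each sample's private 3-mer spectrum (96 relative rates computed from only
that sample's singletons) forms a row of a non-negative matrix factorized
at rank 3 by Frobenius-objective multiplicative updates: 5 random
restarts, 500 iterations, relative tolerance 1e-6 by default (deeper
settings are used where near-exact reconstruction is the point —
multiplicative updates converge linearly and need ~2×10⁴ iterations to
push an exactly-rank-3 input below 1e-6 relative error). The objective is
asserted non-increasing every iteration, up to float roundoff. The seed is
a required, logged parameter, and results are deterministic given it.

Contributions are row-normalized to proportions before outlier screening,
since a "relative contribution" is compositional; raw loadings are
available via `normalize_contributions=False`. A sample is flagged when
any signature's contribution deviates more than `k_sd` (default 2) SDs
from that signature's cohort mean. A signature whose SD is at float-noise
level flags nobody. Flagging is invariant to sample order, and removing
flagged samples changes only singleton counts, never motif counts.

NMF is identifiable only up to permutation and positive diagonal scaling,
and only separable-ish inputs (some near-pure samples per signature)
pin the factors; the recovery tests construct such inputs deliberately.

## De novo validation

Rate-estimation strategies are ranked by their ability to predict de novo
mutations. The testing set is the union of the de novo sites (d = 1) and n
background sites (d = 0) drawn uniformly without replacement from
mappable (non-N) positions, excluding de novo positions (exclusion is a
design choice to avoid label conflicts; whether background draws should
additionally respect an accessibility mask is exposed as `use_mask`).
Because one nonmutated site could serve as background for three different
mutation types, the background is randomly partitioned into three sets —
sizes ceil(n/3) then an even remainder split, so 1,000,000 sites give
333,334/333,333/333,333 — interpreted respectively as nonmutated A>G/C>T,
A>C/C>G and A>T/C>A according to each site's reference base. Every site
gets one of 9 basic types: A>C, A>G, A>T, and CpG/non-CpG splits of the
three C types, where CpG status is evaluated on the canonical strand (a
reference G is a minus-strand C, so its CpG check looks at the *previous*
base being C).

Each strategy M annotates site i with a covariate r_iM — the relative
rate (or model-predicted probability) of the site's subtype at the
strategy's K — used untransformed on the probability scale, and a
logistic regression `logit Pr(d_i = 1) = α₀ + α₁ r_iM` is fit by IRLS
(statsmodels GLM, binomial family; deviance tolerance 1e-8, 100
iterations). Goodness of fit uses `AIC = 2 − 2 ln L` — the parameter count
deliberately counts the single covariate only — and Nagelkerke's R²
against the intercept-only null, computed on the log scale for stability.
A constant covariate reduces to the null fit with R² = 0; non-convergence
or separation is flagged, never silently reported. AIC comparisons demand
identical site counts across strategies and report ΔAIC from the best
model; ΔAIC < 10 is conventionally "comparable". Because the slope
absorbs linear rescaling, any monotone linear transform of a covariate
leaves the ranking unchanged.

## Feature effects

For each 7-mer subtype with at least 20 observed singletons, every genome
site centred on the subtype's motif is labelled Z = 1 iff it carries a
singleton of exactly that subtype, and Z is regressed (ML logistic, IRLS)
on an intercept, 11 binary features (membership of the central site in the
track's intervals), 3 continuous features (mean over a 10-kb centred
window, truncated at contig edges), and read depth at the central site —
16 parameters. Sites with a missing predictor are dropped and counted.
Continuous predictors are divided by one-tenth of their observed range, so
each coefficient is the log-odds change per 10% increase across the
feature's range (the "per 10% increase" convention is not precisely
defined elsewhere; the scale used is stored on the fitted model).
Constant predictor columns are pinned to zero rather than left
unidentified, which also makes the featureless fit reduce exactly to the
marginal rate: inverse-logit(β₀) equals singletons/sites to machine
precision. Separation or collinearity withholds coefficients with a note.
Interaction terms are deliberately excluded (91 extra parameters per
subtype would invite overfitting). Subtypes are processed as independent
site streams, so memory never scales with the number of subtypes.

Benjamini–Hochberg FDR (q = 0.05) is applied per feature across all
fitted subtype models; flags carry the effect direction. Category
enrichment among flagged subtypes (e.g. one basic type, or W[A>G]W flank
membership with W ∈ {A,T}) uses the exact binomial upper tail against the
null proportion implied by the enumeration (1/6 per basic type, 1/4 for
two free W flanks), with the null proportion logged. De novo
enrichment/depletion inside a feature's intervals is a 1-df Pearson 2×2
chi-squared (de novo vs background × inside vs outside), falling back to
a labelled Fisher exact test when an expected cell is zero.

## Rate map

Each predictable site gets three independent probabilities, one per
alternative allele, from the inverse-logit of its subtype's fitted model
evaluated at the site's predictors, using *all* estimated effects whether
or not individually significant. The three are deliberately not
renormalized against a no-mutation probability. Sites inside the
configured telomeric exclusion (default 0 at desk scale, with a warning;
5 Mb is the sensible genome-scale setting since feature data are
unavailable near chromosome ends) or with unfitted subtypes receive the
marginal 7-mer rate, and every prediction carries its provenance. Map
export (6-significant-digit TSV or bedGraph) enforces coordinate order;
VCF annotation adds SUBTYPE/KRATE/PRED INFO fields, passes non-SNVs
through flagged, and flags REF-mismatching records instead of annotating
them.

## Synthetic data

The generator is the analysis model run forwards. A genome is i.i.d.
bases at a requested GC fraction (default 0.4, roughly autosomal). True
7-mer rates are lognormal spread (σ = 0.5) around per-type means — A>G
0.018, C>T 0.022 (CpG C>T 0.12), A>C/A>T 0.004, C>A/C>G 0.007 — chosen to
mirror the observed singleton spectrum of large human cohorts: transitions
over transversions and strongly hypermutable CpG transitions, at
proportions (a few percent of motif sites carrying a singleton) matching
what cohort-scale singleton sets actually yield. Singletons are
independent Bernoulli draws per (site, alt) with logit equal to the
subtype baseline plus any planted feature effects — exactly the
feature-effect regression's generative assumption — and are assigned to
samples uniformly or by planted signatures. De novo sets are weighted
draws without replacement (exponential-race keys) proportional to the
same rates, optionally perturbed to test ranking robustness. QC spike-ins
resample a chosen sample's variants from a spiky Dirichlet(0.05) 3-mer
spectrum. Binary tracks are random non-overlapping 500-bp bins hitting
the requested coverage; continuous tracks are normalized random walks in
100-bp bins; depth is gamma-Poisson (overdispersed) per bin. Every
generator is deterministic given its seed, and the ground-truth object
(rates, betas, signatures, seeds) is serialized beside each dataset.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: mutation clustering and multinucleotide
events (sites are independent), linkage and demography, sequencing-error
profiles beyond the depth covariate, reference mispolarization, and
realistic K-mer composition of a real genome (i.i.d. bases make motif
counts near-uniform within GC strata).

## Problem sizes and numerical choices

The test suite runs at desk scale by the generator's preset: genomes of
0.2–2 Mb, cohorts of 40–200 samples, 2,000–5,000 de novo mutations per
replicate, and 100,000-site backgrounds for the ranking experiments —
large enough to populate the 7-mer taxonomy's common subtypes while a full
run completes in minutes. The QC spike-in experiment uses the 2-Mb end of
the preset so each sample carries a few hundred singletons; with much
smaller cohorts, multinomial noise in the 96-dimensional spectra—not the
spikes—dominates the contribution SDs. Rates are stored at full precision;
4-decimal rounding appears only in display. Logistic tie-breaks,
degenerate inputs (constant covariates, zero-SD signatures, empty strata,
zero-singleton parents) all return explicit markers or documented
reductions rather than NaNs.

## Known limitations

Heterogeneity p-values rely on the chi-squared approximation and are
anti-conservative when expected counts per child are very small; the
desk-scale suite works at expected counts ≥ ~50. The NMF outlier screen
inherits NMF's non-convexity: different seeds can flag marginally
different boundary samples. Feature-effect estimates assume the 10-kb
window mean is the right smoothing scale for continuous features, and
depth enters linearly on the log-odds scale. The validation framework
scores strategies on the probability scale as specified; a logit-scale
covariate would be a different (sometimes better-calibrated) model.
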