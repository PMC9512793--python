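# Methods

## The estimand

For a census panel of m cancer genes and n sequenced tumor sites, the
quantity of interest is each gene's *epidemiologically weighted mutation
proportion*: the probability that a randomly drawn cancer patient from the
whole registry population carries at least one protein-altering somatic
mutation in that gene,

    P_i = sum_j  prob[i, j] * v_j

where `prob[i, j] = count[i, j] / N_j` is the conditional probability that
gene i is mutated in site j's cohort (a sample counts at most once per gene,
regardless of how many distinct mutations it carries), and `v` is the
per-site incidence weight vector. Cohort mutation rates alone over-represent
heavily sequenced cancers; weighting by registry incidence corrects the
sampling frame to the patient population.

## Filtering

Two tiers, applied after gene-synonym resolution and duplicate-call
collapse:

1. **Panel filter** — keep records whose official symbol is in the census
   panel.
2. **Consequence filter** — keep protein-altering classes only:
   missense, nonsense, frameshift, inframe indel, splice. Silent,
   noncoding, structural-variant, fusion and unclassifiable records are
   removed. Frameshift indels are retained under the truncating umbrella by
   default; the retained-class set is a config knob
   (`retained_classes`) for sensitivity analysis, since some published
   pipelines fold frameshifts into "truncating" and others list them
   separately.

Duplicate collapse (same sample, gene, position, alleles) guards against
records duplicated when profiles are merged from several repositories; it
cannot affect prevalence (which deduplicates per sample anyway), only
accumulated rates.

## Incidence weights and the Q rescaling

Preliminary weights are per-site incidence fractions: cases summed over all
available years divided by the total. Summing over years rather than
averaging leaves the weights identical (the two differ by a constant
factor); summation is used because registry reports publish annual counts.
Counts, not crude rates, are the input: weights are the sites' percentage
contribution to total cases, which only equals the rate-based weighting when
population denominators are constant across sites.

Sites with registry incidence but no sequencing data cannot contribute a
conditional probability; their summed preliminary weight is Q, and the
remaining (sequenced) sites' weights are divided by (1 − Q) so the final
vector again sums to one — exactly renormalized after the division to keep
the ±1e-9 invariant independent of floating-point accumulation order. Q = 1
(no sequenced site) is an error. Sites sequenced but *absent from the
registry table* are the opposite mismatch: they get zero weight, are dropped
from the matrix, and trigger a warning rather than an error, since they
carry information the weighting simply cannot use.

Incidence recorded under ICD-O-3 categories is converted by a many-to-one
category → ICD-10-site map: site weight = sum of its categories' weights
(mass conserved, checked to 1e-12 in tests), then the same Q rescaling.
Conversion commutes with normalization, which the tests verify on random
tables.

## Confidence intervals

A parametric bootstrap: for each of `n_reps` (default 2,000) replicates,
every cell's mutated-sample count is redrawn as Poisson with mean equal to
the observed count, and the full scalar-product pipeline is reapplied to the
resimulated counts; the interval is the empirical 2.5/97.5 percentile of the
replicate P_i values.

Numerical choices made deliberately:

- **Counts, not proportions, are resimulated**, and draws are **clamped at
  the cohort size** N_j so resimulated proportions stay in [0, 1]. Without
  the clamp a cell near saturation can yield proportions above 1.
- **Replicate-level propagation**: the interval is computed on the weighted
  P_i per replicate, not per-cell intervals combined afterwards, because the
  estimator is linear in the cells and the replicate-level distribution is
  the object the percentiles should summarize.
- **One RNG stream, seeded once, replicate-major draw order** (chunked
  internally for memory, with a regression test that chunking does not
  change the stream): repeated runs are bit-identical.
- Genes with zero counts everywhere get the degenerate interval (0, 0) —
  Poisson(0) is a point mass. No rule-of-three upper bound is substituted;
  this is a documented limitation for never-observed genes.
- `ci_low <= point <= ci_high` is *not* asserted anywhere: percentile
  intervals from resimulated counts can sit asymmetrically around the point
  estimate; only `ci_low <= ci_high` and containment in [0, 1] are
  guaranteed.

The Poisson resampling model has variance N·p per cell where the binomial
data-generating variance is N·p·(1 − p), so intervals are mildly
conservative at larger p. At the moderate per-site rates used in the
coverage study (p between 0.04 and 0.15, cohorts of 120–200), measured
coverage sits near 95% and within the 92–98% acceptance band.

## Comparison layer

- **Ranking**: descending by rate, ties broken alphabetically (recorded on
  the output); zero-rate genes are unranked, and a short list is returned
  with a warning when fewer than k genes qualify.
- **Top-k overlap** uses the common-rate formula 2·(T − U)/T with T the
  summed list sizes and U the union size; for equal-size deduplicated lists
  this is algebraically |A ∩ B|/k, verified exhaustively for k ≤ 6 over a
  10-gene universe.
- **TP53 pattern**: the top cluster is every gene within `delta` (default
  0.10, i.e. 10 percentage points) of the highest rate. TP53 alone →
  *TP53-Top*; TP53 plus one or two others → *TP53-Plus*; otherwise
  *Non-TP53*. The cluster width is a genuinely open design choice — no
  quantitative rule accompanies published per-cancer pattern labels — so
  delta is a named, reported parameter rather than a constant.
- **Correlation**: Pearson on gene-aligned vectors (union of genes, zeros
  imputed for genes unobserved on one side — they were screened and not
  mutated, not missing), with an `exclude` set for removing dominant genes.
- **Mean comparison**: a two-sided F test on the variances (larger variance
  in the numerator) gates the t test: variance inequality at p < 0.05
  selects Welch's t with Welch–Satterthwaite df, otherwise the
  pooled-variance unpaired t. All legend-style components (F, dfn, dfd, its
  p; t, df, p; means ± SE; 95% CI of the difference) are reported together.

No multiple-testing adjustment is applied across cancers; the comparison
layer reports per-comparison statistics only.

## Caller concordance

Metrics act on deduplicated gene → patient-set maps per caller, over the
**union** gene universe (a gene missed entirely by one caller penalizes
concordance; using the intersection would hide exactly the disagreements of
interest). The multiway shared rate is |∩ gene lists| / |∪ gene lists|;
pairwise rates likewise per pair. The maximum-error rate is

    E = [Σ_g Σ_pairs |n_a(g) − n_b(g)|] / [n_pairs × Σ_g max_c n_c(g)]

with n_c(g) the number of patients caller c calls mutated in gene g. The
normalization (pairs × per-gene maxima) is this package's declared choice:
it makes E a scale-free fraction that is 0 exactly when all callers agree on
every per-gene patient count and ≤ 1 always. Other normalizations of the
same numerator are possible; reports emit the formula verbatim so the number
is never quoted without its definition.

## The synthetic-study generator

The generator is the test bed: it emulates the *structure* of a
multi-repository pan-cancer study, not the biology of mutagenesis.

- **Truth model**: per-site per-gene probabilities drawn from a two-part
  mixture — most genes from Beta(1.1, 30) (mean ≈ 3.5%), a small driver
  subset (always including the first gene, the TP53 analogue, plus ~8% of
  the rest) from Beta(2.5, 4) (mean ≈ 38%). This reproduces the qualitative
  shape real panels show: one dominant gene, a handful of mid-frequency
  drivers, a long low-frequency tail. Site incidence is lognormal
  (median ≈ 2×10⁴ cases/site); two extra sites by default receive incidence
  but no cohort, so Q-rescaling is always exercised.
- **Cohorts**: genes mutate independently per sample (Bernoulli); a mutated
  sample-gene pair carries 1 + Poisson(0.15) records, so accumulated rates
  strictly exceed prevalence in expectation by ~15%. Samples split evenly
  across configurable subtype cohorts per site, giving the subtype → site
  aggregation real work. Demographics: gender 50/50;
  smoking 30% smoker / 60% non-smoker / 10% unknown — plausible registry
  marginals, configurable in source.
- **Noise**: a configurable fraction (default 5%) of records are
  non-qualifying — silent/noncoding/SV/fusion classes on panel genes, or
  protein-altering classes on off-panel symbols — and a configurable
  fraction (default 5%) of qualifying records are emitted under a bundled
  synonym alias. Both are removed/recovered exactly by resolution +
  filtering, a round-trip property the tests assert record-for-record.
- **Caller call sets** are independent thinnings of a base cohort's records
  at per-caller drop rates.

What the generator does **not** emulate — and therefore what passing tests
do not certify about real data: realistic trinucleotide spectra or
signatures, gene–gene mutation correlation (real co-mutation and mutual
exclusivity violate the independence assumption), sequencing-depth or
panel-coverage artifacts, inter-repository batch effects beyond literal
duplicates, and copy-number/SV biology beyond the noise tokens.

## Problem sizes used in the checked runs

The test suite and the acceptance script regenerate everything from scratch:
the end-to-end study uses 60 genes × 12 sequenced sites (+2 incidence-only)
at 300 samples/site; parameter recovery uses 40 genes × 6 sites at 2,000
samples/site; CI coverage uses 500 regenerated 6-gene × 3-site datasets with
2,000 bootstrap replicates each. These sizes give binomial sampling errors
small enough for 3-SD recovery bounds and stable coverage estimates while a
full run stays in the seconds-to-minutes range.

## Known limitations

- Weighted proportions inherit every bias of the input cohorts (panel
  composition, tumor purity, caller choice); the weighting corrects the
  sampling frame across cancers, nothing within a cancer.
- The Poisson bootstrap is mildly conservative at high per-site rates
  (variance N·p vs binomial N·p(1 − p)).
- The TP53-pattern delta rule is a formalization of a qualitative
  published classification; borderline cohorts can flip label with delta.
- Synonym resolution is only as good as the alias table; the bundled table
  is a small curated default meant to be replaced by a project-specific one.
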