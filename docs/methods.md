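# Methods

## Analysis model

The pipeline treats a sequencing library as a multinomial draw from a pool
of amplifiable 16S templates: the specimen's bacteria, a spike-in plasmid
added at `spike_copies_added` copies to a `homogenate_proportion` fraction
of the homogenate, reagent-derived contaminant templates, and non-target
templates (chloroplast, mitochondrial, archaeal, chimeric). Under the
assumption of no amplification bias between template types, read counts are
proportional to template copies within a library, which gives the absolute
abundance estimator

    copies_per_insect = (bacterial_reads / spike_reads)
                        × spike_copies_added / homogenate_proportion,

with `bacterial_reads` restricted to symbiont-class genotypes. The
estimator is linear in the bacterial counts, inversely proportional to the
spike counts, and invariant to rescaling a whole library — the properties
the test suite asserts. It is undefined when `spike_reads = 0`; such
samples are refused for quantification but kept for compositional analyses.
Spike parameters live in the per-sample metadata, never as constants: a
sample with missing parameters is refused rather than defaulted, because
the nominal 10,000 copies / 20% held only for most samples in the kind of
experiment emulated here.

## Contaminant classification

For each genotype the evidence statistic is

    ratio = max over blanks of relative abundance
          / max over experimental samples of relative abundance,

with relative abundance computed against the *bacterial* library size
(after spike and non-target removal, so the spike-dominated blanks cannot
distort denominators). The genotype is a contaminant when `ratio ≥
threshold` (default 1.0), including the infinite-ratio case of blank-only
genotypes; a genotype absent from all blanks has ratio 0 and is kept. The
max/max aggregation and the threshold are configurable (`aggregation=
"mean"`, `scope="per_blank_type"` which fires if any single blank type
does), and every call is recorded with its two maxima, the ratio, and the
rule that fired.

Why max-over-blanks vs max-over-samples: a true symbiont reaches high
relative abundance in at least one host specimen, while reagent
contamination is bounded by its share of the (contaminant-only) blank
profile; a genotype at least as prominent in a blank as in its *best*
sample has no credible host association. The classification is monotone in
the threshold (raising it never adds contaminants) and in the blank set
(removing a blank can only move genotypes toward symbiont) — both asserted
exactly in tests.

Degenerate inputs: blanks with zero bacterial reads are ignored in the
maxima (0/0 carries no evidence) with a warning; if *no* blank has
bacterial reads, no genotype can be called a contaminant (warned); absence
of blank samples altogether is an error, since the design requires negative
controls per laboratory step.

## Abundance statistics

* Global model on log₁₀ copies: `two_way_fixed` fits treatment + line as
  fixed factors by OLS and reports the treatment F from Type II sums of
  squares without an interaction (an interaction is refused with a warning
  when any line×arm cell has a single sample); `mixed_random_species` fits
  a random line intercept (REML) and reports the Wald test of the treatment
  coefficient. Both are exposed because either parameterization is
  defensible for this design; the fixed two-way variant is the default and
  the mixed fit is the sensitivity check. Log base 10 is fixed for
  reporting (the F statistic is base-invariant). With a single line the
  fixed model reduces to one-way ANOVA, whose F equals the squared pooled
  t statistic (asserted).
* Per-group tests: tie-corrected Kruskal–Wallis per host line (species ×
  culture line — the grouping unit for all per-group comparisons) and per
  body-size class (five bins). Groups with fewer than two samples or a
  single treatment arm are skipped with a logged reason. All-tied data make
  H a 0/0; the policy is H = 0, p = 1 with a tie note. Effect direction is
  the sign of (median control − median treated).
* Fold changes: per line, the ratio of geometric means between arms; the
  grand summary is the geometric mean of per-line folds with a t-interval
  on log₁₀ folds across lines. Because "average fold" is ambiguous, the
  median-based per-line fold and the back-transformed model coefficient are
  also emitted; the geometric-mean summary is the documented default and
  none is asserted to be what any particular study computed.
* Significance stars: * <0.05, ** <0.01, *** <0.001; α = 0.05 throughout.

## Composition statistics

* Rarefaction depth is chosen per line as the largest depth retaining at
  least `min_sample_fraction` (default 0.8) of that line's samples,
  balancing samples kept against reads (and expected features, reported via
  the hypergeometric survival probability) kept. Rarefaction is a single
  multivariate-hypergeometric draw per sample — without replacement, not
  averaged over repeated draws — with the seed recorded. Only alpha/beta
  diversity uses rarefied tables; abundance and genus summaries use the
  original counts to avoid added stochastic bias.
* Shannon entropy uses log base 2 (bits) by default, configurable.
* Bray–Curtis is Σ|x−y|/Σ(x+y) over genotypes (scipy's implementation);
  zero-total samples are a named error.
* PCoA is the eigendecomposition of the Gower-centered −½D² matrix. Axes
  with eigenvalues above `1e-10·max|λ|` are reported; proportions explained
  are over positive eigenvalues only; negative eigenvalues (non-Euclidean
  input) are counted and reported, never corrected.
* PERMANOVA computes the pseudo-F from total and within-group sums of
  squared distances; p = (hits + 1)/(permutations + 1) under uniformly
  random relabelings, with ties counted as ≥ observed (conservative, with a
  1e-12 slack against float jitter). `mode="exhaustive"` enumerates every
  distinct assignment of the label multiset and returns the exact fraction
  (e.g., all 20 relabelings of a 3+3 design); tests verify it against an
  independent brute-force enumerator and the sampled statistic against
  scikit-bio. Labels are permuted freely within each per-line analysis: no
  strata are needed because each line is analyzed separately.
* PERMDISP measures each sample's distance to its group centroid in the
  full principal-coordinate space, subtracting imaginary-axis contributions
  in the squared terms and clipping at zero, then takes a one-way ANOVA F
  on those distances; the permutation p relabels the computed distances
  (centroids are not recomputed per permutation, the standard
  dispersion-residual permutation). On Euclidean inputs the centroid
  distances equal distances to group means of the original points
  (asserted to 1e-8).
* Genus summaries sum counts by genus (missing genus → `unclassified`
  before thresholding); genera with mean relative abundance below the
  threshold are pooled into an always-present `other` bin — 5% for
  stacked-bar composition data, 1% for the between-arm shift table.

## Synthetic-data generator

The generator emulates the design of a multi-species insect microbiome
experiment with a treatment expected to depleted amplifiable template:

| parameter | default | rationale |
|---|---|---|
| `n_lines` | 19 | host lines; the first three species contribute two culture lines each (19 lines of 16 species) |
| `samples_per_arm` | 8–12 | the targeted per-arm sampling in such collections |
| depth | log-normal, ln-mean 9.0, ln-sd 1.1, bounded [55, 93 394] | spans the observed per-library read range of the emulated study without reproducing it exactly |
| `spike_copies` / `homogenate_proportion` | 10 000 / 0.2 | the nominal spike-in protocol |
| `treatment_fold` | 15 | the template reduction the treatment is expected to cause |
| `within_line_sd` | 0.3 log₁₀ | moderate biological variation among conspecific specimens from one culture |
| `line_log10_mean_range` | 5.0–8.0 | line mean copies per insect, from sparse microbiota to dense endosymbionts |
| community | 1 dominant symbiont (50–95% share) + 12 commensals, Dirichlet concentration 50 | species-specific dominant symbionts with moderate compositional overdispersion; the true overdispersion of real amplicon counts is unknown, so this is a documented assumption |
| `n_contaminants` / `contaminant_template` | 15 / 500 copies per library | a constant reagent pool — constant per library, not per insect, which reproduces the qualitative observation that contamination becomes more prominent when biological template drops |
| blanks | 6 extraction / 7 PCR1 / 3 PCR2 | one negative control set per laboratory step and batch |

Extraction blanks contain contaminant + spike template (the spike is added
at extraction); PCR blanks contain contaminant template only (a toggle adds
spike there, since real blank composition varies by protocol). The
contaminant profile is drawn once per experiment and held fixed across
libraries — same reagent lots — so blank and sample shares differ only by
multinomial noise and by dilution with biological template.

What the generator does **not** emulate: sequencing error and chimera
formation, PCR-cycle stochasticity, index cross-talk between libraries,
cross-contamination of genuine symbionts into blanks, 16S copy-number
variation per genome, or amplification-efficiency bias. Passing tests
therefore demonstrate internal consistency and estimator calibration under
the stated model, not robustness to those real-data artifacts; in
particular the near-perfect contaminant recall reflects the clean
separation the generating model implies, and real blank-vs-sample evidence
is messier.

## Test problem sizes

Desk-scale checks use exact closed forms (Kruskal–Wallis H = 27/7 on
{1,2,3} vs {4,5,6}; Shannon of a uniform 4-vector = 2 bits; Bray–Curtis of
[6,2] vs [2,2] = 1/3; PCoA recovery of planted 2-D geometry to 1e-8).
Calibration and recovery studies are sized to give stable Monte-Carlo
answers quickly: the null-calibration study runs 1,000 replicate
single-line experiments at 10 samples per arm (where the chi-square
approximation to the Kruskal–Wallis null is accurate) with 199-permutation
PERMANOVA, asserting both rejection rates within three binomial standard
errors of 5%; fold-change recovery uses 10 lines × 10 samples per arm; the
rarefaction expectation is checked against the hypergeometric mean over
10,000 seeded draws; classifier truth recovery runs at the full default
design (19 lines).

## Known limitations

* The blank-ratio rule is one defensible operationalization of
  "ratios of each genotype in blank and experimental libraries"; published
  studies using in-house rules may make different genotype-level calls, so
  genotype-by-genotype agreement with any specific dataset is not claimed.
* The max statistic is sensitive to very shallow libraries (a single read
  in a tiny library is a large relative abundance); the mean aggregation is
  provided for such regimes.
* PERMDISP permutes dispersion residuals rather than recomputing centroids
  per relabeling; the two variants can differ slightly for very unbalanced
  groups.
* Quantification inherits the no-amplification-bias assumption; no
  correction for per-genome 16S copy number is attempted.
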