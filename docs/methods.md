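# Methods

## The quantity of interest

For a cohort of tumour samples with somatic mutation calls, define for
each sample *i* and gene *g* the count *c(i, g)* of distinct passing
mutations (distinct by chromosome, position and alleles; exact
duplicates from merged caller outputs are collapsed). A gene is labelled
`multiple` in a sample when *c ≥ 2*, `single` when *c = 1*. A sample is
an **MM tumour** when at least one gene is `multiple`, an **SM tumour**
when it is mutated but no gene reaches 2, and `no_mutation` otherwise.
Everything else in the package conditions on these labels: per-gene
wild/single/multiple breakdowns and the MM fraction of mutated samples
*n_multiple / (n_single + n_multiple)*, oncogene/TSG stratification,
functional-impact composition of SM- versus MM-mutations, TMB and
signature context, allelic configuration of MM pairs, and survival.

MM counting includes all passing coding mutations regardless of impact
level (synonymous included): impact composition is an *output* of the
analysis, so the counting rule must not precondition on it.

## Variant filter

A call is discarded iff it fails at least one of six criteria
(thresholds are configuration, defaults in parentheses): quality score
below 60; depth below 20; variant reads on one strand only (fail iff
`alt_fwd == 0 or alt_rev == 0` — the literal reading of the rule); mean
clipped read length below 100 bases; mean relative position of the
variant within its reads below 0.05; membership in a user-supplied
site blacklist (empty by default — in-house false-positive lists are
lab-specific and not portable). All thresholds compare with `<`, so the
boundary values 60 / 20 / 100 / 0.05 pass. QC fields absent from a
source format (public MAFs are typically pre-filtered upstream) are
stored as unknown and treated as passing, with a logged warning. The
filter is a pure partition of its input — kept plus discarded equals
input, order preserved — and therefore idempotent; the discard log
records *every* failed criterion per call, not only the first.

## Phasing decision rule

Evidence is counted at fragment level: rows sharing a `read_id` are one
fragment, matching amplicon and paired-end semantics where both mates
sample the same molecule. Among fragments covering both sites of a pair
(fragments showing a third allele at either site are ignored):

- **cis** if `n_both_alt >= 2` and `n_both_alt > n_exclusive`;
- **trans** if `n_exclusive >= 2` and `n_exclusive > n_both_alt`;
- **undetermined** otherwise, and always when co-coverage is below
  `min_cocover` (default 2).

The two-fragment majority means no single chimeric or error-bearing
read can decide a configuration. The cohort cis fraction for a gene is
cis / (cis + trans) over determinable pairs; with no determinable pair
it is undefined rather than zero.

## Signature refitting

Single-nucleotide variants are catalogued over the 96 trinucleotide
contexts (pyrimidine convention; purine-reference calls are
reverse-complemented, flanks swapped and complemented). Exposures are
fitted to a fixed 96 × K signature matrix by greedy forward selection
on the normalised catalog *t*: at each step, for each signature *j*,
the 1-D problem min ||t − Σ w_k s_k||² over *w_j* (others fixed,
*w_j ≥ 0*, total weight ≤ 1) is solved in closed form — the objective
is an exact quadratic in *w_j*, so the update is the clamped analytic
minimiser rather than a numeric line search; this keeps the procedure
deterministic and lets a noiseless single-signature catalog recover
weight 1.0 to machine precision. Iteration stops when the best single
update improves the SSE by less than a factor 1e-3 of the current SSE
(a relative criterion: on the normalised 96-bin scale total SSE is
itself of order 1e-3, so an absolute threshold would stop after one
signature). After convergence, weights below the reporting cutoff
(0.06) are zeroed and the survivors renormalised to the pre-cutoff
total. Samples with fewer than 50 catalogued mutations are flagged
low-confidence. The residual never increases across iterations.

The bundled matrix (`synthetic_signature_matrix`) is a deterministic
synthetic stand-in for the reference signature catalogue, which is
distributed separately and not redistributable here: 28 smooth Dirichlet
profiles plus two hand-shaped columns — `Signature.1` concentrating C>T
at NpCpG (deamination-like) and `Signature.16` concentrating T>C at
ApTpN (the liver-cancer-associated shape). Recovery properties of the
refit do not depend on the exact reference profiles; users with the
licensed catalogue can pass it as a TSV.

## Tumour mutation burden

TMB = passing mutation count / target size in Mb; the default target is
a 45 Mb exome. Dichotomisation into hyper/hypo uses `tmb >= cutoff`,
either at a fixed per-Mb value (default 6.65) or at a cohort percentile
(default 95). Both modes exist because published hypermutation cutoffs
are variously stated as absolute burdens or cohort percentiles and the
two disagree whenever the cohort's shape differs from the one the
absolute value was derived on; the run manifest records which mode and
value were used.

## Survival and group statistics

Kaplan–Meier estimation uses the product-limit estimator (lifelines);
the median is the first observed time with S(t) ≤ 0.5, undefined if the
curve never crosses. The log-rank test is the standard
observed-minus-expected quadratic form with k−1 degrees of freedom
(lifelines). Cox proportional-hazards models are fitted by
partial-likelihood maximisation through statsmodels `PHReg`, chosen
because it offers both Efron (default; better with heavy ties) and
Breslow tie handling; confidence intervals are 95% Wald intervals on
the log-hazard scale, and constant covariates are rejected before
fitting. Group comparisons: Mann–Whitney (exact null when both groups
have ≤ 20 untied observations, tie-corrected normal approximation
otherwise), χ² without continuity correction, Fisher's exact test on
2×2 tables, one-way ANOVA; all tests two-sided; Bonferroni adjustment
multiplies by the comparison count and caps at 1. Tumour markers AFP
and PIVKA-II are stored on their natural scales and log10-transformed
only at comparison time. Conventional clinical dichotomisation cutoffs
are exposed as configuration: ICG-R15 20%, AFP 200 ng/mL, PIVKA-II
100 mAU/mL, tumour size 30 mm, age 70.

In report tables, univariate Cox rows are fitted per covariate and the
multivariate model over all estimable covariates; a covariate whose fit
is singular (e.g. a rare exposure in a small cohort) is skipped with a
warning rather than aborting the run.

## Synthetic cohort generator

The generator's defaults are the study conditions the analysis is
designed for; they were fixed from cohort-level anchors, not tuned to
test outcomes.

- **Mutation totals.** Per-sample totals are log-normal
  (median 100, σ = 0.65), giving a heavy right tail whose 95th
  percentile lands near 6.5 mutations/Mb on a 45 Mb exome — the
  hypermutation-cutoff regime.
- **Gene allocation.** Totals are allocated multinomially over a
  20-gene panel plus 3200 uniform background genes. The background size
  follows a birthday-collision calculation: with median *N* = 100
  mutations over *B* genes, P(some gene gets ≥ 2) ≈ 1 − exp(−N(N−1)/2B),
  and *B* ≈ 3200 puts cohort MM prevalence near the observed ~80%.
- **Panel genes.** Each has a length, an allocation rate, a hotspot
  concentration (probability a mutation falls in a short exon-3-like
  window) and an MM enrichment factor: once a gene is hit, further hits
  arrive with the enriched per-event probability over the remaining
  draws, so enrichment 1 reduces exactly to the neutral binomial
  allocation (this is what the closed-form conditional-binomial test
  checks). Two named presets: a short hotspot-concentrated
  beta-catenin-like gene (2.4 kb, 80% hotspot) and a long dispersed
  mucin-like gene (43 kb). Default enrichment is a mild 1.2 — the heavy
  tail of mutation totals already produces most within-gene recurrence,
  and stronger values push gene-level MM fractions far above the
  15–30% regime observed in real cohorts.
- **Genome and substitution types.** Every gene occupies its own
  synthetic contig, drawn before any mutation. Substitution types are
  then sampled *conditionally on the genome*: at each drawn site the
  three possible alternate alleles are weighted by a fixed signature
  mixture (default 0.5/0.3/0.2 over the liver-like, deamination-like
  and one flat profile) evaluated at the site's trinucleotide context.
  This keeps emitted MAF, FASTA and context labels mutually consistent
  at the cost of the realised context spectrum being the genome's
  triplet composition reweighted by the mixture, not the mixture
  itself. Within a sample and gene, positions are kept ≥ 3 bp apart so
  contexts never overlap.
- **Phase and reads.** Each additional mutation in a gene joins the
  first mutation's allele with probability 0.83 (cis); pairs are cis
  iff co-allelic, so samples with ≥ 3 hits mechanically produce some
  trans pairs even at high cis probability, and the realised pair-level
  cis fraction sits slightly below the per-decision value. Fragment
  evidence per pair: variant allele fraction 0.5, configurable depth
  (40), co-coverage (0.9) and per-base error (0). Evidence is emitted
  for panel genes; evidence for different pairs is generated
  independently (no sample-level haplotype consistency across ≥ 3-hit
  genes).
- **Survival.** Relapse hazard is exponential:
  h_i = h_0 · 1.72^MM(i) · exp(β·z_i), with baseline h_0 = 0.02/month
  (median ~35 months for non-MM tumours), a microvascular-invasion
  effect of log 1.96 by default, independent exponential censoring
  (0.008/month) capped at 120 months of follow-up. Clinical covariates
  are drawn from distributions matching published hepatectomy-cohort
  tables (82% male, age ~N(70, 8), HCV/HBV/none 31/19/50%, log-normal
  AFP and PIVKA-II, 33% microvascular invasion).
- **Expression.** Per focus gene, tumour/normal fold change is
  log2-normal (σ = 0.5) with an additive log2 shift (default +1) for
  MM carriers of that gene.
- **Reproducibility.** One integer seed; each component draws from a
  named child stream (spawn keys off the seed), so outputs are
  byte-identical across reruns and components can be regenerated
  independently.

**What passing tests do and do not show.** The generator produces the
statistical couplings the analysis assumes — it does not simulate
alignment artifacts, subclonal structure, copy number, indels (all
emitted mutations are SNVs; the frameshift/in-frame impact classes are
exercised through hand-built fixtures instead), strand-asymmetric
error, or the correlation between MM status and impact composition.
Tests passing on synthetic cohorts therefore demonstrate that the
implementation recovers known structure, not that real cohorts satisfy
the model.

## Numerical and degenerate-input conventions

Coordinates are 1-based fully closed throughout (VCF/MAF convention).
MNVs and complex indels are kept as single calls, never decomposed, so
they cannot inflate MM counts. Undefined ratios (MM fraction of a
never-mutated gene, cis fraction with no determinable pair, impact
fractions of an empty group) are reported as undefined/NaN and flagged,
never coerced to 0. Pairwise expression comparisons involving a class
with fewer than two samples are returned untestable rather than
producing a meaningless p-value. Gene identity is by symbol only; no
transcript resolution.

## Problem sizes

Default verification scales: 223-sample cohorts for end-to-end runs;
200 fuzzed variant sets for the filter oracle; 200 random cohorts for
the classification oracle; 500 replicates at depth 50 and 5% error for
noisy phasing; 50 refits of 2000-mutation catalogs for signature
recovery; 2000 null simulations for log-rank calibration and 100
replicates of n = 1000 cohorts for Cox recovery of the generating
hazard ratio 1.72.
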