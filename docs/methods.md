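# Methods

## Mutation categories and the classification table

Every MAF variant-classification string is mapped to one of five
categories (non-silent, synonymous, intron, UTR, flank) through a single
configurable table (`cohort_io.DEFAULT_CATEGORY_MAP`).  Two choices in
that table deserve a note:

- `Splice_Site` is treated as **non-silent** (it is annotated on coding
  sequence and disrupts the protein), while `Splice_Region` — a
  near-junction intronic call — is treated as **intron**.
- `RNA`, `IGR`, `Targeted_Region` and any unrecognised string are excluded
  outright rather than forced into a category; exclusions are counted, not
  silently dropped.

Patient identity is the first 12 characters of a TCGA-style barcode when
one is present; other identifiers pass through opaquely.  Patients are
retained only if they appear in both the genomic and the clinical table
with exactly one genomic sample; the filter is total and idempotent, and
each exclusion reason is reported.

High-resolution feature identifiers serialize as
`start-end-chrom-classification-type-ref-a1-a2` with empty alleles as
empty segments, so an insertion renders with consecutive dashes
(`...-Frame_Shift_Ins-INS---G`).  `decode_feature_id` is the exact inverse
on everything `encode_feature_id` emits.

## Feature engineering

Coordinates are 1-based inclusive (MAF convention) throughout; conversion
happens once at read time and nowhere else.

- **Low resolution** counts a patient's mutations of a category per gene.
- **Medium resolution** tiles the *genomic span* of the gene body
  (flanks excluded) with 50-nt segments anchored at the body's lowest
  coordinate, regardless of strand; a mutation is assigned to the segment
  containing its start coordinate (multi-nucleotide variants are not split
  across segments).  Strand-aware or spliced-transcript tiling would need
  annotation beyond what a MAF provides, so genomic-span tiling was chosen
  as the variant reproducible from the mutation table alone.  Flank
  mutations get two per-gene features (5' and 3' side, by classification)
  instead of segments.  A mutation whose coordinate falls outside its
  gene's annotated span is clamped to the nearest terminal segment with a
  warning.
- **High resolution** features are binary per distinct mutation; two
  changes at one position with different alternate alleles are distinct.
  Features carried by a single patient cohort-wide are discarded; the
  threshold (default 2 carriers) is applied over the full cohort, not per
  cancer type, and is configurable.

Low-resolution flank counts pool both sides of the gene into one count
(the two-sided split lives at medium resolution).  By construction, the
segment counts of a (patient, gene, category) sum exactly to its
low-resolution count — this conservation is asserted in tests against an
independent nested-loop counting oracle.

Matrices are CSR-sparse with a sidecar metadata table keyed by feature id
(resolution, category, gene, segment, polymorphism type); persistence is
MatrixMarket + TSV, so everything stays plain text.

## Classification protocol

The learner is LightGBM with default hyperparameters, frozen explicitly
in `DEFAULT_LEARNER_PARAMS` together with single-threaded deterministic
execution; the boosted-tree family is specified, its settings are an
implementation choice kept in one visible place.  Class imbalance is left
unweighted.

Splits are stratified 0.7/0.3, repeated 10 times; repeat *i* is seeded
`base_seed + i`, so every model sharing a (cancer type, repeat) sees the
same patient partition and dataset comparisons are paired.  A degenerate
(single-class) training split is resampled with an incremented seed and
logged.  Metrics use the conventions: precision/recall fall back to 0 on
an empty denominator and F1 is 0 whenever P + R = 0.

The null baseline draws each test patient's label independently with the
training positive fraction *p*; E[P] = E[R] = *p*, so its expected F1 is
the class prevalence — this analytic value is what the calibration tests
check.

Feature importance is **gain**-based, averaged over the repeats; gain was
chosen over split counts for stability on sparse matrices, and ties are
broken lexicographically by feature id so rankings are reproducible.

The balanced protocol controls for category width: using only
high-resolution features, patients are split into two equal stratified
halves; a model on the first half ranks each category's features and the
top *K* are kept (*K* defaults to the size of the smallest category's
feature set); the five width-*K* datasets and their 5*K*-wide
concatenation are then evaluated on the second half under the usual
scheme.  Selection and evaluation halves are disjoint.

## Ranking analyses

Gene rankings drop zero-importance features, assign each remaining
feature to its gene preserving order, and keep the first occurrence per
gene (rank 0 = best).  Top-10 gene lists are the top-10 *features*
collapsed to genes — they may hold fewer than 10 genes and are not padded
back; list lengths are recorded.

Cross-model Spearman correlations restrict each pair to the intersection
of its gene lists (pairs with fewer than 3 shared genes are skipped and
logged) and average rho across cancer types; because averaging p-values
has no single convention, both the mean p and a Fisher-combined p are
reported.  For very short lists (n < 10) the p-value comes from a
permutation test rather than the large-sample approximation.  The
mutation-count correlation is reported with the sign convention that
positive rho means more-mutated genes rank better.

## Similarity, misclassification and burden

Jaccard similarity operates on binarized profiles (a patient's feature
set is the ids with value 1); the score of two empty profiles is defined
as 0 to avoid 0/0.  The pair protocol samples 100 patients per type
without replacement (5 repetitions, fresh seed per repetition = base +
index), averages all cross-group patient pairs per repetition and then
the repetitions; when a cohort is smaller than the sample size, the
sample shrinks to the cohort with a log message, and sampling the whole
cohort reproduces the exhaustive double loop exactly.  The
misclassification protocol samples 250 per type, 10 repetitions of a
stratified 0.7/0.3 split, with the same boosted-tree learner as the OVA
models for internal consistency.  Raw-count Jaccard is deliberately
unsupported: set sizes are only well defined after binarization.

Burden statistics: the relative F1 gain of the all-features model over
the non-silent model (percent), and the mean over patients of each
patient's relative mutational-burden gain (patients with zero non-silent
burden are excluded and counted).  Adding features that change nothing
yields 0 for both.  Their Pearson correlation across cancer types is
reported with r².

## Survival estimation

All cancer types are pooled; the model never sees the cancer type or any
clinical covariate.  Labels: deceased → (1, days to death), alive →
(0, days to last follow-up); exclusions are patients with no positive
follow-up time and deaths before day 20 (day 20 exactly is included —
the rule is a strict "less than").  Feature subset: all low-resolution
features plus the 5,000 most prevalent high-resolution features (carrier
count, ties broken by smaller feature id); medium resolution is excluded.

The forest is scikit-survival's `RandomSurvivalForest` (log-rank splits
on Kaplan–Meier estimates), 60 trees, maximum depth 32, under 5 repeated
0.7/0.3 splits *stratified by event status* (the stratification is our
choice; it protects small-event cohorts from event-free training splits).
A patient's curve is the average over the repetitions in which they were
held out; patients never held out have missing curves and drop out of
evaluation.  Forest predictions are step functions defined on the
training follow-up range, so grid times are clamped to that range before
evaluation.

Time-dependent AUC is the cumulative/dynamic estimator: at horizon *t*,
cases have an observed event by *t*, controls are still at risk beyond
*t*, censored-before-*t* patients are omitted, risk is 1 − S(t), and ties
count 0.5.  No inverse-probability-of-censoring weights are applied in
the default estimator — it is a plain comparable-pairs concordance that
an exhaustive enumeration reproduces exactly (asserted in tests); an
IPCW variant can be layered on via scikit-survival if needed.  The null
is covariate-independent random risk, a flat line at 0.5 in expectation;
a Kaplan–Meier-constant-risk null is equivalent under the tie rule.
Forest feature importance is permutation importance on held-out Harrell
concordance, averaged over repetitions.

## Synthetic cohorts: what they emulate, and what they do not

The generator emulates the *structure* of a pan-cancer whole-exome
cohort: per-gene region annotations (flank/UTR/exon/intron spans, one
gene per synthetic chromosome to avoid overlap bookkeeping), per-patient
Poisson background mutation counts per category with defaults following
the observed category imbalance (non-silent 8, intron 4, UTR 2,
synonymous 1.5, flank 0.75 per patient), an SNP-dominated polymorphism
mixture (90/6/4 SNP/DEL/INS), a fixed virtual reference base per genomic
position, planted cancer-type-specific signals (exact recurrent point
mutations, or gene-level count bursts with no recurrent position) at
configurable prevalence with recorded carriers, and survival times from
an exponential proportional-hazards model with administrative censoring
(exponential rather than Weibull baselines so closed-form checks are
available).

It does **not** emulate sequence context (no trinucleotide spectra or
mutational signatures), transcript structure beyond one isoform, linked
or subclonal mutations, or cohort-level confounders such as age and
treatment.  Passing recovery tests therefore show that the pipeline
detects the kinds of signal it claims to detect at the stated prevalences
and noise levels — not that any particular real cohort contains such
signal.

## Problem sizes in tests

Unit tests run on cohorts of 40–180 patients with compact gene models;
the end-to-end recovery checks use 3 types × 150 patients for
classification (signal prevalence 0.4, background 2 mutations per
category — at this size every planted-category model separates cleanly
from its null), a 4-type signature-overlap gradient with 100 patients per
type (Jaccard samples of 40, misclassification samples of 100) for the
similarity analysis, and n = 600 with a hazard ratio of 3 on a
30 %-prevalence feature (~40 % censoring) for survival.  These are
deliberate desk-scale reductions of the study design; the protocol
defaults (cohort threshold 200, samples of 100/250, 10/5 repetitions,
5,000 survival features) remain the package defaults.

## Known limitations

- Medium-resolution segments tile genomic, not spliced, coordinates.
- The misclassification model reuses the OVA learner rather than a
  bespoke two-class design.
- Survival curves average only over repetitions where a patient was held
  out, so with few repeats a small fraction of patients has no estimate.
- Gene rankings assume each feature maps to exactly one gene; overlapping
  genes would need a disambiguation rule the MAF does not provide.
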