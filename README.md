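# silentmut

Most somatic-mutation analyses in cancer genomics focus on non-silent
mutations — exonic variants that change the encoded protein.  Silent
mutations (synonymous coding changes, and variants in introns, UTRs and
flanking regions) can nonetheless perturb gene expression, and this package
quantifies how much predictive power they carry for two tasks: **cancer-type
classification** and **survival estimation**.

It is aimed at biostatisticians and computational biologists who want a
tested, reusable implementation of the full analysis pipeline, exercised
end-to-end on synthetic cohorts with planted, fully known signal.

## Method

1. **Category sorting.** Each MAF-style mutation call is sorted into exactly
   one of five categories by its variant classification: non-silent
   (missense, nonsense, frameshift, in-frame indel, splice-site,
   start/stop-affecting), synonymous (`Silent`), intron (incl.
   `Splice_Region`), UTR (5'/3') and flank (5'/3').  Anything else (RNA,
   IGR, ...) is excluded.
2. **Three feature resolutions per category.**
   - *low*: per-gene mutation counts;
   - *medium*: counts per 50-nt gene-body segment, plus two per-gene
     flanking-side counts;
   - *high*: one binary indicator per distinct mutation (position,
     classification, polymorphism type and alleles all distinguish
     features); mutations seen in a single patient are discarded.
   The five single-category datasets plus their union (the *all features*
   dataset) feed every downstream analysis.
3. **One-vs-all classification.** Per (cancer type, dataset), a
   gradient-boosted decision-tree ensemble (LightGBM) separates that type
   from the pooled rest under 10 stratified 0.7/0.3 splits, scored by
   accuracy, precision *P*, recall *R* and

   F1 = 2·P·R / (P + R),

   against a null that guesses labels with the training-set positive
   fraction (expected F1 = prevalence).
4. **Rankings.** Gain-based feature importances collapse to gene rankings
   (zero-importance features dropped, best feature per gene, rank 0 = most
   important), supporting top-k category/polymorphism enrichments, pairwise
   Spearman correlations between single-category models, top-10 gene
   membership matrices, and mutation-count-vs-rank correlation.
5. **Cohort similarity vs misclassification.** For each pair of types A, B:

   J_AB = mean over sampled patient pairs of |F_a ∩ F_b| / |F_a ∪ F_b|
   (binary profiles), and M_AB = (|AB| + |BA|) / total for a two-class
   model under repeated sampled splits; the Spearman correlation of J and M
   across pairs measures how much profile similarity drives
   misclassification.  Per cancer type the relative F1 gain of the
   all-features model over the non-silent model,
   (F1_all − F1_ns)/F1_ns·100, is correlated (Pearson) with the mean
   per-patient relative mutational-burden gain.
6. **Survival.** All types pooled, labels = (event, days since diagnosis)
   with patients lacking post-diagnosis follow-up or dying before day 20
   excluded; all low-resolution plus the 5,000 most prevalent
   high-resolution features feed a random survival forest (60 trees, depth
   32, log-rank splits; 5 repeated 0.7/0.3 splits); predicted curves are
   scored by cumulative/dynamic AUC at 100–4500 days against a
   covariate-free null (expected AUC 0.5).

A synthetic cohort generator plants cancer-type-specific signals (recurrent
point mutations and gene-level count bursts) at configurable prevalence
over Poisson background, and draws survival times from an exponential
proportional-hazards model, providing ground truth for recovery tests.

## Worked example

```python
from silentmut.pipeline import RunConfig, run_all

config = RunConfig(seed=1, n_types=3, patients_per_type=150,
                   output_dir="demo_out", min_cohort=100)
bundle = run_all(config)
print(bundle["metrics"][["cancer_type", "dataset", "f1", "null_f1"]]
      .query("dataset in ('non_silent', 'intron', 'all')"))
```

On the default synthetic cohort (three cancer types, planted non-silent and
intronic signals at prevalence 0.4) this prints, for example:

```
   cancer_type     dataset        f1   null_f1
0          T01  non_silent  0.563675  0.359264
2          T01      intron  0.625367  0.359264
5          T01         all  0.736191  0.359264
6          T02  non_silent  0.584322  0.359264
8          T02      intron  0.635856  0.359264
11         T02         all  0.745240  0.359264
12         T03  non_silent  0.567415  0.359264
14         T03      intron  0.598078  0.359264
17         T03         all  0.768446  0.359264
```

i.e. every model trained on a dataset containing a planted mutation
category clearly beats its null baseline (F1 ≈ prevalence of the positive
class), and combining silent with non-silent features scores highest —
the qualitative behaviour the pipeline is designed to measure.  The same
flow is available from the shell via `silentmut run-all --seed 1`.

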