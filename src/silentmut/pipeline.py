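"""End-to-end orchestration: preprocessing, classification, rankings,
similarity/burden and survival, from a single seeded configuration.

One master seed derives every stage seed, so an identical configuration
produces a byte-identical report bundle.  Outputs are plain TSV/JSON
tables with the seed and a configuration hash embedded.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cohort_io, feature_engineering as fe, importance_rankings as ir
from . import cohort_similarity as cs, ova_classification as ova, survival_estimation as se
from .cohort_io import MutationCategory
from .synthetic_cohort import (
    CohortConfig,
    GeneAnnotation,
    SignatureSpec,
    SurvivalSpec,
    gene_count_signal,
    make_annotation,
    point_signal,
    simulate_cohort,
    simulate_survival,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_all",
    "export_ranked_gene_lists",
    "demo_cohort",
    "stage_seed",
    "classification_schedule",
]

SINGLE_DATASETS = [c.value for c in MutationCategory]
ALL_DATASETS = SINGLE_DATASETS + ["all"]


def classification_schedule(
    included_types: Sequence[str],
    datasets: Sequence[str] = tuple(ALL_DATASETS),
) -> list[tuple[str, str]]:
    """One classifier run per (cancer type, dataset) combination."""
    return [(t, d) for t in included_types for d in datasets]


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Full-pipeline configuration; defaults mirror the study protocol."""

    output_dir: str = "silentmut_out"
    seed: int = 0
    min_cohort: int = 200
    n_repeats: int = 10
    test_fraction: float = 0.3
    jaccard_sample_size: int = 100
    jaccard_repetitions: int = 5
    misclass_sample_size: int = 250
    misclass_repetitions: int = 10
    rsf_trees: int = 60
    rsf_max_depth: int = 32
    rsf_repeats: int = 5
    n_high_res_survival: int = 5000
    min_carriers: int = 2
    learner_params: dict = field(default_factory=dict)

    # synthetic-cohort knobs (used when no external MAF/clinical is given)
    n_genes: int = 30
    patients_per_type: int = 150
    n_types: int = 3
    signal_prevalence: float = 0.4
    background_rate: float | None = None  # None -> generator defaults

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output path excluded)."""
        fields = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def demo_cohort(config: RunConfig):
    """Generate the default synthetic study cohort for ``run_all``.

    Each synthetic cancer type plants one recurrent non-silent point
    mutation and one intronic gene-level count signal (distinct genes per
    type) at the configured prevalence, on top of Poisson background.
    """
    ann_seed = stage_seed(config.seed, "annotation")
    annotation = make_annotation(config.n_genes, seed=ann_seed)
    signatures = []
    for t in range(config.n_types):
        ctype = f"T{t + 1:02d}"
        g_point = annotation[2 * t].gene_symbol
        g_count = annotation[2 * t + 1].gene_symbol
        signatures.append(
            SignatureSpec(
                cancer_type=ctype,
                signals=(
                    point_signal(f"{ctype}_ns_point", g_point, MutationCategory.NON_SILENT, config.signal_prevalence),
                    gene_count_signal(f"{ctype}_intron_count", g_count, MutationCategory.INTRON, config.signal_prevalence),
                ),
            )
        )
    cc = CohortConfig(
        patients_per_type=config.patients_per_type,
        seed=stage_seed(config.seed, "cohort"),
    )
    if config.background_rate is not None:
        cc.background_rates = {c: config.background_rate for c in MutationCategory}
    mutations, clinical, truth = simulate_cohort(annotation, signatures, cc)
    return annotation, mutations, clinical, truth


def _burdens(mutations, patients, categories) -> pd.Series:
    counts = {p: 0 for p in patients}
    for r in mutations:
        cat = cohort_io.categorize(r.variant_classification)
        if cat in categories and r.patient_id in counts:
            counts[r.patient_id] += 1
    return pd.Series(counts, name="burden")


def run_all(
    config: RunConfig,
    annotation: Sequence[GeneAnnotation] | None = None,
    mutations=None,
    clinical: pd.DataFrame | None = None,
    survival_spec: SurvivalSpec | None = None,
) -> dict:
    """Execute the full study flow and write the report bundle.

    Preprocessing -> per-(type, dataset) classification with nulls ->
    resolution ablation and balanced protocol -> ranking analyses ->
    pairwise similarity/misclassification and burden statistics ->
    survival branch.  Returns the in-memory bundle; writes TSV/JSON under
    ``config.output_dir``.
    """
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.config_hash()}

    if mutations is None:
        annotation, mutations, clinical, truth = demo_cohort(config)
    else:
        truth = pd.DataFrame()
        if annotation is None or clinical is None:
            raise ValueError("external mutations require annotation and clinical tables")

    mutations, clinical, filter_report = cohort_io.filter_patients(mutations, clinical)
    patients = sorted(clinical["patient_id"])

    logger.info("building feature matrices for %d patients", len(patients))
    datasets = fe.build_all_datasets(mutations, annotation, patients, min_carriers=config.min_carriers)

    # --- classification branch -------------------------------------------
    scheme = ova.SplitScheme(
        n_repeats=config.n_repeats,
        test_fraction=config.test_fraction,
        base_seed=stage_seed(config.seed, "classification"),
        learner_params=config.learner_params,
    )
    cancer_types = sorted(clinical["cancer_type"].unique())
    included_types = []
    metric_rows = []
    results: dict[tuple[str, str], ova.ModelResult] = {}
    nulls: dict[str, ova.ModelResult] = {}
    for ctype in cancer_types:
        labels = ova.make_ova_labels(clinical, ctype, patients, min_cohort=config.min_cohort)
        if labels is None:
            continue
        included_types.append(ctype)
        nulls[ctype] = ova.null_model(labels, scheme)
        for _, name in classification_schedule([ctype]):
            res = ova.train_ova(datasets[name], labels, scheme, cancer_type=ctype, dataset=name)
            results[(ctype, name)] = res
            m = res.mean_metrics
            metric_rows.append(
                {"cancer_type": ctype, "dataset": name, **m.as_dict(),
                 "null_f1": nulls[ctype].mean_metrics.f1, **stamp}
            )
    metrics_df = pd.DataFrame(metric_rows)
    metrics_df.to_csv(outdir / "classification_metrics.tsv", sep="\t", index=False)
    logger.info(
        "classification: %d runs scheduled", len(classification_schedule(included_types))
    )

    # --- rankings ---------------------------------------------------------
    all_rankings = {
        ctype: ir.make_feature_ranking(results[(ctype, "all")].importances, datasets["all"].meta)
        for ctype in included_types
    }
    single_rankings = {
        ctype: {
            name: ir.make_feature_ranking(results[(ctype, name)].importances, datasets[name].meta)
            for name in SINGLE_DATASETS
        }
        for ctype in included_types
    }
    gene_rankings = {
        ctype: {name: ir.derive_gene_ranking(r) for name, r in models.items()}
        for ctype, models in single_rankings.items()
    }
    bundle_rank = {}
    if included_types:
        type_dist = ir.topk_type_distribution(all_rankings, k=10)
        type_dist.to_csv(outdir / "topk_type_distribution.tsv", sep="\t")
        poly = ir.polymorphism_enrichment(all_rankings, k=10)
        poly.to_csv(outdir / "polymorphism_enrichment.tsv", sep="\t")
        cross = ir.cross_model_rank_correlation(gene_rankings)
        cross.to_csv(outdir / "cross_model_rank_correlation.tsv", sep="\t", index=False)
        membership = ir.top_gene_membership(single_rankings, k=10)
        membership.to_csv(outdir / "top_gene_membership.tsv", sep="\t")
        totals = _burdens_by_gene(mutations, patients)
        all_gene_rankings = {
            ctype: ir.derive_gene_ranking(all_rankings[ctype]) for ctype in included_types
        }
        count_corr = ir.mutation_count_rank_correlation(all_gene_rankings, totals)
        count_corr.to_csv(outdir / "mutation_count_rank_correlation.tsv", sep="\t", index=False)
        export_ranked_gene_lists(
            {ctype: {**gene_rankings[ctype], "all": all_gene_rankings[ctype]} for ctype in included_types},
            outdir / "ranked_gene_lists",
        )
        bundle_rank = {
            "type_distribution": type_dist,
            "polymorphism": poly,
            "cross_model": cross,
            "membership": membership,
            "count_correlation": count_corr,
        }

    # --- similarity / burden ---------------------------------------------
    pair_rows = []
    sim_summary = {}
    if len(included_types) >= 2:
        binary_all = datasets["all"].binarize()
        sim_seed = stage_seed(config.seed, "similarity")
        for a, b in itertools.combinations(included_types, 2):
            jres = cs.jaccard_pair_protocol(
                binary_all, clinical, a, b, seed=sim_seed,
                sample_size=config.jaccard_sample_size, n_repetitions=config.jaccard_repetitions,
            )
            mres = cs.misclassification_protocol(
                datasets["all"], clinical, a, b, seed=sim_seed,
                sample_size=config.misclass_sample_size,
                n_repetitions=config.misclass_repetitions,
                learner_params=config.learner_params,
            )
            pair_rows.append(
                {"type_a": a, "type_b": b, "jaccard": jres.jaccard,
                 "misclassification": mres.misclassification_rate, **stamp}
            )
        pairs_df = pd.DataFrame(pair_rows)
        pairs_df.to_csv(outdir / "similarity_pairs.tsv", sep="\t", index=False)
        if len(pair_rows) >= 3:
            rho, p = cs.similarity_vs_misclassification(pairs_df)
            sim_summary["jaccard_misclassification_spearman_rho"] = rho
            sim_summary["jaccard_misclassification_spearman_p"] = p

        imp_rows = []
        silent_cats = set(MutationCategory) - {MutationCategory.NON_SILENT}
        b_all = _burdens(mutations, patients, set(MutationCategory))
        b_ns = _burdens(mutations, patients, {MutationCategory.NON_SILENT})
        for ctype in included_types:
            f1_all = results[(ctype, "all")].mean_metrics.f1
            f1_ns = results[(ctype, "non_silent")].mean_metrics.f1
            pts = clinical.loc[clinical["cancer_type"] == ctype, "patient_id"]
            mb, n_excl = cs.mb_increase(b_all.loc[pts], b_ns.loc[pts])
            row = {"cancer_type": ctype, "f1_all": f1_all, "f1_non_silent": f1_ns,
                   "mb_increase": mb, "n_zero_burden_excluded": n_excl}
            row["f1_improvement"] = cs.f1_improvement(f1_all, f1_ns) if f1_ns > 0 else np.nan
            imp_rows.append(row)
        improvement_df = pd.DataFrame(imp_rows)
        improvement_df.to_csv(outdir / "f1_improvement.tsv", sep="\t", index=False)
        if len(improvement_df.dropna(subset=["f1_improvement"])) >= 3:
            r, p, r2 = cs.improvement_burden_correlation(
                improvement_df.dropna(subset=["f1_improvement"])
            )
            sim_summary.update(
                {"improvement_burden_pearson_r": r, "improvement_burden_pearson_p": p,
                 "improvement_burden_r2": r2}
            )
        with open(outdir / "similarity_summary.json", "w") as fh:
            json.dump({**sim_summary, **stamp}, fh, indent=2)

    # --- survival branch --------------------------------------------------
    survival_out = {}
    if survival_spec is not None:
        surv_seed = stage_seed(config.seed, "survival")
        feature_df = datasets["all"].binarize().to_dataframe()
        clin_surv = simulate_survival(clinical, feature_df, survival_spec)
        labels, label_report = se.build_survival_labels(clin_surv)
        subset = se.select_survival_features(datasets["all"], n_high=config.n_high_res_survival)
        rsf_cfg = se.RSFConfig(
            n_trees=config.rsf_trees, max_depth=config.rsf_max_depth,
            n_repeats=config.rsf_repeats, test_fraction=config.test_fraction, seed=surv_seed,
        )
        fit = se.fit_rsf(subset, labels, rsf_cfg)
        auc = se.time_dependent_auc(fit.curves, labels)
        null_auc = se.null_survival_auc(labels, seed=surv_seed)
        auc_df = pd.DataFrame({"rsf_auc": auc, "null_auc": null_auc})
        auc_df.to_csv(outdir / "survival_auc.tsv", sep="\t")
        survival_out = {"auc": auc_df, "label_report": label_report, "fit": fit}

    bundle = {
        "filter_report": filter_report,
        "datasets": datasets,
        "metrics": metrics_df,
        "results": results,
        "nulls": nulls,
        "rankings": bundle_rank,
        "pairs": pd.DataFrame(pair_rows),
        "similarity_summary": sim_summary,
        "survival": survival_out,
        "truth": truth,
        "included_types": included_types,
        "elapsed_s": time.time() - t0,
    }
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(
            {**stamp, "n_patients": len(patients), "included_types": included_types,
             "n_classification_runs": len(included_types) * len(ALL_DATASETS),
             "elapsed_s": bundle["elapsed_s"]},
            fh, indent=2,
        )
    return bundle


def _burdens_by_gene(mutations, patients) -> pd.Series:
    pset = set(patients)
    counts: dict[str, int] = {}
    for r in mutations:
        if r.patient_id in pset and cohort_io.categorize(r.variant_classification) is not None:
            counts[r.gene_symbol] = counts.get(r.gene_symbol, 0) + 1
    return pd.Series(counts, name="n_mutations")


def export_ranked_gene_lists(
    gene_rankings: Mapping[str, Mapping[str, pd.DataFrame]],
    outdir: str | Path,
) -> list[Path]:
    """One plain-text ranked gene list per (cancer type, model)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for ctype, models in gene_rankings.items():
        for model, ranking in models.items():
            path = outdir / f"{ctype}.{model}.rnk.txt"
            ir.export_ranked_gene_list(ranking, path)
            written.append(path)
    return written
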