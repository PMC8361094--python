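"""Gene rankings derived from feature importances, and ranking analyses.

A fitted model ranks its features by importance.  Dropping zero-importance
features, assigning each remaining feature to its gene while preserving
order, and keeping only each gene's best (first) occurrence yields a gene
ranking in which the most important gene has rank 0.  On top of these
rankings the module computes: the mutation-category make-up of the top-k
features and its enrichment over the whole dataset, polymorphism-type
(SNP/DEL/INS) enrichment among top features, pairwise Spearman correlation
of gene rankings between single-category models, top-10 gene membership
counts across cancer types, and the correlation between per-gene mutation
totals and gene rank.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "make_feature_ranking",
    "derive_gene_ranking",
    "topk_type_distribution",
    "polymorphism_enrichment",
    "cross_model_rank_correlation",
    "top_gene_membership",
    "mutation_count_rank_correlation",
    "export_ranked_gene_list",
]


def make_feature_ranking(importances: pd.Series, meta: pd.DataFrame) -> pd.DataFrame:
    """Join importances with feature metadata, sorted by descending importance.

    Ties are broken lexicographically by feature id so rankings are
    reproducible.  All features are retained here; zero-importance features
    are dropped later, at gene-ranking time.
    """
    df = meta.copy()
    df["importance"] = importances.reindex(meta.index).fillna(0.0)
    df = df.rename_axis("feature_id").reset_index()
    df = df.sort_values(["importance", "feature_id"], ascending=[False, True]).reset_index(drop=True)
    return df


def derive_gene_ranking(
    ranking: pd.DataFrame,
    feature_to_gene: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Collapse a feature ranking to a gene ranking.

    Zero-importance features are discarded; each remaining feature maps to
    exactly one gene; the first (best) occurrence per gene is kept, in
    order.  Rank 0 is the most important gene.
    """
    if feature_to_gene is None:
        if "gene_symbol" not in ranking.columns:
            raise ValueError("ranking lacks gene_symbol metadata and no mapping was given")
        genes = ranking["gene_symbol"]
    else:
        unmapped = [f for f in ranking["feature_id"] if f not in feature_to_gene]
        if unmapped:
            raise KeyError(f"features with no gene mapping: {unmapped[:5]}")
        genes = ranking["feature_id"].map(feature_to_gene)

    kept = ranking.loc[ranking["importance"] > 0].copy()
    kept["gene_symbol"] = genes.loc[kept.index]
    kept = kept.drop_duplicates(subset="gene_symbol", keep="first")
    out = kept[["gene_symbol"]].reset_index(drop=True)
    out["rank"] = np.arange(len(out))
    return out


def topk_type_distribution(
    rankings: Mapping[str, pd.DataFrame],
    k: int = 10,
) -> pd.DataFrame:
    """Category make-up of the top-k features, averaged across cancer types.

    For each cancer type's (all-features) ranking, the fraction of each
    mutation category among its top-k positive-importance features is
    computed and averaged.  Enrichment is that average divided by the
    category's share of the whole dataset (also averaged across types).
    Rankings shorter than k are used at their available length and flagged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    top_rows, all_rows = [], []
    for cancer_type, ranking in rankings.items():
        nonzero = ranking.loc[ranking["importance"] > 0]
        if len(nonzero) < k:
            logger.warning(
                "%s: ranking has only %d positive-importance features (< k=%d)",
                cancer_type,
                len(nonzero),
                k,
            )
        top = nonzero.head(k)
        top_rows.append(top["category"].value_counts(normalize=True))
        all_rows.append(ranking["category"].value_counts(normalize=True))
    top_frac = pd.DataFrame(top_rows).fillna(0.0).mean()
    all_frac = pd.DataFrame(all_rows).fillna(0.0).mean()
    out = pd.DataFrame({"top_fraction": top_frac, "dataset_fraction": all_frac}).fillna(0.0)
    out["enrichment"] = out["top_fraction"] / out["dataset_fraction"].replace(0.0, np.nan)
    return out.rename_axis("category")


def polymorphism_enrichment(
    rankings: Mapping[str, pd.DataFrame],
    k: int = 10,
) -> pd.DataFrame:
    """SNP/DEL/INS prevalence in the top-k versus the whole dataset.

    Only high-resolution features carry a polymorphism type, so both the
    numerator (top-k) and denominator (dataset) are restricted to them.  If
    no high-resolution feature reaches the top-k of any ranking the ratios
    are reported as missing.
    """
    top_rows, all_rows = [], []
    for cancer_type, ranking in rankings.items():
        high = ranking.loc[(ranking["resolution"] == "HIGH") & (ranking["variant_type"] != "")]
        if high.empty:
            continue
        top_high = ranking.loc[ranking["importance"] > 0].head(k)
        top_high = top_high.loc[(top_high["resolution"] == "HIGH") & (top_high["variant_type"] != "")]
        if not top_high.empty:
            top_rows.append(top_high["variant_type"].value_counts(normalize=True))
        all_rows.append(high["variant_type"].value_counts(normalize=True))
    if not top_rows:
        logger.warning("no high-resolution features in any top-%d list; enrichment undefined", k)
        return pd.DataFrame(columns=["top_fraction", "dataset_fraction", "enrichment"])
    top_frac = pd.DataFrame(top_rows).fillna(0.0).mean()
    all_frac = pd.DataFrame(all_rows).fillna(0.0).mean()
    out = pd.DataFrame({"top_fraction": top_frac, "dataset_fraction": all_frac}).fillna(0.0)
    out["enrichment"] = out["top_fraction"] / out["dataset_fraction"].replace(0.0, np.nan)
    return out.rename_axis("variant_type")


def _spearman(rank_a: np.ndarray, rank_b: np.ndarray, n_exact: int = 10) -> tuple[float, float]:
    """Spearman rho and p; exact permutation p for very short lists."""
    rho, p = stats.spearmanr(rank_a, rank_b)
    n = len(rank_a)
    if n < n_exact:
        res = stats.spearmanr(rank_a, rank_b)
        perm = stats.permutation_test(
            (rank_a,),
            lambda x: stats.spearmanr(x, rank_b).statistic,
            permutation_type="pairings",
            n_resamples=5000,
            random_state=0,
        )
        p = float(perm.pvalue)
        rho = float(res.statistic)
    return float(rho), float(p)


def cross_model_rank_correlation(
    rankings: Mapping[str, Mapping[str, pd.DataFrame]],
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Pairwise Spearman correlation of gene rankings, averaged across types.

    ``rankings[cancer_type][model]`` is a gene-ranking frame (the
    all-features model is excluded by construction: pass only the five
    single-category models).  For each cancer type and model pair, genes
    outside the intersection of the two lists are discarded and Spearman's
    rho is computed on the remaining ranks; rho and p are then averaged
    across cancer types (a Fisher-combined p is reported alongside).  Pairs
    with an intersection below ``min_overlap`` are skipped for that type.
    """
    pair_values: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for cancer_type, models in rankings.items():
        names = sorted(models)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                ra = models[a].set_index("gene_symbol")["rank"]
                rb = models[b].set_index("gene_symbol")["rank"]
                common = ra.index.intersection(rb.index)
                if len(common) < min_overlap:
                    logger.info(
                        "%s: %s vs %s intersection %d < %d, skipped",
                        cancer_type, a, b, len(common), min_overlap,
                    )
                    continue
                rho, p = _spearman(ra.loc[common].to_numpy(), rb.loc[common].to_numpy())
                pair_values.setdefault((a, b), []).append((rho, p))
    rows = []
    for (a, b), vals in sorted(pair_values.items()):
        rhos = np.array([v[0] for v in vals])
        ps = np.array([max(v[1], 1e-300) for v in vals])
        fisher_stat = -2 * np.log(ps).sum()
        fisher_p = float(stats.chi2.sf(fisher_stat, df=2 * len(ps)))
        rows.append(
            {
                "model_a": a,
                "model_b": b,
                "mean_rho": float(rhos.mean()),
                "mean_p": float(ps.mean()),
                "fisher_p": fisher_p,
                "n_cancer_types": len(vals),
            }
        )
    return pd.DataFrame(rows)


def top_gene_membership(
    feature_rankings: Mapping[str, Mapping[str, pd.DataFrame]],
    k: int = 10,
) -> pd.DataFrame:
    """Gene x model counts of appearances in per-type top-k gene lists.

    ``feature_rankings[cancer_type][model]`` is a feature-ranking frame from
    a single-category model.  The top-k gene list of each (type, model) is
    derived by collapsing the top-k positive-importance features to genes
    in order (it may hold fewer than k genes; no padding).  A cell counts
    the cancer types whose list contains the gene, bounded by the number of
    types.
    """
    counts: dict[str, dict[str, int]] = {}
    models_seen: set[str] = set()
    for cancer_type, models in feature_rankings.items():
        for model, ranking in models.items():
            models_seen.add(model)
            top_features = ranking.loc[ranking["importance"] > 0].head(k)
            top_genes = top_features["gene_symbol"].drop_duplicates()
            for gene in top_genes:
                counts.setdefault(gene, {})[model] = counts.setdefault(gene, {}).get(model, 0) + 1
    out = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    out = out.reindex(columns=sorted(models_seen), fill_value=0).sort_index()
    return out.rename_axis("gene_symbol")


def mutation_count_rank_correlation(
    gene_rankings: Mapping[str, pd.DataFrame],
    gene_mutation_totals: pd.Series,
) -> pd.DataFrame:
    """Spearman correlation between per-gene mutation totals and importance.

    Sign convention: a positive rho means more-mutated genes are more
    important.  Rank 0 is the most important gene, so rho is computed
    against the negated rank.  A cancer type with constant counts over its
    ranked genes yields a missing value.
    """
    rows = []
    for cancer_type, ranking in gene_rankings.items():
        genes = ranking["gene_symbol"]
        counts = gene_mutation_totals.reindex(genes)
        if counts.isna().any():
            missing = genes[counts.isna()].tolist()
            raise KeyError(f"{cancer_type}: no mutation total for gene(s) {missing[:5]}")
        if counts.nunique() < 2 or len(counts) < 3:
            rows.append({"cancer_type": cancer_type, "rho": np.nan, "p": np.nan})
            continue
        rho, p = stats.spearmanr(counts.to_numpy(), -ranking["rank"].to_numpy())
        rows.append({"cancer_type": cancer_type, "rho": float(rho), "p": float(p)})
    df = pd.DataFrame(rows)
    df.attrs["mean_rho"] = float(df["rho"].mean())
    return df


def export_ranked_gene_list(gene_ranking: pd.DataFrame, path) -> None:
    """One gene symbol per line in rank order (ranked-list format for
    external enrichment tools)."""
    with open(path, "w") as fh:
        for gene in gene_ranking["gene_symbol"]:
            fh.write(f"{gene}\n")
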