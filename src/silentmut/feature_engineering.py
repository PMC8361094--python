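"""Three-resolution feature matrices per mutation category.

For each of the five mutation categories a cohort is summarised at three
levels of resolution:

* low resolution — number of mutations of the category a patient carries
  anywhere in a gene (one count feature per mutated gene);
* medium resolution — number of mutations in each 50-nucleotide segment of
  the gene body, plus two per-gene features counting 5' and 3' flanking
  mutations;
* high resolution — one binary feature per distinct mutation (position,
  classification, polymorphism type and alleles all distinguish features);
  mutations seen in exactly one patient cohort-wide are discarded.

The five single-category datasets plus their union (the "all features"
dataset) are the inputs to every downstream analysis.  Matrices are held
sparse with a sidecar metadata table keyed by feature id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cohort_io import MutationCategory, MutationRecord, categorize, encode_feature_id
from .synthetic_cohort import GeneAnnotation, annotation_index

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "SEGMENT_LENGTH",
    "build_low_res",
    "build_medium_res",
    "build_high_res",
    "build_category_dataset",
    "build_all_datasets",
    "assemble_dataset",
    "binarize",
]

SEGMENT_LENGTH = 50

RESOLUTIONS = ("LOW", "MEDIUM", "HIGH")

META_COLUMNS = ["resolution", "category", "gene_symbol", "segment", "variant_type"]


@dataclass
class FeatureMatrix:
    """Patients x features with per-feature metadata.

    ``values`` is a CSR matrix of non-negative integers (binary for
    high-resolution columns).  ``meta`` is indexed by feature id and carries
    resolution, category, gene symbol, segment key (segment index or flank
    side for medium resolution) and variant type (high resolution only).
    """

    patients: list[str]
    values: sp.csr_matrix
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.patients), len(self.meta)):
            raise ValueError(
                f"shape {self.values.shape} != ({len(self.patients)}, {len(self.meta)})"
            )
        if self.meta.index.has_duplicates:
            dup = self.meta.index[self.meta.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dup[:5]}")

    # -- accessors ---------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.meta.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.toarray(), index=pd.Index(self.patients, name="patient_id"),
            columns=self.meta.index,
        )

    def column_sums(self) -> pd.Series:
        return pd.Series(np.asarray(self.values.sum(axis=0)).ravel(), index=self.meta.index)

    def carrier_counts(self) -> pd.Series:
        """Number of patients with a non-zero value per feature."""
        return pd.Series(
            np.asarray((self.values > 0).sum(axis=0)).ravel(), index=self.meta.index
        )

    # -- transforms --------------------------------------------------------
    def select_features(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        idx = self.meta.index.get_indexer(feature_ids)
        if (idx < 0).any():
            missing = [f for f, i in zip(feature_ids, idx) if i < 0]
            raise KeyError(f"unknown feature id(s): {missing[:5]}")
        return FeatureMatrix(
            patients=list(self.patients),
            values=self.values[:, idx],
            meta=self.meta.iloc[idx].copy(),
        )

    def select_patients(self, patients: Sequence[str]) -> "FeatureMatrix":
        pos = {p: i for i, p in enumerate(self.patients)}
        idx = [pos[p] for p in patients]
        return FeatureMatrix(
            patients=list(patients), values=self.values[idx, :], meta=self.meta.copy()
        )

    def binarize(self) -> "FeatureMatrix":
        return binarize(self)

    # -- persistence (MTX + TSV sidecars) ----------------------------------
    def save(self, directory: str | Path, stem: str = "features") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        from scipy.io import mmwrite

        mmwrite(directory / f"{stem}.mtx", self.values.tocoo())
        self.meta.rename_axis("feature_id").to_csv(directory / f"{stem}.meta.tsv", sep="\t")
        pd.Series(self.patients, name="patient_id").to_csv(
            directory / f"{stem}.patients.tsv", sep="\t", index=False
        )

    @classmethod
    def load(cls, directory: str | Path, stem: str = "features") -> "FeatureMatrix":
        directory = Path(directory)
        from scipy.io import mmread

        values = sp.csr_matrix(mmread(directory / f"{stem}.mtx"))
        meta = pd.read_csv(directory / f"{stem}.meta.tsv", sep="\t", index_col="feature_id")
        patients = pd.read_csv(directory / f"{stem}.patients.tsv", sep="\t")["patient_id"].tolist()
        return cls(patients=patients, values=values, meta=meta)


def _matrix_from_counts(
    patients: Sequence[str],
    counts: Mapping[tuple[str, str], int],
    meta_rows: Mapping[str, dict],
) -> FeatureMatrix:
    """Assemble a FeatureMatrix from {(patient, feature_id): count}."""
    feature_ids = sorted(meta_rows)
    prow = {p: i for i, p in enumerate(patients)}
    fcol = {f: j for j, f in enumerate(feature_ids)}
    rows, cols, data = [], [], []
    for (p, f), v in counts.items():
        rows.append(prow[p])
        cols.append(fcol[f])
        data.append(v)
    values = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(patients), len(feature_ids)), dtype=np.int64
    )
    meta = pd.DataFrame(
        [meta_rows[f] for f in feature_ids],
        index=pd.Index(feature_ids, name="feature_id"),
        columns=META_COLUMNS,
    )
    return FeatureMatrix(patients=list(patients), values=values, meta=meta)


def _categorized(mutations: Iterable[MutationRecord], category: MutationCategory):
    for r in mutations:
        if categorize(r.variant_classification) is category:
            yield r


def build_low_res(
    mutations: Sequence[MutationRecord],
    category: MutationCategory,
    patients: Sequence[str],
) -> FeatureMatrix:
    """Per-gene mutation counts: one feature per gene with >=1 cohort mutation."""
    counts: dict[tuple[str, str], int] = {}
    meta: dict[str, dict] = {}
    pset = _as_set(patients)
    for r in _categorized(mutations, category):
        if r.patient_id not in pset:
            continue
        fid = f"{r.gene_symbol}|{category.name}|LOW"
        counts[(r.patient_id, fid)] = counts.get((r.patient_id, fid), 0) + 1
        meta[fid] = {
            "resolution": "LOW",
            "category": category.name,
            "gene_symbol": r.gene_symbol,
            "segment": "",
            "variant_type": "",
        }
    return _matrix_from_counts(patients, counts, meta)


def _as_set(patients: Sequence[str]) -> frozenset:
    return frozenset(patients)


def segment_index(position: int, body_start: int) -> int:
    """50-nt segment index of a position, anchored at the gene body start."""
    return (position - body_start) // SEGMENT_LENGTH


def build_medium_res(
    mutations: Sequence[MutationRecord],
    annotation: Sequence[GeneAnnotation] | Mapping[str, GeneAnnotation],
    category: MutationCategory,
    patients: Sequence[str],
) -> FeatureMatrix:
    """50-nt segment counts (non-flank categories) or per-side flank counts.

    Segments tile the genomic span of the gene body from its lowest
    coordinate, regardless of strand; a mutation is assigned by its start
    coordinate.  Mutations outside the annotated gene span are clamped to
    the nearest terminal segment with a warning.  For the flank category the
    two features per gene count mutations by their 5'Flank/3'Flank
    classification instead of by segment.
    """
    genes = annotation if isinstance(annotation, Mapping) else annotation_index(annotation)
    counts: dict[tuple[str, str], int] = {}
    meta: dict[str, dict] = {}
    pset = _as_set(patients)
    n_clamped = 0
    for r in _categorized(mutations, category):
        if r.patient_id not in pset:
            continue
        if r.gene_symbol not in genes:
            raise KeyError(f"mutated gene {r.gene_symbol} absent from annotation")
        gene = genes[r.gene_symbol]
        if category is MutationCategory.FLANK:
            side = "5p" if r.variant_classification == "5'Flank" else "3p"
            fid = f"{r.gene_symbol}|FLANK|{side}"
            seg_key = side
        else:
            body_start, body_end = gene.body_start, gene.body_end
            pos = r.start
            if pos < body_start or pos > body_end:
                n_clamped += 1
                pos = min(max(pos, body_start), body_end)
            k = segment_index(pos, body_start)
            fid = f"{r.gene_symbol}|{category.name}|seg{k}"
            seg_key = str(k)
        counts[(r.patient_id, fid)] = counts.get((r.patient_id, fid), 0) + 1
        meta[fid] = {
            "resolution": "MEDIUM",
            "category": category.name,
            "gene_symbol": r.gene_symbol,
            "segment": seg_key,
            "variant_type": "",
        }
    if n_clamped:
        logger.warning(
            "%d %s mutation(s) fell outside their gene body and were clamped to the nearest terminal segment",
            n_clamped,
            category.name,
        )
    return _matrix_from_counts(patients, counts, meta)


def build_high_res(
    mutations: Sequence[MutationRecord],
    category: MutationCategory,
    patients: Sequence[str],
    min_carriers: int = 2,
) -> FeatureMatrix:
    """Binary specific-mutation indicators; singletons discarded cohort-wide.

    Two mutations at the same position with different alternate alleles are
    distinct features.  A feature whose mutation occurred in fewer than
    ``min_carriers`` patients across the whole cohort (default 2, i.e.
    singletons) is dropped.
    """
    carriers: dict[str, set[str]] = {}
    gene_of: dict[str, str] = {}
    vt_of: dict[str, str] = {}
    pset = _as_set(patients)
    for r in _categorized(mutations, category):
        if r.patient_id not in pset:
            continue
        fid = encode_feature_id(r)
        carriers.setdefault(fid, set()).add(r.patient_id)
        gene_of[fid] = r.gene_symbol
        vt_of[fid] = r.variant_type
    counts: dict[tuple[str, str], int] = {}
    meta: dict[str, dict] = {}
    for fid, pats in carriers.items():
        if len(pats) < min_carriers:
            continue
        meta[fid] = {
            "resolution": "HIGH",
            "category": category.name,
            "gene_symbol": gene_of[fid],
            "segment": "",
            "variant_type": vt_of[fid],
        }
        for p in pats:
            counts[(p, fid)] = 1
    return _matrix_from_counts(patients, counts, meta)


def assemble_dataset(matrices: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation of matrices sharing the patient axis."""
    if not matrices:
        raise ValueError("no matrices to assemble")
    patients = matrices[0].patients
    for m in matrices[1:]:
        if m.patients != patients:
            raise ValueError("patient axes differ between component matrices")
    values = sp.hstack([m.values for m in matrices], format="csr")
    meta = pd.concat([m.meta for m in matrices])
    return FeatureMatrix(patients=list(patients), values=values, meta=meta)


def build_category_dataset(
    mutations: Sequence[MutationRecord],
    annotation: Sequence[GeneAnnotation] | Mapping[str, GeneAnnotation],
    category: MutationCategory,
    patients: Sequence[str],
    resolutions: Sequence[str] = RESOLUTIONS,
    min_carriers: int = 2,
) -> FeatureMatrix:
    """One single-category dataset at the requested resolutions."""
    parts = []
    if "LOW" in resolutions:
        parts.append(build_low_res(mutations, category, patients))
    if "MEDIUM" in resolutions:
        parts.append(build_medium_res(mutations, annotation, category, patients))
    if "HIGH" in resolutions:
        parts.append(build_high_res(mutations, category, patients, min_carriers=min_carriers))
    return assemble_dataset(parts)


def build_all_datasets(
    mutations: Sequence[MutationRecord],
    annotation: Sequence[GeneAnnotation] | Mapping[str, GeneAnnotation],
    patients: Sequence[str],
    resolutions: Sequence[str] = RESOLUTIONS,
    min_carriers: int = 2,
) -> dict[str, FeatureMatrix]:
    """The six datasets: five single-category plus their union ("all")."""
    datasets = {
        cat.value: build_category_dataset(
            mutations, annotation, cat, patients, resolutions, min_carriers
        )
        for cat in MutationCategory
    }
    datasets["all"] = assemble_dataset([datasets[cat.value] for cat in MutationCategory])
    return datasets


def binarize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Counts -> presence/absence; already-binary columns are unchanged."""
    values = matrix.values.copy()
    values.data = (values.data > 0).astype(np.int64)
    return FeatureMatrix(patients=list(matrix.patients), values=values, meta=matrix.meta.copy())
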