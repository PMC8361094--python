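"""Readers, patient filters and mutation-category sorting for somatic cohorts.

Somatic mutation calls arrive as MAF-style tab-delimited tables (one row per
patient-mutation, 1-based inclusive coordinates) together with a clinical
table (cancer-type code, vital status, follow-up times).  Every retained
mutation is sorted into exactly one of five categories: non-silent exonic
changes, synonymous (amino-acid preserving) exonic changes, intronic,
untranslated-region (5'/3' UTR) and flanking-region mutations.  The last
four jointly constitute the "silent" mutations.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MutationCategory",
    "MutationRecord",
    "ClinicalRecord",
    "DEFAULT_CATEGORY_MAP",
    "VARIANT_TYPES",
    "categorize",
    "encode_feature_id",
    "decode_feature_id",
    "read_maf",
    "write_maf",
    "read_clinical",
    "write_clinical",
    "filter_patients",
    "normalize_patient_id",
]


class MutationCategory(Enum):
    """The five mutation categories; every retained call maps to one."""

    NON_SILENT = "non_silent"
    SYNONYMOUS = "synonymous"
    INTRON = "intron"
    UTR = "utr"
    FLANK = "flank"


SILENT_CATEGORIES = (
    MutationCategory.SYNONYMOUS,
    MutationCategory.INTRON,
    MutationCategory.UTR,
    MutationCategory.FLANK,
)

VARIANT_TYPES = ("SNP", "DEL", "INS")

# Variant-classification vocabulary (TCGA MAF dialect) -> category.
# Splice_Site calls are annotated on coding sequence and alter the protein,
# hence non-silent; Splice_Region calls lie in the intron near the junction.
# Anything absent from this table (RNA, IGR, Targeted_Region, ...) is
# excluded from the analysis rather than forced into a category.
DEFAULT_CATEGORY_MAP: Mapping[str, MutationCategory] = {
    "Missense_Mutation": MutationCategory.NON_SILENT,
    "Nonsense_Mutation": MutationCategory.NON_SILENT,
    "Nonstop_Mutation": MutationCategory.NON_SILENT,
    "Frame_Shift_Del": MutationCategory.NON_SILENT,
    "Frame_Shift_Ins": MutationCategory.NON_SILENT,
    "In_Frame_Del": MutationCategory.NON_SILENT,
    "In_Frame_Ins": MutationCategory.NON_SILENT,
    "Translation_Start_Site": MutationCategory.NON_SILENT,
    "Splice_Site": MutationCategory.NON_SILENT,
    "Silent": MutationCategory.SYNONYMOUS,
    "Intron": MutationCategory.INTRON,
    "Splice_Region": MutationCategory.INTRON,
    "3'UTR": MutationCategory.UTR,
    "5'UTR": MutationCategory.UTR,
    "3'Flank": MutationCategory.FLANK,
    "5'Flank": MutationCategory.FLANK,
}


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call for one patient.

    Coordinates are 1-based inclusive (MAF convention).  A record represents
    a genomic position whose nucleic-acid content differs between the
    patient's tumour and matched-normal samples; the classification string
    is trusted as given (no re-annotation).
    """

    patient_id: str
    gene_symbol: str
    chrom: str
    start: int
    end: int
    variant_classification: str
    variant_type: str
    ref_allele: str = "-"
    tumor_allele1: str = "-"
    tumor_allele2: str = "-"
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"start > end for {self.gene_symbol} at {self.chrom}:{self.start}"
            )
        if self.variant_type not in VARIANT_TYPES:
            raise ValueError(f"variant_type must be one of {VARIANT_TYPES}")

    @property
    def category(self) -> MutationCategory | None:
        return categorize(self.variant_classification)

    @property
    def feature_id(self) -> str:
        return encode_feature_id(self)


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient clinical row: cohort code, vital status, follow-up times."""

    patient_id: str
    cancer_type: str
    vital_status: str  # "alive" | "deceased"
    days_to_death: float | None = None
    days_to_last_followup: float | None = None

    def __post_init__(self) -> None:
        if self.vital_status not in ("alive", "deceased"):
            raise ValueError(f"vital_status must be alive/deceased, got {self.vital_status!r}")
        if self.vital_status == "deceased" and self.days_to_death is None:
            raise ValueError(f"deceased patient {self.patient_id} lacks days_to_death")


def categorize(
    variant_classification: str,
    category_map: Mapping[str, MutationCategory] = DEFAULT_CATEGORY_MAP,
) -> MutationCategory | None:
    """Map a variant-classification string to its category.

    Returns ``None`` for classifications outside the five categories
    (these calls are excluded from all downstream feature matrices).
    """
    return category_map.get(variant_classification)


_TCGA_BARCODE = re.compile(r"^TCGA-[A-Z0-9]{2}-[A-Z0-9]{4}")


def normalize_patient_id(barcode: str) -> str:
    """Collapse a TCGA-style sample barcode to its 12-character patient id.

    Non-TCGA identifiers pass through unchanged (they are opaque).
    """
    if _TCGA_BARCODE.match(barcode):
        return barcode[:12]
    return barcode


# ---------------------------------------------------------------------------
# feature-id codec

_ALLELE_EMPTY = ("", "-")


def _fmt_allele(a: str) -> str:
    return "" if a in _ALLELE_EMPTY else a


def encode_feature_id(record: MutationRecord) -> str:
    """Encode a mutation as its high-resolution feature identifier.

    Layout: ``start-end-chrom-classification-type-ref-allele1-allele2``.
    Empty/"-" alleles serialize as empty segments, so an insertion renders
    with consecutive dashes (e.g. ``...-Frame_Shift_Ins-INS---G``).
    """
    return "-".join(
        [
            str(record.start),
            str(record.end),
            record.chrom,
            record.variant_classification,
            record.variant_type,
            _fmt_allele(record.ref_allele),
            _fmt_allele(record.tumor_allele1),
            _fmt_allele(record.tumor_allele2),
        ]
    )


def decode_feature_id(feature_id: str) -> dict:
    """Inverse of :func:`encode_feature_id`.

    Raises ``ValueError`` naming the offending segment on malformed input.
    """
    parts = feature_id.split("-")
    if len(parts) != 8:
        raise ValueError(
            f"feature id {feature_id!r} has {len(parts)} '-'-separated segments, expected 8"
        )
    start_s, end_s, chrom, vclass, vtype, ref, a1, a2 = parts
    try:
        start = int(start_s)
    except ValueError:
        raise ValueError(f"feature id {feature_id!r}: start segment {start_s!r} not an integer")
    try:
        end = int(end_s)
    except ValueError:
        raise ValueError(f"feature id {feature_id!r}: end segment {end_s!r} not an integer")
    if vtype not in VARIANT_TYPES:
        raise ValueError(f"feature id {feature_id!r}: variant-type segment {vtype!r} invalid")
    return {
        "start": start,
        "end": end,
        "chrom": chrom,
        "variant_classification": vclass,
        "variant_type": vtype,
        "ref_allele": ref or "-",
        "tumor_allele1": a1 or "-",
        "tumor_allele2": a2 or "-",
    }


# ---------------------------------------------------------------------------
# MAF / clinical tables

MAF_COLUMNS = {
    "gene_symbol": "Hugo_Symbol",
    "chrom": "Chromosome",
    "start": "Start_Position",
    "end": "End_Position",
    "variant_classification": "Variant_Classification",
    "variant_type": "Variant_Type",
    "ref_allele": "Reference_Allele",
    "tumor_allele1": "Tumor_Seq_Allele1",
    "tumor_allele2": "Tumor_Seq_Allele2",
    "sample_id": "Tumor_Sample_Barcode",
}


def read_maf(path: str | Path, column_map: Mapping[str, str] | None = None) -> list[MutationRecord]:
    """Read a MAF-style tab-delimited mutation table.

    Unknown columns are ignored; rows whose coordinates do not parse are
    rejected with their row index logged.  A missing required column is
    fatal.  An empty file yields an empty list with a warning.
    """
    colmap = dict(MAF_COLUMNS)
    if column_map:
        colmap.update(column_map)
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("MAF file %s is empty", path)
        return []
    if df.empty:
        logger.warning("MAF file %s has a header but no rows", path)
        return []
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise ValueError(f"MAF file {path} is missing required column(s): {', '.join(missing)}")

    records: list[MutationRecord] = []
    bad_rows: list[int] = []
    for idx, row in enumerate(df.to_dict(orient="records")):
        get = lambda f: row[colmap[f]]  # noqa: E731 - per-row column lookup
        try:
            start = int(float(get("start")))
            end = int(float(get("end")))
        except (TypeError, ValueError):
            bad_rows.append(idx)
            continue
        sample = str(get("sample_id"))
        records.append(
            MutationRecord(
                patient_id=normalize_patient_id(sample),
                gene_symbol=str(get("gene_symbol")),
                chrom=str(get("chrom")),
                start=start,
                end=end,
                variant_classification=str(get("variant_classification")),
                variant_type=str(get("variant_type")),
                ref_allele=str(get("ref_allele")) if pd.notna(get("ref_allele")) else "-",
                tumor_allele1=str(get("tumor_allele1")) if pd.notna(get("tumor_allele1")) else "-",
                tumor_allele2=str(get("tumor_allele2")) if pd.notna(get("tumor_allele2")) else "-",
                sample_id=sample,
            )
        )
    if bad_rows:
        logger.warning("MAF file %s: rejected rows with unparseable coordinates: %s", path, bad_rows)
    return records


def write_maf(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write mutation records as a TCGA-column MAF TSV (round-trips read_maf)."""
    rows = []
    for r in records:
        rows.append(
            {
                "Hugo_Symbol": r.gene_symbol,
                "Chromosome": r.chrom,
                "Start_Position": r.start,
                "End_Position": r.end,
                "Variant_Classification": r.variant_classification,
                "Variant_Type": r.variant_type,
                "Reference_Allele": r.ref_allele,
                "Tumor_Seq_Allele1": r.tumor_allele1,
                "Tumor_Seq_Allele2": r.tumor_allele2,
                "Tumor_Sample_Barcode": r.sample_id or r.patient_id,
            }
        )
    pd.DataFrame(rows, columns=list(MAF_COLUMNS.values())).to_csv(path, sep="\t", index=False)


CLINICAL_COLUMNS = [
    "patient_id",
    "cancer_type",
    "vital_status",
    "days_to_death",
    "days_to_last_followup",
]


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV into a validated DataFrame (one row per patient)."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "cancer_type": str, "vital_status": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table {path} missing column(s): {', '.join(missing)}")
    df["patient_id"] = df["patient_id"].map(normalize_patient_id)
    return df[CLINICAL_COLUMNS].copy()


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def filter_patients(
    mutations: Sequence[MutationRecord],
    clinical: pd.DataFrame,
) -> tuple[list[MutationRecord], pd.DataFrame, dict]:
    """Restrict both tables to eligible patients.

    Eligibility: the patient appears in both the genomic and the clinical
    table, has exactly one genomic sample, and has a non-missing cancer-type
    and vital-status entry.  The exclusion report counts each reason.
    Idempotent: applying the filter twice changes nothing.
    """
    samples_per_patient: dict[str, set] = {}
    for r in mutations:
        samples_per_patient.setdefault(r.patient_id, set()).add(r.sample_id or r.patient_id)

    clin = clinical.drop_duplicates(subset="patient_id").copy()
    clin_patients = set(clin["patient_id"])
    genomic_patients = set(samples_per_patient)

    multi_sample = {p for p, s in samples_per_patient.items() if len(s) > 1}
    missing_clinical = genomic_patients - clin_patients
    missing_genomic = clin_patients - genomic_patients
    incomplete = set(
        clin.loc[clin["cancer_type"].isna() | clin["vital_status"].isna(), "patient_id"]
    )

    eligible = (genomic_patients & clin_patients) - multi_sample - incomplete
    report = {
        "n_input_genomic": len(genomic_patients),
        "n_input_clinical": len(clin_patients),
        "n_missing_clinical": len(missing_clinical),
        "n_missing_genomic": len(missing_genomic),
        "n_multi_sample": len(multi_sample & clin_patients),
        "n_incomplete_clinical": len(incomplete & genomic_patients),
        "n_eligible": len(eligible),
    }
    logger.info("patient filter: %s", report)
    kept_mut = [r for r in mutations if r.patient_id in eligible]
    kept_clin = clin[clin["patient_id"].isin(eligible)].reset_index(drop=True)
    return kept_mut, kept_clin, report


def category_counts(
    mutations: Iterable[MutationRecord],
    category_map: Mapping[str, MutationCategory] = DEFAULT_CATEGORY_MAP,
) -> Counter:
    """Count retained mutations per category; excluded calls under ``None``."""
    return Counter(categorize(r.variant_classification, category_map) for r in mutations)
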