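"""Synthetic somatic cohorts with planted, fully known signal.

The generator emulates the structure of a pan-cancer whole-exome cohort:
per-patient mutation records spanning the five mutation categories with a
realistic category imbalance (non-silent mutations dominate, flanking-region
calls are rare), an SNP/DEL/INS polymorphism mixture heavily weighted toward
SNPs, cancer-type-specific planted mutation signatures at configurable
prevalence on top of Poisson background noise, and survival times drawn from
a proportional-hazards model tied to planted features with administrative
right censoring.  Full ground truth (who carries which planted signal) is
recorded so that downstream recovery analyses can be validated.

No sequence-level realism is attempted: there is no trinucleotide context
and no mutational-signature structure, only category/position bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import (
    ClinicalRecord,
    MutationCategory,
    MutationRecord,
    encode_feature_id,
)

__all__ = [
    "Region",
    "GeneAnnotation",
    "PlantedSignal",
    "SignatureSpec",
    "CohortConfig",
    "SurvivalSpec",
    "make_annotation",
    "simulate_cohort",
    "simulate_survival",
    "point_signal",
    "gene_count_signal",
]

# Region kind -> classification strings it emits (all map back to the same
# category through cohort_io.DEFAULT_CATEGORY_MAP).
REGION_CLASSIFICATIONS: Mapping[str, tuple[str, ...]] = {
    "flank5": ("5'Flank",),
    "utr5": ("5'UTR",),
    "exon": (
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "Splice_Site",
        "Silent",
    ),
    "intron": ("Intron", "Splice_Region"),
    "utr3": ("3'UTR",),
    "flank3": ("3'Flank",),
}

# Category -> (region kinds it may fall in, classification strings it uses)
CATEGORY_REGIONS: Mapping[MutationCategory, tuple[tuple[str, ...], tuple[str, ...]]] = {
    MutationCategory.NON_SILENT: (
        ("exon",),
        ("Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del", "Frame_Shift_Ins", "Splice_Site"),
    ),
    MutationCategory.SYNONYMOUS: (("exon",), ("Silent",)),
    MutationCategory.INTRON: (("intron",), ("Intron", "Splice_Region")),
    MutationCategory.UTR: (("utr5", "utr3"), ("5'UTR", "3'UTR")),
    MutationCategory.FLANK: (("flank5", "flank3"), ("5'Flank", "3'Flank")),
}

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class Region:
    kind: str  # flank5 | utr5 | exon | intron | utr3 | flank3
    start: int  # 1-based inclusive
    end: int


@dataclass(frozen=True)
class GeneAnnotation:
    """One synthetic gene: ordered, contiguous region spans on its own chromosome."""

    gene_symbol: str
    chrom: str
    strand: str
    regions: tuple[Region, ...]

    @property
    def body_start(self) -> int:
        """Lowest coordinate of the gene body (flanks excluded)."""
        return min(r.start for r in self.regions if r.kind not in ("flank5", "flank3"))

    @property
    def body_end(self) -> int:
        return max(r.end for r in self.regions if r.kind not in ("flank5", "flank3"))

    @property
    def span(self) -> tuple[int, int]:
        return min(r.start for r in self.regions), max(r.end for r in self.regions)

    def regions_of_kind(self, kinds: Sequence[str]) -> list[Region]:
        return [r for r in self.regions if r.kind in kinds]

    def kind_at(self, pos: int) -> str | None:
        for r in self.regions:
            if r.start <= pos <= r.end:
                return r.kind
        return None


@dataclass(frozen=True)
class PlantedSignal:
    """One cancer-type-specific planted signal with known carriers.

    ``kind='point'`` plants one exact recurrent mutation (a high-resolution
    feature); ``kind='gene_count'`` plants a burst of ``extra_mutations``
    mutations of the category scattered across the gene (a low-resolution
    count signal with no recurrent position).
    """

    signal_id: str
    gene_symbol: str
    category: MutationCategory
    prevalence: float
    kind: str = "point"  # point | gene_count
    extra_mutations: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.kind not in ("point", "gene_count"):
            raise ValueError(f"unknown signal kind {self.kind!r}")


def point_signal(signal_id, gene_symbol, category, prevalence):
    return PlantedSignal(signal_id, gene_symbol, category, prevalence, kind="point")


def gene_count_signal(signal_id, gene_symbol, category, prevalence, extra_mutations=4):
    return PlantedSignal(
        signal_id, gene_symbol, category, prevalence, kind="gene_count", extra_mutations=extra_mutations
    )


@dataclass(frozen=True)
class SignatureSpec:
    cancer_type: str
    signals: tuple[PlantedSignal, ...] = ()


@dataclass
class CohortConfig:
    """Cohort-level knobs.

    Background rates are Poisson means per patient per category.  Defaults
    follow the category imbalance of pan-cancer whole-exome data at desk
    scale: non-silent calls dominate, then intronic, UTR, synonymous and
    flanking calls in decreasing order.  The polymorphism mixture is
    SNP-dominated with a small excess of deletions over insertions.
    """

    patients_per_type: int = 150
    background_rates: Mapping[MutationCategory, float] = field(
        default_factory=lambda: {
            MutationCategory.NON_SILENT: 8.0,
            MutationCategory.INTRON: 4.0,
            MutationCategory.UTR: 2.0,
            MutationCategory.SYNONYMOUS: 1.5,
            MutationCategory.FLANK: 0.75,
        }
    )
    variant_type_weights: Mapping[str, float] = field(
        default_factory=lambda: {"SNP": 0.90, "DEL": 0.06, "INS": 0.04}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.background_rates.values()):
            raise ValueError("background rates must be non-negative")
        total = sum(self.variant_type_weights.values())
        if not np.isclose(total, 1.0):
            raise ValueError("variant_type_weights must sum to 1")


@dataclass
class SurvivalSpec:
    """Exponential proportional-hazards truth model.

    Event times are Exponential(h0 * exp(sum_j beta_j x_ij)); patients still
    alive at the administrative horizon are censored there.  ``betas`` maps
    feature ids (columns of the feature matrix handed to
    :func:`simulate_survival`) to log hazard ratios.
    """

    baseline_hazard: float = 1.0 / 1500.0  # events per day
    betas: Mapping[str, float] = field(default_factory=dict)
    horizon_days: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if self.horizon_days <= 0:
            raise ValueError("censoring horizon must be positive")


# ---------------------------------------------------------------------------
# annotation


def make_annotation(
    n_genes: int,
    seed: int = 0,
    n_exons: int = 3,
    flank_length: int = 1000,
    region_scale: float = 1.0,
) -> list[GeneAnnotation]:
    """Draw ``n_genes`` synthetic genes, one per synthetic chromosome.

    Region layout along each chromosome: 5'flank, 5'UTR, alternating
    exons/introns, 3'UTR, 3'flank — non-overlapping and contiguous.  Region
    lengths are drawn uniformly at gene-scale sizes so the gene body is
    always >= several hundred nt (50-nt segmentation stays non-degenerate).
    Deterministic for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    genes = []
    for g in range(n_genes):
        chrom = f"chrS{g + 1}"
        pos = int(rng.integers(10_000, 1_000_000))
        regions: list[Region] = []

        def add(kind: str, length: int) -> None:
            nonlocal pos
            regions.append(Region(kind, pos, max(pos + length - 1, pos)))
            pos += max(length, 1)

        scale = lambda n: max(int(n * region_scale), 10)  # noqa: E731
        add("flank5", flank_length)
        add("utr5", scale(int(rng.integers(80, 250))))
        for e in range(n_exons):
            add("exon", scale(int(rng.integers(120, 400))))
            if e < n_exons - 1:
                add("intron", scale(int(rng.integers(150, 600))))
        add("utr3", scale(int(rng.integers(150, 500))))
        add("flank3", flank_length)
        genes.append(
            GeneAnnotation(
                gene_symbol=f"G{g + 1:03d}",
                chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                regions=tuple(regions),
            )
        )
    return genes


def annotation_index(annotation: Sequence[GeneAnnotation]) -> dict[str, GeneAnnotation]:
    return {g.gene_symbol: g for g in annotation}


# ---------------------------------------------------------------------------
# cohort simulation


def _ref_base(chrom: str, pos: int) -> str:
    """Deterministic reference base per position (a fixed virtual genome)."""
    h = (pos * 2654435761 + sum(map(ord, chrom))) & 0xFFFFFFFF
    return str(_BASES[h % 4])


def _draw_alleles(rng: np.random.Generator, variant_type: str, chrom: str, pos: int) -> tuple[str, str, str]:
    if variant_type == "SNP":
        ref = _ref_base(chrom, pos)
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        return ref, ref, alt
    if variant_type == "DEL":
        ref = _ref_base(chrom, pos)
        return ref, ref, "-"
    ins = str(rng.choice(_BASES))
    return "-", "-", ins


def _random_mutation(
    rng: np.random.Generator,
    patient_id: str,
    gene: GeneAnnotation,
    category: MutationCategory,
    variant_type: str,
) -> MutationRecord:
    kinds, classes = CATEGORY_REGIONS[category]
    regions = gene.regions_of_kind(kinds)
    lengths = np.array([r.end - r.start + 1 for r in regions], dtype=float)
    region = regions[int(rng.choice(len(regions), p=lengths / lengths.sum()))]
    pos = int(rng.integers(region.start, region.end + 1))
    vclass = str(rng.choice([c for c in classes if c in REGION_CLASSIFICATIONS[region.kind]]))
    ref, a1, a2 = _draw_alleles(rng, variant_type, gene.chrom, pos)
    end = pos
    return MutationRecord(
        patient_id=patient_id,
        gene_symbol=gene.gene_symbol,
        chrom=gene.chrom,
        start=pos,
        end=end,
        variant_classification=vclass,
        variant_type=variant_type,
        ref_allele=ref,
        tumor_allele1=a1,
        tumor_allele2=a2,
        sample_id=patient_id,
    )


def planted_point_mutation(gene: GeneAnnotation, category: MutationCategory) -> MutationRecord:
    """The exact recurrent mutation a point signal plants, as a template.

    Deterministic in (gene, category): the midpoint of the first region that
    emits the category, an SNP with A>T alleles and the category's first
    classification string.  Every carrier of the signal receives this exact
    record, making it a recoverable high-resolution feature.
    """
    kinds, classes = CATEGORY_REGIONS[category]
    region = gene.regions_of_kind(kinds)[0]
    pos = (region.start + region.end) // 2
    return MutationRecord(
        patient_id="__template__",
        gene_symbol=gene.gene_symbol,
        chrom=gene.chrom,
        start=pos,
        end=pos,
        variant_classification=classes[0],
        variant_type="SNP",
        ref_allele="A",
        tumor_allele1="A",
        tumor_allele2="T",
        sample_id="__template__",
    )


def simulate_cohort(
    annotation: Sequence[GeneAnnotation],
    signatures: Sequence[SignatureSpec],
    config: CohortConfig,
) -> tuple[list[MutationRecord], pd.DataFrame, pd.DataFrame]:
    """Simulate mutations + clinical table + planted-signal truth table.

    Each patient receives Poisson(background rate) mutations per category,
    placed uniformly within length-weighted matching regions of uniformly
    chosen genes, plus each of their cancer type's planted signals
    independently with its prevalence.  The truth table records one row per
    (patient, signal) with the carrier flag and, for point signals, the
    planted high-resolution feature id.
    """
    gene_index = annotation_index(annotation)
    for spec in signatures:
        for s in spec.signals:
            if s.gene_symbol not in gene_index:
                raise ValueError(f"signal {s.signal_id}: gene {s.gene_symbol} not in annotation")
            kinds, _ = CATEGORY_REGIONS[s.category]
            if not gene_index[s.gene_symbol].regions_of_kind(kinds):
                raise ValueError(
                    f"signal {s.signal_id}: gene {s.gene_symbol} lacks a region emitting {s.category}"
                )

    rng = np.random.default_rng(config.seed)
    vt_names = list(config.variant_type_weights)
    vt_probs = np.array([config.variant_type_weights[v] for v in vt_names])

    mutations: list[MutationRecord] = []
    clinical_rows = []
    truth_rows = []
    for spec in signatures:
        for i in range(config.patients_per_type):
            pid = f"{spec.cancer_type}-{i:04d}"
            clinical_rows.append(
                {
                    "patient_id": pid,
                    "cancer_type": spec.cancer_type,
                    "vital_status": "alive",
                    "days_to_death": np.nan,
                    "days_to_last_followup": np.nan,
                }
            )
            # background
            for category, rate in config.background_rates.items():
                for _ in range(int(rng.poisson(rate))):
                    gene = annotation[int(rng.integers(len(annotation)))]
                    kinds, _ = CATEGORY_REGIONS[category]
                    if not gene.regions_of_kind(kinds):
                        continue
                    vt = str(rng.choice(vt_names, p=vt_probs))
                    mutations.append(_random_mutation(rng, pid, gene, category, vt))
            # planted signals
            for s in spec.signals:
                carrier = bool(rng.random() < s.prevalence)
                feature_id = ""
                if s.kind == "point":
                    template = planted_point_mutation(gene_index[s.gene_symbol], s.category)
                    feature_id = encode_feature_id(template)
                    if carrier:
                        mutations.append(
                            MutationRecord(
                                **{
                                    **template.__dict__,
                                    "patient_id": pid,
                                    "sample_id": pid,
                                }
                            )
                        )
                elif carrier:
                    for _ in range(s.extra_mutations):
                        mutations.append(
                            _random_mutation(rng, pid, gene_index[s.gene_symbol], s.category, "SNP")
                        )
                truth_rows.append(
                    {
                        "patient_id": pid,
                        "cancer_type": spec.cancer_type,
                        "signal_id": s.signal_id,
                        "gene_symbol": s.gene_symbol,
                        "category": s.category.name,
                        "kind": s.kind,
                        "feature_id": feature_id,
                        "carrier": carrier,
                    }
                )

    clinical = pd.DataFrame(clinical_rows)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "patient_id",
            "cancer_type",
            "signal_id",
            "gene_symbol",
            "category",
            "kind",
            "feature_id",
            "carrier",
        ],
    )
    return mutations, clinical, truth


# ---------------------------------------------------------------------------
# survival simulation


def simulate_survival(
    clinical: pd.DataFrame,
    features: pd.DataFrame,
    spec: SurvivalSpec,
) -> pd.DataFrame:
    """Overwrite vital status / time fields from a proportional-hazards draw.

    ``features`` is a patients x features DataFrame (binary or counts)
    indexed by patient id; ``spec.betas`` gives the log hazard ratio of each
    named column.  Event time ~ Exponential(h0 * exp(x @ beta)); patients
    whose event falls beyond the administrative horizon are censored there
    (vital_status "alive", days_to_last_followup = horizon).
    """
    rng = np.random.default_rng(spec.seed)
    clin = clinical.copy().reset_index(drop=True)
    eta = np.zeros(len(clin))
    for fid, beta in spec.betas.items():
        if fid not in features.columns:
            raise KeyError(f"beta refers to unknown feature {fid!r}")
        x = features[fid].reindex(clin["patient_id"]).fillna(0).to_numpy(dtype=float)
        eta += beta * x
    hazard = spec.baseline_hazard * np.exp(eta)
    event_time = rng.exponential(1.0 / hazard)
    censored = event_time > spec.horizon_days

    clin["vital_status"] = np.where(censored, "alive", "deceased")
    clin["days_to_death"] = np.where(censored, np.nan, np.ceil(event_time))
    clin["days_to_last_followup"] = np.where(censored, float(spec.horizon_days), np.nan)
    return clin
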