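"""Category sorting, feature-id codec, MAF/clinical I/O and patient filters."""

import numpy as np
import pandas as pd
import pytest

from silentmut.cohort_io import (
    DEFAULT_CATEGORY_MAP,
    MutationCategory,
    MutationRecord,
    categorize,
    category_counts,
    decode_feature_id,
    encode_feature_id,
    filter_patients,
    normalize_patient_id,
    read_clinical,
    read_maf,
    write_clinical,
    write_maf,
)


@pytest.mark.parametrize(
    "classification, expected",
    [
        ("Missense_Mutation", MutationCategory.NON_SILENT),
        ("Nonsense_Mutation", MutationCategory.NON_SILENT),
        ("Frame_Shift_Ins", MutationCategory.NON_SILENT),
        ("Splice_Site", MutationCategory.NON_SILENT),
        ("Silent", MutationCategory.SYNONYMOUS),
        ("Intron", MutationCategory.INTRON),
        ("Splice_Region", MutationCategory.INTRON),
        ("3'UTR", MutationCategory.UTR),
        ("5'UTR", MutationCategory.UTR),
        ("3'Flank", MutationCategory.FLANK),
        ("5'Flank", MutationCategory.FLANK),
        ("RNA", None),
        ("IGR", None),
        ("Targeted_Region", None),
    ],
)
def test_categorize(classification, expected):
    assert categorize(classification) is expected


def test_five_categories_and_exhaustive_map():
    assert len(MutationCategory) == 5
    assert set(DEFAULT_CATEGORY_MAP.values()) == set(MutationCategory)


def test_encode_known_snp_feature():
    """A recurrent missense SNP encodes to the position-class-allele id."""
    rec = MutationRecord(
        patient_id="p", gene_symbol="BRAF", chrom="chr7",
        start=140753336, end=140753336,
        variant_classification="Missense_Mutation", variant_type="SNP",
        ref_allele="A", tumor_allele1="A", tumor_allele2="T",
    )
    assert encode_feature_id(rec) == "140753336-140753336-chr7-Missense_Mutation-SNP-A-A-T"


def test_encode_insertion_empty_alleles():
    rec = MutationRecord(
        patient_id="p", gene_symbol="GLI1", chrom="chr12",
        start=57466291, end=57466292,
        variant_classification="Frame_Shift_Ins", variant_type="INS",
        ref_allele="-", tumor_allele1="-", tumor_allele2="G",
    )
    fid = encode_feature_id(rec)
    assert fid == "57466291-57466292-chr12-Frame_Shift_Ins-INS---G"
    assert decode_feature_id(fid)["ref_allele"] == "-"
    assert decode_feature_id(fid)["tumor_allele2"] == "G"


def test_encode_decode_roundtrip_random():
    rng = np.random.default_rng(5)
    classes = list(DEFAULT_CATEGORY_MAP)
    for _ in range(1000):
        vt = ["SNP", "DEL", "INS"][int(rng.integers(3))]
        bases = "ACGT"
        if vt == "SNP":
            ref = a1 = bases[int(rng.integers(4))]
            a2 = bases[int(rng.integers(4))]
        elif vt == "DEL":
            ref = a1 = bases[int(rng.integers(4))]
            a2 = "-"
        else:
            ref = a1 = "-"
            a2 = bases[int(rng.integers(4))]
        start = int(rng.integers(1, 10**8))
        rec = MutationRecord(
            patient_id="p", gene_symbol="G", chrom=f"chr{int(rng.integers(1, 23))}",
            start=start, end=start + int(rng.integers(0, 3)),
            variant_classification=classes[int(rng.integers(len(classes)))],
            variant_type=vt, ref_allele=ref, tumor_allele1=a1, tumor_allele2=a2,
        )
        decoded = decode_feature_id(encode_feature_id(rec))
        for key, val in decoded.items():
            assert getattr(rec, key) == val


@pytest.mark.parametrize(
    "bad", ["1-2-chr1-Missense_Mutation-SNP-A-A", "x-2-chr1-Silent-SNP-A-A-T",
            "1-2-chr1-Silent-XXX-A-A-T"],
)
def test_decode_malformed(bad):
    with pytest.raises(ValueError):
        decode_feature_id(bad)


from hypothesis import given, settings, strategies as st  # noqa: E402

_allele = st.sampled_from(["A", "C", "G", "T", "-", "AT", "GGC"])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    start=st.integers(min_value=1, max_value=10**9),
    length=st.integers(min_value=0, max_value=5),
    chrom=st.sampled_from(["chr1", "chrX", "chrS12"]),
    vclass=st.sampled_from(sorted(DEFAULT_CATEGORY_MAP)),
    vtype=st.sampled_from(["SNP", "DEL", "INS"]),
    ref=_allele, a1=_allele, a2=_allele,
)
def test_codec_roundtrip_property(start, length, chrom, vclass, vtype, ref, a1, a2):
    rec = MutationRecord(
        patient_id="p", gene_symbol="G", chrom=chrom, start=start, end=start + length,
        variant_classification=vclass, variant_type=vtype,
        ref_allele=ref, tumor_allele1=a1, tumor_allele2=a2,
    )
    decoded = decode_feature_id(encode_feature_id(rec))
    for key, val in decoded.items():
        assert getattr(rec, key) == val


def test_maf_roundtrip(tmp_path, annotation):
    from tests.conftest import random_cohort

    rng = np.random.default_rng(17)
    _, records = random_cohort(rng, annotation, 5, 50)
    path = tmp_path / "cohort.maf.tsv"
    write_maf(records, path)
    back = read_maf(path)
    assert back == records


def test_read_maf_empty_and_missing_column(tmp_path):
    empty = tmp_path / "empty.maf.tsv"
    empty.write_text("")
    assert read_maf(empty) == []

    bad = tmp_path / "bad.maf.tsv"
    bad.write_text("Hugo_Symbol\tChromosome\nTP53\tchr17\n")
    with pytest.raises(ValueError, match="Start_Position"):
        read_maf(bad)


def test_read_maf_rejects_unparseable_coordinates(tmp_path):
    path = tmp_path / "coords.maf.tsv"
    header = "\t".join(
        ["Hugo_Symbol", "Chromosome", "Start_Position", "End_Position",
         "Variant_Classification", "Variant_Type", "Reference_Allele",
         "Tumor_Seq_Allele1", "Tumor_Seq_Allele2", "Tumor_Sample_Barcode"]
    )
    good = "TP53\tchr17\t100\t100\tSilent\tSNP\tA\tA\tG\tP1"
    bad = "TP53\tchr17\tNA\t100\tSilent\tSNP\tA\tA\tG\tP2"
    path.write_text(f"{header}\n{good}\n{bad}\n")
    records = read_maf(path)
    assert len(records) == 1 and records[0].patient_id == "P1"


def test_normalize_tcga_barcode():
    assert normalize_patient_id("TCGA-AB-1234-01A-11D") == "TCGA-AB-1234"
    assert normalize_patient_id("T01-0001") == "T01-0001"


def _clin(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "cancer_type", "vital_status",
                       "days_to_death", "days_to_last_followup"]
    )


def _mut(pid, sample=None):
    return MutationRecord(
        patient_id=pid, gene_symbol="G", chrom="chr1", start=1, end=1,
        variant_classification="Silent", variant_type="SNP",
        ref_allele="A", tumor_allele1="A", tumor_allele2="G",
        sample_id=sample or pid,
    )


def test_filter_patients_drops_and_is_idempotent():
    muts = [_mut("A"), _mut("B", "B-s1"), _mut("B", "B-s2"), _mut("C")]
    clinical = _clin([
        ("A", "X", "alive", None, 100.0),
        ("B", "X", "alive", None, 100.0),   # two genomic samples -> dropped
        ("D", "X", "alive", None, 100.0),   # clinical only -> dropped
    ])
    kept_m, kept_c, report = filter_patients(muts, clinical)
    assert {r.patient_id for r in kept_m} == {"A"}
    assert kept_c["patient_id"].tolist() == ["A"]
    assert report["n_multi_sample"] == 1 and report["n_missing_genomic"] == 1
    # patient C had no clinical row
    assert report["n_missing_clinical"] == 1

    again_m, again_c, _ = filter_patients(kept_m, kept_c)
    assert again_m == kept_m
    assert again_c.equals(kept_c)


def test_filter_patients_identity_when_all_eligible():
    muts = [_mut("A"), _mut("B")]
    clinical = _clin([("A", "X", "alive", None, 1.0), ("B", "X", "alive", None, 1.0)])
    kept_m, kept_c, _ = filter_patients(muts, clinical)
    assert kept_m == muts
    assert sorted(kept_c["patient_id"]) == ["A", "B"]


def test_category_counts_partition(annotation):
    from tests.conftest import random_cohort

    rng = np.random.default_rng(3)
    _, records = random_cohort(rng, annotation, 10, 200)
    records.append(_mut("P000"))
    excluded = MutationRecord(
        patient_id="P000", gene_symbol="G", chrom="chr1", start=5, end=5,
        variant_classification="RNA", variant_type="SNP",
    )
    records.append(excluded)
    counts = category_counts(records)
    assert sum(v for k, v in counts.items() if k is not None) == len(records) - counts[None]
    assert counts[None] == 1


def test_clinical_roundtrip(tmp_path):
    clinical = _clin([("A", "X", "deceased", 120.0, None), ("B", "Y", "alive", None, 300.0)])
    path = tmp_path / "clinical.tsv"
    write_clinical(clinical, path)
    back = read_clinical(path)
    assert back["patient_id"].tolist() == ["A", "B"]
    assert back.loc[0, "days_to_death"] == 120.0
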