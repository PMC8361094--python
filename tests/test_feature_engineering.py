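"""Feature matrices vs an independent nested-loop counting oracle."""

import numpy as np
import pandas as pd
import pytest

from silentmut.cohort_io import MutationCategory, MutationRecord, categorize, encode_feature_id
from silentmut.feature_engineering import (
    FeatureMatrix,
    assemble_dataset,
    binarize,
    build_all_datasets,
    build_category_dataset,
    build_high_res,
    build_low_res,
    build_medium_res,
    segment_index,
)
from silentmut.synthetic_cohort import annotation_index
from tests.conftest import random_cohort


# ---------------------------------------------------------------------------
# independent brute-force oracle (plain nested loops over records)


def oracle_low(records, category, patients):
    counts = {}
    for p in patients:
        for r in records:
            if r.patient_id == p and categorize(r.variant_classification) is category:
                counts[(p, r.gene_symbol)] = counts.get((p, r.gene_symbol), 0) + 1
    return counts


def oracle_medium(records, genes, category, patients):
    counts = {}
    for p in patients:
        for r in records:
            if r.patient_id != p or categorize(r.variant_classification) is not category:
                continue
            if category is MutationCategory.FLANK:
                key = "5p" if r.variant_classification == "5'Flank" else "3p"
            else:
                g = genes[r.gene_symbol]
                pos = min(max(r.start, g.body_start), g.body_end)
                key = (pos - g.body_start) // 50
            counts[(p, r.gene_symbol, key)] = counts.get((p, r.gene_symbol, key), 0) + 1
    return counts


def oracle_high(records, category, patients):
    carriers = {}
    for r in records:
        if categorize(r.variant_classification) is category and r.patient_id in patients:
            carriers.setdefault(encode_feature_id(r), set()).add(r.patient_id)
    return {fid: pats for fid, pats in carriers.items() if len(pats) >= 2}


def compare_with_oracle(records, annotation, patients):
    genes = annotation_index(annotation)
    for category in MutationCategory:
        low = build_low_res(records, category, patients).to_dataframe()
        expected = oracle_low(records, category, patients)
        assert float(low.sum().sum()) == sum(expected.values())
        for (p, g), v in expected.items():
            assert low.loc[p, f"{g}|{category.name}|LOW"] == v

        med = build_medium_res(records, annotation, category, patients).to_dataframe()
        emed = oracle_medium(records, genes, category, patients)
        assert float(med.sum().sum()) == sum(emed.values())
        for (p, g, key), v in emed.items():
            suffix = key if isinstance(key, str) else f"seg{key}"
            col = f"{g}|{'FLANK' if isinstance(key, str) else category.name}|{suffix}"
            assert med.loc[p, col] == v

        high = build_high_res(records, category, patients)
        ehigh = oracle_high(records, category, set(patients))
        assert set(high.feature_ids) == set(ehigh)
        hdf = high.to_dataframe()
        for fid, pats in ehigh.items():
            assert set(hdf.index[hdf[fid] == 1]) == pats

        # conservation: medium sums to low per (patient, gene)
        for (p, g), v in expected.items():
            med_total = sum(val for (pp, gg, _), val in emed.items() if pp == p and gg == g)
            assert med_total == v


def test_matrices_match_bruteforce_oracle(annotation):
    rng = np.random.default_rng(42)
    for _ in range(10):
        n_pat = int(rng.integers(5, 30))
        patients, records = random_cohort(rng, annotation, n_pat, int(rng.integers(30, 150)))
        compare_with_oracle(records, annotation, patients)


def test_low_res_direct_count(annotation):
    """A patient's per-gene count equals the number of their mutations there."""
    g = annotation[0]
    intron = next(r for r in g.regions if r.kind == "intron")
    recs = [
        MutationRecord("P1", g.gene_symbol, g.chrom, intron.start + off, intron.start + off,
                       "Intron", "SNP", "A", "A", "G")
        for off in (0, 1, 2)
    ]
    fm = build_low_res(recs, MutationCategory.INTRON, ["P1", "P2"])
    df = fm.to_dataframe()
    assert df.loc["P1", f"{g.gene_symbol}|INTRON|LOW"] == 3
    assert df.loc["P2", f"{g.gene_symbol}|INTRON|LOW"] == 0


def test_two_patient_toy_counts(annotation):
    """Two patients' marked mutations reproduce per-region counts: the
    intron dataset counts intronic hits per gene, the UTR dataset UTR hits."""
    g = annotation[0]
    intron = next(r for r in g.regions if r.kind == "intron")
    utr3 = next(r for r in g.regions if r.kind == "utr3")

    def rec(pid, pos, vclass):
        return MutationRecord(pid, g.gene_symbol, g.chrom, pos, pos, vclass, "SNP", "A", "A", "G")

    records = [
        rec("P1", intron.start, "Intron"),
        rec("P1", intron.start + 60, "Intron"),
        rec("P2", intron.start + 1, "Intron"),
        rec("P1", utr3.start, "3'UTR"),
        rec("P2", utr3.start + 2, "3'UTR"),
        rec("P2", utr3.start + 3, "3'UTR"),
    ]
    patients = ["P1", "P2"]
    intron_counts = build_low_res(records, MutationCategory.INTRON, patients).to_dataframe()
    utr_counts = build_low_res(records, MutationCategory.UTR, patients).to_dataframe()
    assert intron_counts[f"{g.gene_symbol}|INTRON|LOW"].tolist() == [2, 1]
    assert utr_counts[f"{g.gene_symbol}|UTR|LOW"].tolist() == [1, 2]


def test_segment_index_arithmetic():
    assert segment_index(1073, 1001) == 1  # floor((1073-1001)/50)
    assert segment_index(1001, 1001) == 0
    assert segment_index(1050, 1001) == 0
    assert segment_index(1051, 1001) == 1


def test_medium_conservation_property(annotation, small_cohort):
    mutations, clinical, _, _ = small_cohort
    patients = sorted(clinical["patient_id"])
    for category in (MutationCategory.NON_SILENT, MutationCategory.INTRON):
        low = build_low_res(mutations, category, patients)
        med = build_medium_res(mutations, annotation, category, patients)
        low_df = low.to_dataframe()
        med_df = med.to_dataframe()
        gene_of = med.meta["gene_symbol"]
        summed = med_df.T.groupby(gene_of).sum().T
        for gene in summed.columns:
            col = f"{gene}|{category.name}|LOW"
            assert (summed[gene] == low_df[col]).all()


def test_high_res_singleton_filter_and_allele_distinction():
    recs = []

    def rec(pid, pos, a2):
        return MutationRecord(pid, "G1", "chr1", pos, pos, "Silent", "SNP", "A", "A", a2)

    # shared mutation (2 carriers), singleton, allele-distinct pair
    recs += [rec("P1", 100, "G"), rec("P2", 100, "G")]
    recs += [rec("P1", 200, "G")]
    recs += [rec("P1", 300, "G"), rec("P2", 300, "T"), rec("P3", 300, "T")]
    fm = build_high_res(recs, MutationCategory.SYNONYMOUS, ["P1", "P2", "P3"])
    ids = fm.feature_ids
    assert "100-100-chr1-Silent-SNP-A-A-G" in ids
    assert "200-200-chr1-Silent-SNP-A-A-G" not in ids  # single carrier
    assert "300-300-chr1-Silent-SNP-A-A-T" in ids  # 2 carriers
    assert "300-300-chr1-Silent-SNP-A-A-G" not in ids  # distinct alt, 1 carrier
    assert (fm.carrier_counts() >= 2).all()
    assert fm.column_sums()["100-100-chr1-Silent-SNP-A-A-G"] == 2


def test_assemble_all_is_disjoint_union(small_datasets):
    datasets, _ = small_datasets
    n_all = datasets["all"].shape[1]
    assert n_all == sum(datasets[c.value].shape[1] for c in MutationCategory)
    # single-resolution subset relation
    intron = datasets["intron"]
    high_only = intron.select_features(
        list(intron.meta.index[intron.meta["resolution"] == "HIGH"])
    )
    assert set(high_only.feature_ids) <= set(intron.feature_ids)


def test_assemble_patient_mismatch_fatal(small_datasets):
    datasets, patients = small_datasets
    shifted = datasets["intron"].select_patients(patients[:-1])
    with pytest.raises(ValueError, match="patient axes"):
        assemble_dataset([datasets["utr"], shifted])


def test_binarize(small_datasets):
    datasets, _ = small_datasets
    fm = datasets["all"]
    b = binarize(fm)
    arr = b.values.toarray()
    assert set(np.unique(arr)) <= {0, 1}
    assert ((fm.values.toarray() > 0) == (arr == 1)).all()
    bb = binarize(b)
    assert (bb.values != b.values).nnz == 0
    # HIGH features unchanged by binarization
    high_ids = list(fm.meta.index[fm.meta["resolution"] == "HIGH"])
    assert (
        fm.select_features(high_ids).values != b.select_features(high_ids).values
    ).nnz == 0


def test_save_load_roundtrip(tmp_path, small_datasets):
    datasets, _ = small_datasets
    fm = datasets["utr"]
    fm.save(tmp_path, stem="utr")
    back = FeatureMatrix.load(tmp_path, stem="utr")
    assert back.patients == fm.patients
    assert list(back.meta.index) == list(fm.meta.index)
    assert (back.values != fm.values).nnz == 0


def test_mutation_outside_gene_body_clamped(annotation, caplog):
    g = annotation[0]
    rec = MutationRecord("P1", g.gene_symbol, g.chrom, g.body_end + 10_000, g.body_end + 10_000,
                         "Intron", "SNP", "A", "A", "G")
    fm = build_medium_res([rec], annotation, MutationCategory.INTRON, ["P1"])
    (fid,) = fm.feature_ids
    last_seg = segment_index(g.body_end, g.body_start)
    assert fid == f"{g.gene_symbol}|INTRON|seg{last_seg}"
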