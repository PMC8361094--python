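"""Jaccard/misclassification protocols and burden statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from silentmut.cohort_similarity import (
    f1_improvement,
    improvement_burden_correlation,
    jaccard,
    jaccard_pair_protocol,
    mb_increase,
    misclassification_protocol,
    similarity_vs_misclassification,
)
from silentmut.feature_engineering import FeatureMatrix


def _fm(df):
    meta = pd.DataFrame(
        {"resolution": "HIGH", "category": "NON_SILENT", "gene_symbol": "G",
         "segment": "", "variant_type": "SNP"},
        index=pd.Index(df.columns, name="feature_id"),
    )
    return FeatureMatrix(
        patients=list(df.index), values=sp.csr_matrix(df.to_numpy()), meta=meta
    )


def _clinical(type_of):
    return pd.DataFrame(
        {"patient_id": list(type_of), "cancer_type": list(type_of.values()),
         "vital_status": "alive", "days_to_death": np.nan, "days_to_last_followup": 100.0}
    )


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ({1, 2, 3}, {1, 2, 3}, 1.0),
        ({1, 2}, {3, 4}, 0.0),
        ({1, 2, 3}, {2, 3, 4}, 0.5),
        (set(), set(), 0.0),
        (set(), {1}, 0.0),
    ],
)
def test_jaccard(a, b, expected):
    assert jaccard(a, b) == pytest.approx(expected, abs=1e-12)
    assert jaccard(a, b) == jaccard(b, a)


def test_jaccard_protocol_clones_and_disjoint():
    profiles = pd.DataFrame(
        np.tile([1, 0, 1, 0, 0], (10, 1)),
        index=[f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)],
        columns=[f"f{i}" for i in range(5)],
    )
    clinical = _clinical({f"A{i}": "A" for i in range(5)} | {f"B{i}": "B" for i in range(5)})
    res = jaccard_pair_protocol(_fm(profiles), clinical, "A", "B", sample_size=5)
    assert res.jaccard == pytest.approx(1.0)

    disjoint = profiles.copy()
    disjoint.iloc[5:] = [0, 1, 0, 1, 1]
    res = jaccard_pair_protocol(_fm(disjoint), clinical, "A", "B", sample_size=5)
    assert res.jaccard == pytest.approx(0.0)


def test_jaccard_protocol_matches_bruteforce_on_toy():
    """When the sample is the whole cohort the protocol equals the exhaustive
    double loop exactly."""
    rng = np.random.default_rng(3)
    profiles = pd.DataFrame(
        (rng.random((10, 8)) < 0.4).astype(int),
        index=[f"A{i}" for i in range(5)] + [f"B{i}" for i in range(5)],
        columns=[f"f{i}" for i in range(8)],
    )
    clinical = _clinical({f"A{i}": "A" for i in range(5)} | {f"B{i}": "B" for i in range(5)})
    res = jaccard_pair_protocol(
        _fm(profiles), clinical, "A", "B", sample_size=5, n_repetitions=1
    )
    total = 0.0
    for i in range(5):
        fa = {c for c in profiles.columns if profiles.loc[f"A{i}", c]}
        for j in range(5):
            fb = {c for c in profiles.columns if profiles.loc[f"B{j}", c]}
            total += jaccard(fa, fb)
    assert res.jaccard == pytest.approx(total / 25, abs=1e-12)


def test_jaccard_protocol_binarizes_counts():
    counts = pd.DataFrame(
        [[3, 0], [2, 0], [1, 0], [0, 5], [0, 1], [0, 2]],
        index=[f"A{i}" for i in range(3)] + [f"B{i}" for i in range(3)],
        columns=["f1", "f2"],
    )
    clinical = _clinical({f"A{i}": "A" for i in range(3)} | {f"B{i}": "B" for i in range(3)})
    res = jaccard_pair_protocol(_fm(counts), clinical, "A", "B", sample_size=3)
    assert res.jaccard == pytest.approx(0.0)  # disjoint after binarization


def test_misclassification_separable_and_eq_consistency():
    rng = np.random.default_rng(0)
    n = 40
    # A carries f0..f2, B carries f3..f5; pure separation
    a = np.zeros((n, 6)); a[:, :3] = (rng.random((n, 3)) < 0.9)
    b = np.zeros((n, 6)); b[:, 3:] = (rng.random((n, 3)) < 0.9)
    profiles = pd.DataFrame(
        np.vstack([a, b]).astype(int),
        index=[f"A{i}" for i in range(n)] + [f"B{i}" for i in range(n)],
        columns=[f"f{i}" for i in range(6)],
    )
    clinical = _clinical(
        {f"A{i}": "A" for i in range(n)} | {f"B{i}": "B" for i in range(n)}
    )
    res = misclassification_protocol(
        _fm(profiles), clinical, "A", "B", sample_size=n, n_repetitions=3,
        learner_params={"n_estimators": 30, "min_child_samples": 5},
    )
    assert res.misclassification_rate < 0.1
    # stored confusion counts reproduce the rate: M = (|AB|+|BA|) / total
    for (aa, ab, ba, bb), m in zip(res.confusion_counts, res.per_repetition):
        assert aa + ab + ba + bb == 2 * round(n * 0.3)
        assert m == pytest.approx((ab + ba) / (aa + ab + ba + bb), abs=1e-12)


def test_misclassification_shuffled_labels_near_half():
    rng = np.random.default_rng(1)
    n = 60
    profiles = pd.DataFrame(
        (rng.random((2 * n, 10)) < 0.3).astype(int),
        index=[f"P{i}" for i in range(2 * n)],
        columns=[f"f{i}" for i in range(10)],
    )
    # labels carry no information (random assignment to A/B)
    types = rng.permutation(["A"] * n + ["B"] * n)
    clinical = _clinical(dict(zip(profiles.index, types)))
    res = misclassification_protocol(
        _fm(profiles), clinical, "A", "B", sample_size=n, n_repetitions=4,
        learner_params={"n_estimators": 30},
    )
    assert 0.3 < res.misclassification_rate < 0.7


@pytest.mark.parametrize(
    "f1_all, f1_ns, expected",
    [(0.5, 0.4, 25.0), (0.4, 0.4, 0.0), (0.3, 0.4, -25.0)],
)
def test_f1_improvement(f1_all, f1_ns, expected):
    assert f1_improvement(f1_all, f1_ns) == pytest.approx(expected, abs=1e-12)


def test_f1_improvement_zero_baseline_undefined():
    with pytest.raises(ValueError):
        f1_improvement(0.5, 0.0)


def test_mb_increase():
    idx = ["P1", "P2"]
    # everyone doubles -> 100
    val, n_excl = mb_increase(pd.Series([20, 8], idx), pd.Series([10, 4], idx))
    assert val == pytest.approx(100.0, abs=1e-12) and n_excl == 0
    # (+50%, +150%) -> 100
    val, _ = mb_increase(pd.Series([15, 10], idx), pd.Series([10, 4], idx))
    assert val == pytest.approx(100.0, abs=1e-12)
    # no silent mutations anywhere -> 0
    val, _ = mb_increase(pd.Series([10, 4], idx), pd.Series([10, 4], idx))
    assert val == pytest.approx(0.0, abs=1e-12)
    # zero non-silent burden excluded and counted
    val, n_excl = mb_increase(pd.Series([10, 4], idx), pd.Series([10, 0], idx))
    assert val == pytest.approx(0.0, abs=1e-12) and n_excl == 1
    # all excluded -> missing
    val, n_excl = mb_increase(pd.Series([10], ["P1"]), pd.Series([0], ["P1"]))
    assert np.isnan(val) and n_excl == 1


def test_improvement_burden_correlation_linear_and_oracle():
    df = pd.DataFrame({"f1_improvement": [1.0, 2.0, 3.0, 4.0], "mb_increase": [2.0, 4.0, 6.0, 8.0]})
    r, p, r2 = improvement_burden_correlation(df)
    assert r == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    rng = np.random.default_rng(4)
    x = rng.random(10)
    y = rng.random(10)
    df = pd.DataFrame({"f1_improvement": x, "mb_increase": y})
    r, p, r2 = improvement_burden_correlation(df)
    # covariance-formula oracle
    oracle = np.cov(x, y, bias=True)[0, 1] / (x.std() * y.std())
    assert r == pytest.approx(oracle, abs=1e-12)
    assert r2 == pytest.approx(r * r, abs=1e-15)

    with pytest.raises(ValueError):
        improvement_burden_correlation(df.head(2))


def test_similarity_vs_misclassification_oracle_and_degenerate():
    from scipy import stats

    rng = np.random.default_rng(5)
    pairs = pd.DataFrame({"jaccard": rng.random(8), "misclassification": rng.random(8)})
    rho, p = similarity_vs_misclassification(pairs)
    oracle = stats.pearsonr(
        stats.rankdata(pairs["jaccard"]), stats.rankdata(pairs["misclassification"])
    ).statistic
    assert rho == pytest.approx(oracle, abs=1e-12)

    const = pd.DataFrame({"jaccard": [0.2] * 5, "misclassification": rng.random(5)})
    rho, p = similarity_vs_misclassification(const)
    assert np.isnan(rho)

    with pytest.raises(ValueError):
        similarity_vs_misclassification(pairs.head(2))
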