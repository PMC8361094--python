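"""Pairwise cohort similarity, misclassification and burden statistics.

For every unordered pair of cancer types the module estimates (a) the mean
Jaccard similarity between binary mutation profiles of randomly sampled
patients of the two types and (b) the two-class misclassification rate of
a boosted-tree model separating the pair under repeated stratified splits.
The Spearman correlation between the two across pairs quantifies how much
genetic-profile similarity drives misclassification.

Per cancer type, the relative F1 gain of the all-features model over the
non-silent model and the mean per-patient relative mutational-burden gain
from adding silent mutations are computed, and their Pearson correlation
across types assesses whether the F1 gain is a mere burden effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .feature_engineering import FeatureMatrix
from .ova_classification import SplitScheme, _confusion, _fit_lgbm

logger = logging.getLogger(__name__)

__all__ = [
    "JaccardPairResult",
    "MisclassPairResult",
    "jaccard",
    "jaccard_pair_protocol",
    "misclassification_protocol",
    "similarity_vs_misclassification",
    "f1_improvement",
    "mb_increase",
    "improvement_burden_correlation",
]


@dataclass(frozen=True)
class JaccardPairResult:
    type_a: str
    type_b: str
    per_repetition: tuple[float, ...]

    @property
    def jaccard(self) -> float:
        return float(np.mean(self.per_repetition))


@dataclass(frozen=True)
class MisclassPairResult:
    type_a: str
    type_b: str
    # per repetition: (|AA|, |AB|, |BA|, |BB|)
    confusion_counts: tuple[tuple[int, int, int, int], ...]

    @property
    def per_repetition(self) -> tuple[float, ...]:
        return tuple(
            (ab + ba) / (aa + bb + ab + ba) for aa, ab, ba, bb in self.confusion_counts
        )

    @property
    def misclassification_rate(self) -> float:
        return float(np.mean(self.per_repetition))


def jaccard(f_a: set, f_b: set) -> float:
    """|intersection| / |union| of two feature-id sets; 0 when both empty."""
    union = len(f_a) + len(f_b) - len(f_a & f_b)
    if union == 0:
        return 0.0
    return len(f_a & f_b) / union


def _patients_of_type(clinical: pd.DataFrame, cancer_type: str) -> list[str]:
    return clinical.loc[clinical["cancer_type"] == cancer_type, "patient_id"].tolist()


def _resolve_sample_size(requested: int, *cohort_sizes: int) -> int:
    size = min([requested, *cohort_sizes])
    if size < requested:
        logger.warning("sample size lowered from %d to %d (smallest cohort)", requested, size)
    return size


def jaccard_pair_protocol(
    features: FeatureMatrix,
    clinical: pd.DataFrame,
    type_a: str,
    type_b: str,
    seed: int = 0,
    sample_size: int = 100,
    n_repetitions: int = 5,
) -> JaccardPairResult:
    """Sampled mean pairwise Jaccard similarity between two cancer types.

    Per repetition ``sample_size`` patients are drawn without replacement
    from each type (fresh seed per repetition = base + index), every
    cross-group patient pair is scored and the scores averaged; the final
    value is the mean over repetitions.  Features are binarized before
    scoring — a patient's profile is the set of features with value 1.
    """
    binary = features.binarize()
    X = binary.values.astype(np.int64)
    pos = {p: i for i, p in enumerate(binary.patients)}
    a_all = [pos[p] for p in _patients_of_type(clinical, type_a)]
    b_all = [pos[p] for p in _patients_of_type(clinical, type_b)]
    size = _resolve_sample_size(sample_size, len(a_all), len(b_all))

    reps = []
    for rep in range(n_repetitions):
        rng = np.random.default_rng(seed + rep)
        a_idx = rng.choice(a_all, size=size, replace=False)
        b_idx = rng.choice(b_all, size=size, replace=False)
        Xa = X[a_idx]
        Xb = X[b_idx]
        inter = (Xa @ Xb.T).toarray().astype(float)
        sa = np.asarray(Xa.sum(axis=1)).ravel()
        sb = np.asarray(Xb.sum(axis=1)).ravel()
        union = sa[:, None] + sb[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            jac = np.where(union > 0, inter / np.where(union > 0, union, 1), 0.0)
        reps.append(float(jac.mean()))
    return JaccardPairResult(type_a=type_a, type_b=type_b, per_repetition=tuple(reps))


def misclassification_protocol(
    features: FeatureMatrix,
    clinical: pd.DataFrame,
    type_a: str,
    type_b: str,
    seed: int = 0,
    sample_size: int = 250,
    n_repetitions: int = 10,
    test_fraction: float = 0.3,
    learner_params: dict | None = None,
) -> MisclassPairResult:
    """Sampled two-class misclassification rate between two cancer types.

    Per repetition ``sample_size`` patients per type are drawn without
    replacement, stratified 0.7/0.3 split, a boosted-tree two-class model
    is fit on the training set, and the misclassification rate
    (|AB| + |BA|) / total is computed on the test set; the pair's rate is
    the mean over repetitions.
    """
    from sklearn.model_selection import StratifiedShuffleSplit

    X_full = features.values.astype(np.float64)
    pos = {p: i for i, p in enumerate(features.patients)}
    a_all = [pos[p] for p in _patients_of_type(clinical, type_a)]
    b_all = [pos[p] for p in _patients_of_type(clinical, type_b)]
    size = _resolve_sample_size(sample_size, len(a_all), len(b_all))
    params = dict(SplitScheme(learner_params=learner_params or {}).merged_params())

    reps = []
    for rep in range(n_repetitions):
        rng = np.random.default_rng(seed + rep)
        a_idx = rng.choice(a_all, size=size, replace=False)
        b_idx = rng.choice(b_all, size=size, replace=False)
        idx = np.concatenate([a_idx, b_idx])
        y = np.concatenate([np.ones(size, dtype=int), np.zeros(size, dtype=int)])  # 1 = A
        sss = StratifiedShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed + rep)
        train, test = next(sss.split(np.zeros(len(y)), y))
        model = _fit_lgbm(X_full[idx[train]], y[train], seed + rep, params)
        y_pred = np.asarray(model.predict(X_full[idx[test]]))
        tp, fp, tn, fn = _confusion(y[test], y_pred)
        # A is the positive class: AA=tp, AB=fn (A called B), BA=fp, BB=tn
        reps.append((tp, fn, fp, tn))
    return MisclassPairResult(type_a=type_a, type_b=type_b, confusion_counts=tuple(reps))


def similarity_vs_misclassification(pairs: pd.DataFrame) -> tuple[float, float]:
    """Spearman rho between J and M across unordered type pairs.

    ``pairs`` needs columns ``jaccard`` and ``misclassification``.  With
    fewer than 3 pairs the correlation is an error; with a constant J (or
    M) it is undefined and reported missing.
    """
    if len(pairs) < 3:
        raise ValueError("need >= 3 type pairs for a correlation")
    j = pairs["jaccard"].to_numpy(float)
    m = pairs["misclassification"].to_numpy(float)
    if np.allclose(j, j[0]) or np.allclose(m, m[0]):
        logger.warning("degenerate similarity/misclassification values; correlation undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(j, m)
    return float(rho), float(p)


def f1_improvement(f1_all: float, f1_non_silent: float) -> float:
    """Signed percent F1 gain of the all-features model over non-silent."""
    if f1_non_silent <= 0:
        raise ValueError("non-silent F1 must be positive for a relative improvement")
    return (f1_all - f1_non_silent) / f1_non_silent * 100.0


def mb_increase(
    burden_all: pd.Series,
    burden_non_silent: pd.Series,
) -> tuple[float, int]:
    """Mean per-patient percent mutational-burden gain from silent mutations.

    Both inputs are per-patient total mutation counts over the same
    patients.  Patients with zero non-silent burden are excluded (their
    relative increase is undefined); the count of exclusions is returned.
    """
    ns = burden_non_silent.reindex(burden_all.index)
    valid = ns > 0
    n_excluded = int((~valid).sum())
    if valid.sum() == 0:
        return float("nan"), n_excluded
    rel = (burden_all[valid] - ns[valid]) / ns[valid] * 100.0
    return float(rel.mean()), n_excluded


def improvement_burden_correlation(records: pd.DataFrame) -> tuple[float, float, float]:
    """Pearson r (and p, r^2) between F1 improvement and burden increase.

    ``records`` needs columns ``f1_improvement`` and ``mb_increase``, one
    row per cancer type; fewer than 3 types is an error.
    """
    if len(records) < 3:
        raise ValueError("need >= 3 cancer types for a correlation")
    r, p = stats.pearsonr(
        records["f1_improvement"].to_numpy(float), records["mb_increase"].to_numpy(float)
    )
    return float(r), float(p), float(r * r)
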