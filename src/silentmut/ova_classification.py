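"""One-vs-all cancer-type classifiers with matched null baselines.

For every (cancer type, dataset) pair a gradient-boosted decision-tree
ensemble is trained to separate that type ("positive") from all other
included types pooled ("negative"), under a repeated stratified 0.7/0.3
split protocol (10 repeats by default).  Performance is summarised by
accuracy, precision P, recall R and F1 = 2PR/(P+R), averaged across
repeats.  The null baseline guesses each test patient's label
independently with the training-set positive fraction, so its expected
precision and recall both equal that fraction.

Models sharing a (cancer type, repeat) use the same patient partition, so
comparisons between datasets are paired.  Feature importance is the mean
gain-based importance across repeats, with ties broken lexicographically
by feature id for reproducible rankings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

from .feature_engineering import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SplitScheme",
    "ClassificationMetrics",
    "ModelResult",
    "make_ova_labels",
    "train_ova",
    "null_model",
    "compute_metrics",
    "resolution_ablation",
    "balanced_protocol",
]

DEFAULT_MIN_COHORT = 200  # a type must exceed this to be classified

# Frozen learner configuration: LightGBM defaults plus single-threaded,
# seed-controlled execution so repeated runs are bit-identical.
DEFAULT_LEARNER_PARAMS: Mapping[str, object] = {
    "n_estimators": 100,
    "n_jobs": 1,
    "verbose": -1,
    "deterministic": True,
    "force_row_wise": True,
}


@dataclass(frozen=True)
class SplitScheme:
    """Repeated stratified splitting protocol."""

    n_repeats: int = 10
    test_fraction: float = 0.3
    base_seed: int = 0
    learner_params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")

    def splits(self, labels: np.ndarray):
        """Yield (train_idx, test_idx) per repeat; repeat i is seeded base+i.

        A degenerate split (single-class training set) is resampled with an
        incremented seed.
        """
        n = len(labels)
        for rep in range(self.n_repeats):
            seed = self.base_seed + rep
            while True:
                sss = StratifiedShuffleSplit(
                    n_splits=1, test_size=self.test_fraction, random_state=seed
                )
                train_idx, test_idx = next(sss.split(np.zeros(n), labels))
                if len(np.unique(labels[train_idx])) > 1:
                    yield train_idx, test_idx
                    break
                logger.warning("degenerate split at repeat %d; reseeding", rep)
                seed += self.n_repeats

    def merged_params(self) -> dict:
        params = dict(DEFAULT_LEARNER_PARAMS)
        params.update(self.learner_params)
        return params


@dataclass(frozen=True)
class ClassificationMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


@dataclass
class ModelResult:
    """Averaged outcome of one (cancer type, dataset) run."""

    cancer_type: str
    dataset: str
    per_repeat: list[ClassificationMetrics]
    importances: pd.Series  # mean gain importance per feature, index = feature id

    @property
    def mean_metrics(self) -> ClassificationMetrics:
        return ClassificationMetrics(
            accuracy=float(np.mean([m.accuracy for m in self.per_repeat])),
            precision=float(np.mean([m.precision for m in self.per_repeat])),
            recall=float(np.mean([m.recall for m in self.per_repeat])),
            f1=float(np.mean([m.f1 for m in self.per_repeat])),
        )

    def ranked_importances(self) -> pd.Series:
        """Importances sorted descending, ties broken by feature id."""
        df = self.importances.rename("importance").rename_axis("feature_id").reset_index()
        df = df.sort_values(["importance", "feature_id"], ascending=[False, True])
        return df.set_index("feature_id")["importance"]


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> ClassificationMetrics:
    """Accuracy/precision/recall/F1 from confusion counts.

    Precision and recall fall back to 0 on an empty denominator, and F1 is
    0 whenever P + R = 0 (either score being zero zeroes the harmonic mean).
    """
    total = tp + fp + tn + fn
    if total <= 0:
        raise ValueError("confusion counts sum to zero")
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return ClassificationMetrics(
        accuracy=(tp + tn) / total, precision=precision, recall=recall, f1=f1
    )


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, fp, tn, fn


def make_ova_labels(
    clinical: pd.DataFrame,
    cancer_type: str,
    patients: Sequence[str],
    min_cohort: int = DEFAULT_MIN_COHORT,
) -> pd.Series | None:
    """Binary one-vs-all labels over ``patients`` (1 = the given type).

    Returns ``None`` (with a logged reason) when the type's cohort does not
    exceed ``min_cohort`` patients.
    """
    type_of = clinical.set_index("patient_id")["cancer_type"]
    labels = (type_of.reindex(patients) == cancer_type).astype(int)
    labels.index.name = "patient_id"
    n_pos = int(labels.sum())
    if n_pos <= min_cohort:
        logger.info(
            "skipping %s: cohort size %d does not exceed threshold %d",
            cancer_type,
            n_pos,
            min_cohort,
        )
        return None
    return labels


def _fit_lgbm(X, y, seed: int, params: Mapping[str, object]):
    from lightgbm import LGBMClassifier

    model = LGBMClassifier(random_state=seed, **params)
    model.fit(X, y)
    return model


def train_ova(
    features: FeatureMatrix,
    labels: pd.Series,
    scheme: SplitScheme,
    cancer_type: str = "",
    dataset: str = "",
) -> ModelResult:
    """Repeatedly fit a boosted-tree OVA model and average the outcomes."""
    y = labels.reindex(features.patients).to_numpy(dtype=int)
    X = features.values.astype(np.float64)
    params = scheme.merged_params()
    per_repeat: list[ClassificationMetrics] = []
    gain = np.zeros(X.shape[1])
    for rep, (train_idx, test_idx) in enumerate(scheme.splits(y)):
        model = _fit_lgbm(X[train_idx], y[train_idx], scheme.base_seed + rep, params)
        y_pred = model.predict(X[test_idx])
        per_repeat.append(compute_metrics(*_confusion(y[test_idx], np.asarray(y_pred))))
        booster = model.booster_
        gain += booster.feature_importance(importance_type="gain")
    importances = pd.Series(gain / scheme.n_repeats, index=features.meta.index)
    return ModelResult(
        cancer_type=cancer_type, dataset=dataset, per_repeat=per_repeat, importances=importances
    )


def null_model(labels: pd.Series | np.ndarray, scheme: SplitScheme) -> ModelResult:
    """Label-distribution guessing baseline.

    Per repeat: the same stratified split as the real model, then each test
    patient is called positive independently with probability equal to the
    training positive fraction.  Expected precision and recall both equal
    that fraction, so the expected F1 is the positive prevalence.
    """
    y = np.asarray(labels, dtype=int) if not isinstance(labels, pd.Series) else labels.to_numpy(int)
    per_repeat = []
    for rep, (train_idx, test_idx) in enumerate(scheme.splits(y)):
        rng = np.random.default_rng(scheme.base_seed + 7919 * (rep + 1))
        p = float(y[train_idx].mean())
        y_pred = (rng.random(len(test_idx)) < p).astype(int)
        per_repeat.append(compute_metrics(*_confusion(y[test_idx], y_pred)))
    return ModelResult(
        cancer_type="", dataset="null", per_repeat=per_repeat,
        importances=pd.Series(dtype=float),
    )


RESOLUTION_SETS: tuple[tuple[str, ...], ...] = (
    ("HIGH",),
    ("HIGH", "MEDIUM"),
    ("HIGH", "MEDIUM", "LOW"),
)


def resolution_ablation(
    features: FeatureMatrix,
    labels: pd.Series,
    scheme: SplitScheme,
    cancer_type: str = "",
    dataset: str = "",
) -> pd.DataFrame:
    """Mean F1 using high-only, high+medium and all-resolution features.

    All three runs share the same splits per repeat (the scheme is seeded),
    so resolution comparisons are paired.
    """
    rows = []
    for res_set in RESOLUTION_SETS:
        keep = features.meta.index[features.meta["resolution"].isin(res_set)]
        sub = features.select_features(list(keep))
        result = train_ova(sub, labels, scheme, cancer_type, dataset)
        rows.append(
            {
                "cancer_type": cancer_type,
                "dataset": dataset,
                "resolutions": "+".join(res_set),
                "n_features": sub.shape[1],
                "mean_f1": result.mean_metrics.f1,
            }
        )
    return pd.DataFrame(rows)


def balanced_protocol(
    datasets: Mapping[str, FeatureMatrix],
    labels: pd.Series,
    scheme: SplitScheme,
    feature_budget: int | str = "auto",
    selection_seed: int | None = None,
) -> tuple[dict[str, ModelResult], int]:
    """Equal-width datasets controlling for feature-count imbalance.

    Only high-resolution features are used.  Patients are split into two
    equal stratified halves: a model trained on the first half ranks each
    single-category dataset's features and the top K are retained
    (``feature_budget='auto'`` sets K to the size of the smallest category's
    high-resolution feature set); the balanced datasets — five of width K
    plus the balanced "all" dataset concatenating the five selections (5K
    features) — are then evaluated on the second half under the usual
    repeated-split scheme.  Selection and evaluation halves are disjoint.
    """
    single = {name: fm for name, fm in datasets.items() if name != "all"}
    high = {}
    for name, fm in single.items():
        keep = fm.meta.index[fm.meta["resolution"] == "HIGH"]
        high[name] = fm.select_features(list(keep))

    sizes = {name: fm.shape[1] for name, fm in high.items()}
    if feature_budget == "auto":
        K = min(sizes.values())
    else:
        K = int(feature_budget)
        if K > min(sizes.values()):
            logger.warning(
                "feature budget %d exceeds smallest category size %d; lowering",
                K,
                min(sizes.values()),
            )
            K = min(sizes.values())
    if K < 1:
        raise ValueError("no high-resolution features available for the balanced protocol")

    patients = next(iter(high.values())).patients
    y = labels.reindex(patients).to_numpy(dtype=int)
    seed = scheme.base_seed if selection_seed is None else selection_seed
    sss = StratifiedShuffleSplit(n_splits=1, test_size=0.5, random_state=seed)
    half1_idx, half2_idx = next(sss.split(np.zeros(len(y)), y))
    half1 = [patients[i] for i in half1_idx]
    half2 = [patients[i] for i in half2_idx]

    params = SplitScheme(
        n_repeats=1, test_fraction=scheme.test_fraction, base_seed=seed,
        learner_params=scheme.learner_params,
    )
    selections: dict[str, list[str]] = {}
    for name, fm in high.items():
        sel_result = train_ova(fm.select_patients(half1), labels.reindex(half1), params)
        ranked = sel_result.ranked_importances()
        selections[name] = list(ranked.index[:K])

    results: dict[str, ModelResult] = {}
    for name, fm in high.items():
        balanced = fm.select_patients(half2).select_features(selections[name])
        assert balanced.shape[1] == K
        results[name] = train_ova(balanced, labels.reindex(half2), scheme, dataset=f"balanced_{name}")
    all_parts = [
        high[name].select_patients(half2).select_features(selections[name]) for name in high
    ]
    from .feature_engineering import assemble_dataset

    balanced_all = assemble_dataset(all_parts)
    results["all"] = train_ova(balanced_all, labels.reindex(half2), scheme, dataset="balanced_all")
    return results, K
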