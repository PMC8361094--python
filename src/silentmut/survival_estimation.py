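"""Random-survival-forest survival estimation with time-dependent AUC.

All cancer types are pooled into a single cohort; the model sees only
genomic features (never the cancer type or any clinical covariate).
Labels pair an event indicator (deceased/censored) with days since the
initial diagnosis; patients with no follow-up after diagnosis or who died
fewer than 20 days after diagnosis are excluded.  A random survival
forest (log-rank splitting on Kaplan-Meier estimates, 60 trees, maximum
depth 32) is fit under a repeated 0.7/0.3 split protocol (5 repeats) and
held-out per-patient survival curves are averaged across the repeats in
which the patient was held out.  Performance is the cumulative/dynamic
AUC at ten fixed horizons (100..4500 days), compared against a
covariate-free null whose expected AUC is 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_engineering import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RSFConfig",
    "DEFAULT_TIME_GRID",
    "build_survival_labels",
    "select_survival_features",
    "fit_rsf",
    "SurvivalFit",
    "time_dependent_auc",
    "null_survival_auc",
    "rsf_feature_importance",
]

DEFAULT_TIME_GRID: tuple[float, ...] = (100, 500, 1000, 1500, 2000, 2500, 3000, 3500, 4000, 4500)

MIN_DAYS_AFTER_DIAGNOSIS = 20


@dataclass(frozen=True)
class RSFConfig:
    """Random-survival-forest and protocol hyperparameters."""

    n_trees: int = 60
    max_depth: int = 32
    n_repeats: int = 5
    test_fraction: float = 0.3
    seed: int = 0
    min_samples_leaf: int = 3

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.max_depth < 1:
            raise ValueError("n_trees and max_depth must be >= 1")


def build_survival_labels(
    clinical: pd.DataFrame,
    min_days: int = MIN_DAYS_AFTER_DIAGNOSIS,
) -> tuple[pd.DataFrame, dict]:
    """Event/time labels with exclusions, pooling all cancer types.

    Deceased patients contribute (event=1, days_to_death); alive patients
    contribute (event=0, days_to_last_followup).  Excluded and counted:
    patients with no time information after diagnosis (missing or
    non-positive time) and deceased patients with time < ``min_days``
    (day ``min_days`` exactly is included — the rule is strict "less
    than").
    """
    rows = []
    report = {"n_input": len(clinical), "no_followup": 0, "early_death": 0}
    for rec in clinical.itertuples(index=False):
        deceased = rec.vital_status == "deceased"
        time = rec.days_to_death if deceased else rec.days_to_last_followup
        if time is None or pd.isna(time) or float(time) <= 0:
            report["no_followup"] += 1
            continue
        time = float(time)
        if deceased and time < min_days:
            report["early_death"] += 1
            continue
        rows.append({"patient_id": rec.patient_id, "event": int(deceased), "time": time})
    labels = pd.DataFrame(rows, columns=["patient_id", "event", "time"])
    report["n_included"] = len(labels)
    logger.info("survival labels: %s", report)
    return labels, report


def select_survival_features(
    dataset: FeatureMatrix,
    n_high: int = 5000,
) -> FeatureMatrix:
    """All low-resolution features plus the most prevalent high-resolution ones.

    High-resolution features are ranked by carrier count (mutation
    prevalence in the cohort); the top ``n_high`` are kept, ties at the
    cutoff broken by lexicographically smaller feature id.  Medium
    resolution is excluded.  If fewer than ``n_high`` high-resolution
    features exist, all are taken.
    """
    meta = dataset.meta
    low_ids = list(meta.index[meta["resolution"] == "LOW"])
    high_ids = list(meta.index[meta["resolution"] == "HIGH"])
    if len(high_ids) <= n_high:
        if len(high_ids) < n_high:
            logger.info("only %d high-resolution features available (< %d); taking all", len(high_ids), n_high)
        chosen_high = sorted(high_ids)
    else:
        carriers = dataset.carrier_counts().loc[high_ids]
        order = sorted(high_ids, key=lambda f: (-carriers[f], f))
        chosen_high = order[:n_high]
    return dataset.select_features(low_ids + chosen_high)


@dataclass
class SurvivalFit:
    """Held-out survival-probability curves averaged over repeats."""

    time_grid: tuple[float, ...]
    # patients x grid, NaN where a patient was never held out
    curves: pd.DataFrame
    labels: pd.DataFrame  # event/time indexed by patient_id
    models: list = field(default_factory=list)
    test_sets: list = field(default_factory=list)  # patient-index arrays per repeat
    feature_ids: list[str] = field(default_factory=list)


def _stratified_split(event: np.ndarray, test_fraction: float, seed: int):
    from sklearn.model_selection import StratifiedShuffleSplit

    while True:
        sss = StratifiedShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed)
        train, test = next(sss.split(np.zeros(len(event)), event))
        if event[train].sum() > 0:
            return train, test
        logger.warning("no events in training split (seed %d); resampling", seed)
        seed += 1000


def fit_rsf(
    features: FeatureMatrix,
    labels: pd.DataFrame,
    config: RSFConfig = RSFConfig(),
    time_grid: Sequence[float] = DEFAULT_TIME_GRID,
    keep_models: bool = True,
) -> SurvivalFit:
    """Fit random survival forests under the repeated-split protocol.

    Splits are stratified by event status.  Each repetition's forest
    predicts survival curves for its held-out patients, evaluated on the
    time grid (clipped to the training follow-up range, where the forest's
    step function is defined); a patient's final curve is the average over
    the repetitions in which they were held out.  Deterministic for a
    fixed seed.
    """
    from sksurv.ensemble import RandomSurvivalForest

    common = [p for p in features.patients if p in set(labels["patient_id"])]
    if len(common) < len(features.patients):
        features = features.select_patients(common)
    lab = labels.set_index("patient_id").loc[common]
    event = lab["event"].to_numpy(int)
    time = lab["time"].to_numpy(float)
    if len(common) < 50:
        raise ValueError("need >= 50 patients for survival estimation")
    if event.sum() < 10:
        raise ValueError("need >= 10 events for survival estimation")

    X = features.values.toarray().astype(np.float64)
    grid = np.asarray(sorted(time_grid), dtype=float)
    sums = np.zeros((len(common), len(grid)))
    counts = np.zeros((len(common), len(grid)))
    models, test_sets = [], []
    y_struct = np.empty(len(common), dtype=[("event", bool), ("time", float)])
    y_struct["event"] = event.astype(bool)
    y_struct["time"] = time

    for rep in range(config.n_repeats):
        train, test = _stratified_split(event, config.test_fraction, config.seed + rep)
        forest = RandomSurvivalForest(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            min_samples_leaf=config.min_samples_leaf,
            n_jobs=1,
            random_state=config.seed + rep,
        )
        forest.fit(X[train], y_struct[train])
        surv_fns = forest.predict_survival_function(X[test])
        eval_times = np.clip(grid, float(forest.unique_times_[0]), float(forest.unique_times_[-1]))
        for row, fn in zip(test, surv_fns):
            s = fn(eval_times)
            sums[row] += s
            counts[row] += 1
        if keep_models:
            models.append(forest)
            test_sets.append(test)

    with np.errstate(invalid="ignore"):
        mean_curves = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    curves = pd.DataFrame(mean_curves, index=pd.Index(common, name="patient_id"), columns=grid)
    return SurvivalFit(
        time_grid=tuple(grid),
        curves=curves,
        labels=lab.reset_index(),
        models=models,
        test_sets=test_sets,
        feature_ids=features.feature_ids,
    )


def time_dependent_auc(
    curves: pd.DataFrame,
    labels: pd.DataFrame,
    time_grid: Sequence[float] | None = None,
) -> pd.Series:
    """Cumulative/dynamic AUC of risk = 1 - S(t) at each grid time.

    At horizon t, cases are patients with an observed event by t and
    controls are patients still at risk beyond t; patients censored before
    t are omitted from both sets.  The AUC is the fraction of comparable
    case-control pairs in which the case has the higher risk, ties counted
    as 0.5 — an unweighted concordance (no censoring weights).  A time
    with no comparable pairs is reported missing.
    """
    lab = labels.set_index("patient_id").loc[curves.index]
    event = lab["event"].to_numpy(int)
    time = lab["time"].to_numpy(float)
    grid = list(curves.columns) if time_grid is None else list(time_grid)
    out = {}
    for t in grid:
        risk = 1.0 - curves[t].to_numpy(float)
        known = ~np.isnan(risk)
        cases = known & (event == 1) & (time <= t)
        controls = known & (time > t)
        if cases.sum() == 0 or controls.sum() == 0:
            out[t] = np.nan
            continue
        rc = risk[cases][:, None]
        rk = risk[controls][None, :]
        wins = (rc > rk).sum() + 0.5 * (rc == rk).sum()
        out[t] = float(wins / (cases.sum() * controls.sum()))
    return pd.Series(out, name="auc").rename_axis("time")


def null_survival_auc(
    labels: pd.DataFrame,
    time_grid: Sequence[float] = DEFAULT_TIME_GRID,
    seed: int = 0,
    n_repetitions: int = 100,
) -> pd.Series:
    """Covariate-independent random-risk baseline (expected AUC 0.5).

    Risk scores are drawn independently of all features; the AUC at each
    grid time is averaged over repetitions.
    """
    rng = np.random.default_rng(seed)
    grid = sorted(time_grid)
    acc = pd.Series(0.0, index=pd.Index(grid, name="time"))
    n_valid = pd.Series(0, index=acc.index)
    for _ in range(n_repetitions):
        risk = rng.random(len(labels))
        curves = pd.DataFrame(
            1.0 - np.tile(risk[:, None], (1, len(grid))),
            index=pd.Index(labels["patient_id"], name="patient_id"),
            columns=grid,
        )
        auc = time_dependent_auc(curves, labels)
        valid = auc.notna()
        acc[valid] += auc[valid]
        n_valid[valid] += 1
    with np.errstate(invalid="ignore"):
        return (acc / n_valid.replace(0, np.nan)).rename("auc")


def rsf_feature_importance(
    fit: SurvivalFit,
    features: FeatureMatrix,
    n_permutations: int = 3,
    seed: int = 0,
) -> pd.Series:
    """Permutation importance on held-out concordance, averaged over repeats.

    For each repetition's forest and test set, the drop in Harrell
    concordance of the forest's risk score when one feature column is
    permuted, averaged over permutations and repetitions.  Sorted
    descending, ties broken by feature id.
    """
    from sksurv.metrics import concordance_index_censored

    if not fit.models:
        raise ValueError("fit was run with keep_models=False; no forests retained")
    lab = fit.labels.set_index("patient_id").loc[list(fit.curves.index)]
    event = lab["event"].to_numpy(bool)
    time = lab["time"].to_numpy(float)
    X = features.select_patients(list(fit.curves.index)).values.toarray().astype(np.float64)
    n_features = X.shape[1]
    importance = np.zeros(n_features)
    rng = np.random.default_rng(seed)

    for forest, test in zip(fit.models, fit.test_sets):
        Xt = X[test]
        ev, tt = event[test], time[test]
        base = concordance_index_censored(ev, tt, forest.predict(Xt))[0]
        for j in range(n_features):
            drop = 0.0
            for _ in range(n_permutations):
                Xp = Xt.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                c = concordance_index_censored(ev, tt, forest.predict(Xp))[0]
                drop += base - c
            importance[j] += drop / n_permutations
    importance /= len(fit.models)
    series = pd.Series(importance, index=pd.Index(fit.feature_ids, name="feature_id"))
    order = sorted(series.index, key=lambda f: (-series[f], f))
    return series.loc[order]
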