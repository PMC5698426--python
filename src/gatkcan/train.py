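"""Threshold training: fitness, PSO search, cross-validation, α selection.

Functional surface over :class:`gatkcan.estimators.PSOThresholdClassifier`.
The training inputs are labeled feature frames (one row per called variant,
``label`` 1 = true mutation) as produced by
:func:`gatkcan.features.build_feature_frame`.

The SNV procedure: stratified-sample tumors by stage (2/3/2/3 for stages
I–IV), sweep α from 0 to 1 in steps of 0.1 with leave-one-tumor-out
cross-validation, select α, then retrain on all sampled tumors. The indel
procedure trains on a seeded split of 50 reported + 10 artifact indels and
evaluates on the remainder, following the SNV procedure otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimators import (
    PSOConfig,
    PSOThresholdClassifier,
    SearchSpace,
    ThresholdRuleClassifier,
    _as_columns,
    pso_search,
)
from .metrics import confusion_from_arrays, metric_set, rates
from .types import ConfusionCounts, MetricSet, ThresholdSet

__all__ = [
    "TrainingPlan",
    "PSOResult",
    "CVResult",
    "TrainResult",
    "fitness",
    "pso_optimize",
    "cross_validate",
    "select_alpha",
    "train_snv",
    "train_indel",
]

DEFAULT_ALPHA_GRID = tuple(round(0.1 * k, 1) for k in range(11))


@dataclass(frozen=True)
class TrainingPlan:
    """Sampling scheme for training: tumors per stage, α grid, indel split."""

    tumors_per_stage: Mapping[str, int] = field(
        default_factory=lambda: {"I": 2, "II": 3, "III": 2, "IV": 3}
    )
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    indel_n_reported: int = 50
    indel_n_artifacts: int = 10

    def __post_init__(self) -> None:
        if not self.alpha_grid or self.alpha_grid[0] != 0.0 or self.alpha_grid[-1] != 1.0:
            raise ValueError("alpha grid must span 0 to 1")


@dataclass(frozen=True)
class PSOResult:
    thresholds: ThresholdSet
    fitness: float
    trajectory: np.ndarray


@dataclass(frozen=True)
class CVResult:
    fold_metrics: tuple[MetricSet, ...]
    fold_tumors: tuple[str, ...]
    mean_fitness: float

    @property
    def mean_mcc(self) -> float:
        return float(np.mean([m.mcc for m in self.fold_metrics]))


@dataclass(frozen=True)
class TrainResult:
    thresholds: ThresholdSet
    alpha: float
    fitness: float
    trajectory: np.ndarray
    cv_results: pd.DataFrame | None
    sampled_tumors: tuple[str, ...] | None = None
    test_metrics: MetricSet | None = None


def fitness(m: MetricSet | ConfusionCounts, alpha: float) -> float:
    """The training objective α(1−cFPR) + (1−α)TPR, in [0, 1]."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if isinstance(m, ConfusionCounts):
        m = rates(m)
    return alpha * (1.0 - m.cfpr) + (1.0 - alpha) * m.tpr


def _require_labeled(df: pd.DataFrame) -> np.ndarray:
    if "label" not in df.columns:
        raise ValueError("training frame needs a 'label' column (1 = true mutation)")
    y = df["label"].to_numpy(dtype=int)
    if y.size == 0 or y.min() == y.max():
        raise ValueError("training data must contain both true mutations and artifacts")
    return y


def pso_optimize(
    train: pd.DataFrame,
    alpha: float,
    space: SearchSpace | None = None,
    cfg: PSOConfig = PSOConfig(),
    scope: str = "snv",
) -> PSOResult:
    """Swarm-optimize one ThresholdSet at fixed α on a labeled frame.

    Deterministic for a fixed ``cfg.seed``. ``trajectory`` holds the
    best-so-far fitness per generation (initial population included).
    """
    y = _require_labeled(train)
    space = space if space is not None else SearchSpace.default(scope)
    cols = _as_columns(train)
    rng = np.random.default_rng(np.random.SeedSequence(0 if cfg.seed is None else cfg.seed))
    vec, best, trajectory = pso_search(cols, y, alpha, space, cfg, rng)
    rule = ThresholdRuleClassifier(
        scope=scope, alpha=alpha, **{d: float(v) for d, v in zip(space.dims(), vec)}
    ).fit()
    return PSOResult(rule.to_threshold_set(), best, trajectory)


def cross_validate(
    tumors: pd.DataFrame,
    alpha: float,
    space: SearchSpace | None = None,
    cfg: PSOConfig = PSOConfig(),
    scope: str = "snv",
) -> CVResult:
    """Leave-one-tumor-out cross-validation at fixed α.

    Fold i trains the swarm on every tumor but i and evaluates on tumor i.
    """
    _require_labeled(tumors)
    tumor_ids = list(pd.unique(tumors["tumor_id"]))
    if len(tumor_ids) < 2:
        raise ValueError("cross-validation needs at least 2 tumors")
    space = space if space is not None else SearchSpace.default(scope)
    ss = np.random.SeedSequence(0 if cfg.seed is None else cfg.seed)
    children = ss.spawn(len(tumor_ids))
    fold_metrics: list[MetricSet] = []
    fold_fitness: list[float] = []
    for child, held_out in zip(children, tumor_ids):
        train_df = tumors[tumors["tumor_id"] != held_out]
        test_df = tumors[tumors["tumor_id"] == held_out]
        y_train = _require_labeled(train_df)
        rng = np.random.default_rng(child)
        vec, _, _ = pso_search(_as_columns(train_df), y_train, alpha, space, cfg, rng)
        rule = ThresholdRuleClassifier(
            scope=scope, alpha=alpha, **{d: float(v) for d, v in zip(space.dims(), vec)}
        ).fit()
        pred = rule.predict(test_df)
        m = metric_set(confusion_from_arrays(pred, test_df["label"].to_numpy(dtype=int)))
        fold_metrics.append(m)
        fold_fitness.append(fitness(m, alpha))
    return CVResult(tuple(fold_metrics), tuple(map(str, tumor_ids)), float(np.mean(fold_fitness)))


def select_alpha(
    cv_results: Mapping[float, Sequence[MetricSet]], criterion: str = "mcc"
) -> float:
    """The α maximizing the mean cross-validated criterion; ties go to smaller α."""
    if not cv_results:
        raise ValueError("empty cross-validation results")
    means = {
        float(a): float(np.mean([getattr(m, criterion) for m in folds]))
        for a, folds in cv_results.items()
    }
    best = max(means.values())
    return min(a for a, v in means.items() if v >= best - 1e-12)


def _stratified_tumor_sample(
    tumors: pd.DataFrame, plan: TrainingPlan, rng: np.random.Generator
) -> list[str]:
    if "stage" not in tumors.columns:
        raise ValueError("cohort frame needs a 'stage' column for stratified sampling")
    stage_of = tumors.drop_duplicates("tumor_id").set_index("tumor_id")["stage"]
    sampled: list[str] = []
    for stage, k in plan.tumors_per_stage.items():
        pool = sorted(stage_of.index[stage_of == stage])
        if len(pool) < k:
            raise ValueError(f"stage {stage}: need {k} tumors, have {len(pool)}")
        idx = rng.choice(len(pool), size=k, replace=False)
        sampled.extend(pool[i] for i in sorted(idx))
    return sampled


def _fit_estimator(
    df: pd.DataFrame,
    scope: str,
    plan: TrainingPlan,
    space: SearchSpace | None,
    cfg: PSOConfig,
    groups,
) -> PSOThresholdClassifier:
    est = PSOThresholdClassifier(
        scope=scope,
        alpha=None,
        alpha_grid=plan.alpha_grid,
        space=space,
        n_particles=cfg.n_particles,
        n_generations=cfg.n_generations,
        inertia=cfg.inertia,
        cognitive=cfg.cognitive,
        social=cfg.social,
        random_state=0 if cfg.seed is None else cfg.seed,
    )
    est.fit(df, df["label"].to_numpy(dtype=int), groups=groups)
    return est


def train_snv(
    cohort: pd.DataFrame,
    plan: TrainingPlan = TrainingPlan(),
    space: SearchSpace | None = None,
    cfg: PSOConfig = PSOConfig(),
) -> TrainResult:
    """Full SNV training: stratified tumor sampling, α sweep with
    leave-one-tumor-out CV, final retrain on all sampled tumors.

    ``cohort`` is a labeled feature frame with ``tumor_id`` and ``stage``
    columns covering at least the per-stage tumor counts in ``plan``.
    """
    _require_labeled(cohort)
    rng = np.random.default_rng(
        np.random.SeedSequence([0 if cfg.seed is None else cfg.seed, 11])
    )
    sampled = _stratified_tumor_sample(cohort, plan, rng)
    sub = cohort[cohort["tumor_id"].isin(sampled)]
    snv = sub[sub["variant_class"] == "SNV"] if "variant_class" in sub.columns else sub
    est = _fit_estimator(snv, "snv", plan, space, cfg, groups=snv["tumor_id"].to_numpy())
    return TrainResult(
        thresholds=est.thresholds_,
        alpha=est.alpha_,
        fitness=est.fitness_,
        trajectory=est.trajectory_,
        cv_results=est.cv_results_,
        sampled_tumors=tuple(sampled),
    )


def train_indel(
    reported_indels: pd.DataFrame,
    artifact_indels: pd.DataFrame,
    plan: TrainingPlan = TrainingPlan(),
    space: SearchSpace | None = None,
    cfg: PSOConfig = PSOConfig(),
) -> TrainResult:
    """Indel training on a seeded 50 reported + 10 artifact split.

    The remaining reported and artifact indels form the held-out test set on
    which ``test_metrics`` are computed. Training folds for the α sweep are
    a seeded 10-way partition of the 60 training variants (indels carry no
    tumor grouping here).
    """
    n_rep, n_art = plan.indel_n_reported, plan.indel_n_artifacts
    if len(reported_indels) < n_rep or len(artifact_indels) < n_art:
        raise ValueError(
            f"need at least {n_rep} reported and {n_art} artifact indels, "
            f"got {len(reported_indels)} and {len(artifact_indels)}"
        )
    rng = np.random.default_rng(
        np.random.SeedSequence([0 if cfg.seed is None else cfg.seed, 13])
    )
    rep = reported_indels.assign(label=1).reset_index(drop=True)
    art = artifact_indels.assign(label=0).reset_index(drop=True)
    rep_idx = rng.choice(len(rep), size=n_rep, replace=False)
    art_idx = rng.choice(len(art), size=n_art, replace=False)
    train_df = pd.concat([rep.iloc[sorted(rep_idx)], art.iloc[sorted(art_idx)]])
    test_df = pd.concat(
        [rep.drop(index=rep_idx), art.drop(index=art_idx)], ignore_index=True
    )
    est = _fit_estimator(train_df, "indel", plan, space, cfg, groups=None)
    test_metrics = None
    if len(test_df):
        pred = est.predict(test_df)
        test_metrics = metric_set(
            confusion_from_arrays(pred, test_df["label"].to_numpy(dtype=int))
        )
    return TrainResult(
        thresholds=est.thresholds_,
        alpha=est.alpha_,
        fitness=est.fitness_,
        trajectory=est.trajectory_,
        cv_results=est.cv_results_,
        test_metrics=test_metrics,
    )
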