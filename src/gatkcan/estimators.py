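"""Scikit-learn style estimators at the core of the toolkit.

Three classifiers over per-variant feature rows (label 1 = true mutation,
0 = artifact):

``HardFilterClassifier``
    The fixed GATK hard-filter rules (no training).
``ThresholdRuleClassifier``
    The catalog-aware decision rule with explicit cutoffs: the dNM == 0
    shortcut, then strict cutoff comparisons on FS, QD, dNM band, the
    cohort strand-test P, and (for SNVs) MQ and MQRankSum.
``PSOThresholdClassifier``
    Learns the cutoffs by particle swarm optimization of the fitness
    α·(1−cFPR) + (1−α)·TPR over a discretized search space, selecting α by
    grouped cross-validation when not fixed.

Feature rows may be a DataFrame with the named columns or a plain array in
``FEATURE_COLUMNS`` order. Missing statistics (NaN) pass every cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .types import (
    Label,
    Prediction,
    ThresholdSet,
    VariantClass,
    STAT_DNM,
    STAT_FS,
    STAT_MQ,
    STAT_MQRANKSUM,
    STAT_MW,
    STAT_QD,
    STAT_READPOS,
)

__all__ = [
    "FEATURE_COLUMNS",
    "HARD_FILTER_SNV",
    "HARD_FILTER_INDEL",
    "SearchSpace",
    "PSOConfig",
    "HardFilterClassifier",
    "ThresholdRuleClassifier",
    "PSOThresholdClassifier",
]

FEATURE_COLUMNS = ["qd", "fs", "mq", "mq_rank_sum", "read_pos_rank_sum", "dnm", "mw_p"]

#: GATK hard-filter defaults; a variant failing any clause is an artifact.
HARD_FILTER_SNV = {
    "qd_min": 2.0,
    "fs_max": 60.0,
    "mq_min": 40.0,
    "mq_rank_sum_min": -12.5,
    "read_pos_rank_sum_min": -8.0,
}
HARD_FILTER_INDEL = {"qd_min": 2.0, "fs_max": 200.0, "read_pos_rank_sum_min": -20.0}

# cutoff name -> (feature column, displayed statistic, fails when)
_CLAUSES = {
    "qd_min": ("qd", STAT_QD, "below"),
    "fs_max": ("fs", STAT_FS, "above"),
    "mq_min": ("mq", STAT_MQ, "below"),
    "mq_rank_sum_min": ("mq_rank_sum", STAT_MQRANKSUM, "below"),
    "read_pos_rank_sum_min": ("read_pos_rank_sum", STAT_READPOS, "below"),
    "mw_p_min": ("mw_p", STAT_MW, "below"),
}

# Ordered trainable dimensions per scope (also the particle coordinate order).
SNV_DIMS = ("dnm_min", "fs_max", "mq_min", "mq_rank_sum_min", "qd_min", "mw_p_min")
INDEL_DIMS = ("dnm_min", "fs_max", "qd_min", "mw_p_min")


def _as_columns(X) -> dict[str, np.ndarray]:
    if isinstance(X, pd.DataFrame):
        cols = {}
        for name in FEATURE_COLUMNS:
            if name in X.columns:
                cols[name] = X[name].to_numpy(dtype=float)
            else:
                cols[name] = np.full(len(X), np.nan)
        return cols
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(FEATURE_COLUMNS):
        raise ValueError(
            f"array input must have {len(FEATURE_COLUMNS)} columns in order {FEATURE_COLUMNS}"
        )
    return {name: X[:, j] for j, name in enumerate(FEATURE_COLUMNS)}


def _violations(
    cols: Mapping[str, np.ndarray], cutoffs: Mapping[str, float]
) -> dict[str, np.ndarray]:
    """Per-statistic strict-inequality violation masks; NaN never violates."""
    out: dict[str, np.ndarray] = {}
    for name, cutoff in cutoffs.items():
        if name == "dnm_min":
            d = cols["dnm"]
            out[STAT_DNM] = (d > 0) & (d < cutoff)
            continue
        col, stat, direction = _CLAUSES[name]
        v = cols[col]
        with np.errstate(invalid="ignore"):
            out[stat] = (v > cutoff) if direction == "above" else (v < cutoff)
    return out


def _predictions_from_masks(
    masks: Mapping[str, np.ndarray], shortcut: np.ndarray
) -> list[Prediction]:
    names = list(masks)
    stacked = np.stack([masks[n] for n in names]) if names else np.zeros((0, shortcut.size), bool)
    preds: list[Prediction] = []
    for i in range(shortcut.size):
        if shortcut[i]:
            preds.append(Prediction(Label.TRUE_MUTATION, frozenset(), shortcut_used=True))
            continue
        failed = frozenset(n for j, n in enumerate(names) if stacked[j, i])
        label = Label.ARTIFACT if failed else Label.TRUE_MUTATION
        preds.append(Prediction(label, failed))
    return preds


class HardFilterClassifier(ClassifierMixin, BaseEstimator):
    """GATK hard filtering with the published default cutoffs.

    SNV scope: artifact iff QD < 2.0, FS > 60.0, MQ < 40.0,
    MQRankSum < −12.5 or ReadPosRankSum < −8.0. Indel scope: artifact iff
    QD < 2.0, FS > 200.0 or ReadPosRankSum < −20.0. Comparisons are strict;
    boundary and missing values pass. There is nothing to fit.
    """

    def __init__(self, scope: str = "snv"):
        self.scope = scope

    def _cutoffs(self) -> dict[str, float]:
        scope = str(self.scope).lower()
        if scope == "snv":
            return dict(HARD_FILTER_SNV)
        if scope == "indel":
            return dict(HARD_FILTER_INDEL)
        raise ValueError(f"scope must be 'snv' or 'indel', got {self.scope!r}")

    def fit(self, X=None, y=None):
        self._cutoffs()
        self.classes_ = np.array([0, 1])
        self.is_fitted_ = True
        return self

    def predict(self, X) -> np.ndarray:
        cols = _as_columns(X)
        masks = _violations(cols, self._cutoffs())
        artifact = np.any(np.stack(list(masks.values())), axis=0)
        return (~artifact).astype(int)

    def predict_detailed(self, X) -> list[Prediction]:
        cols = _as_columns(X)
        masks = _violations(cols, self._cutoffs())
        n = next(iter(cols.values())).size
        return _predictions_from_masks(masks, np.zeros(n, dtype=bool))


class ThresholdRuleClassifier(ClassifierMixin, BaseEstimator):
    """The trained decision rule with explicit cutoffs.

    A variant with dNM == 0 (exact catalog match) is a true mutation
    regardless of every other statistic. Otherwise it is an artifact iff any
    strict comparison fails: FS > fs_max, QD < qd_min, 0 < dNM < dnm_min,
    strand-test P < mw_p_min, and for SNVs additionally MQ < mq_min or
    MQRankSum < mq_rank_sum_min. ReadPosRankSum is never consulted.
    """

    def __init__(
        self,
        scope: str = "snv",
        alpha: float = 0.5,
        dnm_min: float = 0.0,
        fs_max: float = math.inf,
        qd_min: float = 0.0,
        mw_p_min: float = 0.0,
        mq_min: float | None = None,
        mq_rank_sum_min: float | None = None,
    ):
        self.scope = scope
        self.alpha = alpha
        self.dnm_min = dnm_min
        self.fs_max = fs_max
        self.qd_min = qd_min
        self.mw_p_min = mw_p_min
        self.mq_min = mq_min
        self.mq_rank_sum_min = mq_rank_sum_min

    @classmethod
    def from_threshold_set(cls, ts: ThresholdSet) -> "ThresholdRuleClassifier":
        return cls(
            scope=ts.scope.value.lower(),
            alpha=ts.alpha,
            mq_min=ts.mq_min,
            mq_rank_sum_min=ts.mq_rank_sum_min,
            **{k: getattr(ts, k) for k in ("dnm_min", "fs_max", "qd_min", "mw_p_min")},
        ).fit()

    def to_threshold_set(self) -> ThresholdSet:
        scope = VariantClass(str(self.scope).upper())
        kwargs = dict(
            scope=scope,
            alpha=self.alpha,
            dnm_min=self.dnm_min,
            fs_max=self.fs_max,
            qd_min=self.qd_min,
            mw_p_min=self.mw_p_min,
        )
        if scope is VariantClass.SNV:
            mq_min = 0.0 if self.mq_min is None else self.mq_min
            mq_rs = -math.inf if self.mq_rank_sum_min is None else self.mq_rank_sum_min
            kwargs.update(mq_min=mq_min, mq_rank_sum_min=mq_rs)
        return ThresholdSet(**kwargs)

    def _cutoffs(self) -> dict[str, float]:
        scope = str(self.scope).lower()
        cutoffs = {
            "dnm_min": self.dnm_min,
            "fs_max": self.fs_max,
            "qd_min": self.qd_min,
            "mw_p_min": self.mw_p_min,
        }
        if scope == "snv":
            cutoffs["mq_min"] = 0.0 if self.mq_min is None else self.mq_min
            cutoffs["mq_rank_sum_min"] = (
                -math.inf if self.mq_rank_sum_min is None else self.mq_rank_sum_min
            )
        elif scope != "indel":
            raise ValueError(f"scope must be 'snv' or 'indel', got {self.scope!r}")
        return cutoffs

    def fit(self, X=None, y=None):
        self._cutoffs()
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        self.classes_ = np.array([0, 1])
        self.is_fitted_ = True
        return self

    def predict(self, X) -> np.ndarray:
        cols = _as_columns(X)
        masks = _violations(cols, self._cutoffs())
        artifact = np.any(np.stack(list(masks.values())), axis=0)
        shortcut = cols["dnm"] == 0
        return (shortcut | ~artifact).astype(int)

    def predict_detailed(self, X) -> list[Prediction]:
        cols = _as_columns(X)
        masks = _violations(cols, self._cutoffs())
        return _predictions_from_masks(masks, cols["dnm"] == 0)


# ----------------------------------------------------------------------------
# Threshold training: discretized search space + particle swarm optimization
# ----------------------------------------------------------------------------

#: Search-space bounds (lower, upper, segment count) per trainable cutoff.
#: Segment counts follow the published partition dNM/FS/MQ/MQRankSum/QD/MW-P =
#: 1000/60/50/100/20/6; candidate cutoffs are the segment grid points.
DEFAULT_BOUNDS = {
    "dnm_min": (1.0, 10_000.0, 1000),
    "fs_max": (0.0, 300.0, 60),
    "mq_min": (0.0, 70.0, 50),
    "mq_rank_sum_min": (-20.0, 10.0, 100),
    "qd_min": (0.0, 4.0, 20),
    "mw_p_min": (0.001, 0.3, 6),
}


@dataclass(frozen=True)
class SearchSpace:
    """Per-cutoff (lower, upper, n_segments) boxes; the grid has n+1 points."""

    bounds: dict[str, tuple[float, float, int]]

    def __post_init__(self) -> None:
        for name, (lo, hi, n) in self.bounds.items():
            if hi <= lo or n < 1:
                raise ValueError(f"invalid bounds for {name}: {(lo, hi, n)}")

    @classmethod
    def default(cls, scope: str = "snv") -> "SearchSpace":
        dims = SNV_DIMS if str(scope).lower() == "snv" else INDEL_DIMS
        return cls({d: DEFAULT_BOUNDS[d] for d in dims})

    def dims(self) -> tuple[str, ...]:
        return tuple(self.bounds)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[d][0] for d in self.bounds])
        hi = np.array([self.bounds[d][1] for d in self.bounds])
        nseg = np.array([self.bounds[d][2] for d in self.bounds])
        return lo, hi, nseg

    def grid(self, dim: str) -> np.ndarray:
        lo, hi, n = self.bounds[dim]
        return np.linspace(lo, hi, n + 1)


@dataclass(frozen=True)
class PSOConfig:
    """Swarm size and dynamics. Defaults reproduce the training scale of
    4,000 particles over 500 generations with standard constriction-style
    coefficients (inertia 0.72, cognitive = social = 1.49)."""

    n_particles: int = 4000
    n_generations: int = 500
    inertia: float = 0.72
    cognitive: float = 1.49
    social: float = 1.49
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_generations < 0:
            raise ValueError("need n_particles >= 1 and n_generations >= 0")


def _snap(positions: np.ndarray, lo: np.ndarray, hi: np.ndarray, nseg: np.ndarray) -> np.ndarray:
    """Round continuous particle positions to the nearest segment grid point."""
    step = (hi - lo) / nseg
    k = np.rint((positions - lo) / step)
    return lo + np.clip(k, 0, nseg) * step


def evaluate_thresholds(
    cols: Mapping[str, np.ndarray],
    y: np.ndarray,
    thresholds: np.ndarray,
    dims: Sequence[str],
    alpha: float,
    chunk: int = 1024,
) -> np.ndarray:
    """Fitness α(1−cFPR) + (1−α)TPR for each row of ``thresholds``.

    Fully vectorized over particles × variants; the dNM == 0 shortcut is
    applied and NaN statistics pass, exactly as in prediction.
    """
    thresholds = np.atleast_2d(thresholds)
    y = np.asarray(y, dtype=bool)
    n_true = int(y.sum())
    n_false = int((~y).sum())
    dnm = cols["dnm"]
    shortcut = dnm == 0
    feats = {}
    for j, d in enumerate(dims):
        col = "dnm" if d == "dnm_min" else _CLAUSES[d][0]
        feats[j] = cols[col]
    out = np.empty(thresholds.shape[0])
    for start in range(0, thresholds.shape[0], chunk):
        T = thresholds[start : start + chunk]
        artifact = np.zeros((T.shape[0], y.size), dtype=bool)
        with np.errstate(invalid="ignore"):
            for j, d in enumerate(dims):
                t = T[:, j, None]
                v = feats[j][None, :]
                if d == "dnm_min":
                    artifact |= (v > 0) & (v < t)
                elif _CLAUSES[d][2] == "above":
                    artifact |= v > t
                else:
                    artifact |= v < t
        pred_true = shortcut[None, :] | ~artifact
        tp = (pred_true & y[None, :]).sum(axis=1)
        fp = (pred_true & ~y[None, :]).sum(axis=1)
        tpr = tp / n_true if n_true else np.zeros_like(tp, dtype=float)
        cfpr = fp / n_false if n_false else np.zeros_like(fp, dtype=float)
        out[start : start + T.shape[0]] = alpha * (1.0 - cfpr) + (1.0 - alpha) * tpr
    return out


def pso_search(
    cols: Mapping[str, np.ndarray],
    y: np.ndarray,
    alpha: float,
    space: SearchSpace,
    cfg: PSOConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Run one swarm; returns (best grid-snapped position, fitness, trajectory).

    Particles move continuously inside the box and are snapped to the
    segment grid for evaluation; velocities are clamped to the box width.
    The best-so-far trajectory has one entry per evaluated generation
    (``n_generations + 1`` including the initial population) and is
    non-decreasing.
    """
    dims = space.dims()
    lo, hi, nseg = space.arrays()
    width = hi - lo
    P, D = cfg.n_particles, len(dims)
    x = lo + rng.random((P, D)) * width
    v = (rng.random((P, D)) - 0.5) * width
    snapped = _snap(x, lo, hi, nseg)
    fit = evaluate_thresholds(cols, y, snapped, dims, alpha)
    pbest_x, pbest_f = snapped.copy(), fit.copy()
    g = int(np.argmax(fit))
    gbest_x, gbest_f = snapped[g].copy(), float(fit[g])
    trajectory = [gbest_f]
    for _ in range(cfg.n_generations):
        r1 = rng.random((P, D))
        r2 = rng.random((P, D))
        v = (
            cfg.inertia * v
            + cfg.cognitive * r1 * (pbest_x - x)
            + cfg.social * r2 * (gbest_x[None, :] - x)
        )
        np.clip(v, -width, width, out=v)
        x = np.clip(x + v, lo, hi)
        snapped = _snap(x, lo, hi, nseg)
        fit = evaluate_thresholds(cols, y, snapped, dims, alpha)
        improved = fit > pbest_f
        pbest_x[improved] = snapped[improved]
        pbest_f[improved] = fit[improved]
        g = int(np.argmax(pbest_f))
        if pbest_f[g] > gbest_f:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
        trajectory.append(gbest_f)
    return gbest_x, gbest_f, np.asarray(trajectory)


def _vector_to_kwargs(vec: np.ndarray, dims: Sequence[str]) -> dict[str, float]:
    return {d: float(vec[j]) for j, d in enumerate(dims)}


class PSOThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Learn decision-rule cutoffs by particle swarm optimization.

    ``fit(X, y, groups=tumor_ids)`` either trains at a fixed ``alpha`` or,
    when ``alpha=None``, sweeps ``alpha_grid`` (default 0 to 1 by 0.1) with
    leave-one-group-out cross-validation — each tumor once as the held-out
    fold — selects the α maximizing the mean cross-validated ``criterion``
    (ties toward smaller α), then retrains on all rows at the selected α.

    Fitted attributes: ``thresholds_`` (a :class:`ThresholdSet`), ``alpha_``,
    ``fitness_`` (training fitness of the final swarm), ``trajectory_``
    (best-so-far fitness per generation), ``cv_results_`` (per α × fold
    metrics, when the sweep ran).
    """

    def __init__(
        self,
        scope: str = "snv",
        alpha: float | None = None,
        alpha_grid: Sequence[float] | None = None,
        space: SearchSpace | None = None,
        n_particles: int = 4000,
        n_generations: int = 500,
        inertia: float = 0.72,
        cognitive: float = 1.49,
        social: float = 1.49,
        cv_folds: int = 10,
        criterion: str = "mcc",
        random_state: int | None = None,
    ):
        self.scope = scope
        self.alpha = alpha
        self.alpha_grid = alpha_grid
        self.space = space
        self.n_particles = n_particles
        self.n_generations = n_generations
        self.inertia = inertia
        self.cognitive = cognitive
        self.social = social
        self.cv_folds = cv_folds
        self.criterion = criterion
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    def _space(self) -> SearchSpace:
        return self.space if self.space is not None else SearchSpace.default(self.scope)

    def _config(self, seed: int | None) -> PSOConfig:
        return PSOConfig(
            n_particles=self.n_particles,
            n_generations=self.n_generations,
            inertia=self.inertia,
            cognitive=self.cognitive,
            social=self.social,
            seed=seed,
        )

    def _folds(self, n: int, groups) -> list[np.ndarray]:
        if groups is not None:
            groups = np.asarray(groups)
            uniq = pd.unique(groups)
            if uniq.size < 2:
                raise ValueError("cross-validation needs at least 2 groups")
            return [np.asarray(groups == g) for g in uniq]
        if self.cv_folds < 2 or n < self.cv_folds:
            raise ValueError("cross-validation needs cv_folds >= 2 and n >= cv_folds")
        rng = np.random.default_rng(
            np.random.SeedSequence([0 if self.random_state is None else self.random_state, 7])
        )
        assignment = rng.permutation(np.arange(n) % self.cv_folds)
        return [assignment == k for k in range(self.cv_folds)]

    def _rule(self, vec: np.ndarray, dims: Sequence[str], alpha: float) -> ThresholdRuleClassifier:
        kwargs = _vector_to_kwargs(vec, dims)
        return ThresholdRuleClassifier(scope=str(self.scope).lower(), alpha=alpha, **kwargs).fit()

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y, groups=None):
        from .metrics import confusion_from_arrays, mcc, rates

        cols = _as_columns(X)
        y = np.asarray(y, dtype=int)
        if y.size == 0 or y.min() == y.max():
            raise ValueError("training data must contain both classes")
        space = self._space()
        dims = space.dims()
        ss = np.random.SeedSequence(0 if self.random_state is None else self.random_state)
        grid = (
            list(self.alpha_grid)
            if self.alpha_grid is not None
            else [round(0.1 * k, 1) for k in range(11)]
        )

        alpha_ = self.alpha
        if alpha_ is None:
            folds = self._folds(y.size, groups)
            children = ss.spawn(len(grid) * len(folds) + 1)
            rows = []
            for ai, alpha in enumerate(grid):
                for fi, test_mask in enumerate(folds):
                    train_mask = ~test_mask
                    sub_cols = {k: v[train_mask] for k, v in cols.items()}
                    sub_y = y[train_mask]
                    if sub_y.min() == sub_y.max():
                        raise ValueError("a training fold lost one class entirely")
                    rng = np.random.default_rng(children[ai * len(folds) + fi])
                    vec, train_fit, _ = pso_search(
                        sub_cols, sub_y, alpha, space, self._config(None), rng
                    )
                    rule = self._rule(vec, dims, alpha)
                    test_cols = {k: v[test_mask] for k, v in cols.items()}
                    pred = rule.predict(pd.DataFrame(test_cols))
                    c = confusion_from_arrays(pred, y[test_mask])
                    r = rates(c)
                    rows.append(
                        {
                            "alpha": alpha,
                            "fold": fi,
                            "tpr": r.tpr,
                            "cfpr": r.cfpr,
                            "precision": r.precision,
                            "mcc": mcc(c),
                            "fitness": alpha * (1 - r.cfpr) + (1 - alpha) * r.tpr,
                            "train_fitness": train_fit,
                        }
                    )
            cv = pd.DataFrame(rows)
            means = cv.groupby("alpha")[self.criterion].mean()
            best = means.max()
            alpha_ = float(min(a for a in means.index if means[a] >= best - 1e-12))
            self.cv_results_ = cv
            final_rng = np.random.default_rng(children[-1])
        else:
            self.cv_results_ = None
            final_rng = np.random.default_rng(ss.spawn(1)[0])

        vec, fitness, trajectory = pso_search(
            cols, y, alpha_, space, self._config(None), final_rng
        )
        self.alpha_ = float(alpha_)
        self.best_vector_ = vec
        self.fitness_ = float(fitness)
        self.trajectory_ = trajectory
        self.rule_ = self._rule(vec, dims, self.alpha_)
        self.thresholds_ = self.rule_.to_threshold_set()
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "rule_")
        return self.rule_.predict(X)

    def predict_detailed(self, X) -> list[Prediction]:
        check_is_fitted(self, "rule_")
        return self.rule_.predict_detailed(X)
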