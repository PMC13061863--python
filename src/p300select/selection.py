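"""Wrapper-based electrode selection for P300 calibration.

Greedy forward search adds one electrode at a time, each step keeping the
candidate whose augmented subset maximizes SWLDA calibration accuracy (ties
go to the electrode earlier in montage order).  For held-out evaluation the
subset is treated as a hyper-parameter and stabilized by leave-one-trial-out
consensus: each fold's greedy ordering awards an electrode added at rank k
the score max(0, M − k + 1), scores are summed over folds, and the top-M
electrodes form the consensus subset.

An exhaustive-search oracle over all M-subsets is provided for validation
on small channel pools.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np

from .errors import CalibrationError, SchemaError, SelectionError
from .features import FeatureConfig, FeatureMatrix, extract_features
from .sessions import EpochSet, select_channels
from .swlda import (
    SWLDAConfig,
    SWLDAModel,
    _f_crit_table,
    stepwise_crossproducts,
)

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "ConsensusResult",
    "SessionEvaluator",
    "forward_select",
    "exhaustive_select",
    "score_fold_orders",
    "consensus_select",
    "subset_size_curve",
    "SubsetSizeCurve",
    "generalization_experiment",
    "GeneralizationReport",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Settings for the greedy wrapper search."""

    subset_size: int = 8  # M, the target custom-subset size
    pool: tuple[str, ...] | None = None  # candidate electrodes (None: all)
    feature: FeatureConfig = field(default_factory=FeatureConfig)
    swlda: SWLDAConfig = field(default_factory=SWLDAConfig)

    def __post_init__(self) -> None:
        if self.subset_size < 1:
            raise SchemaError("subset_size must be >= 1")
        if self.pool is not None and len(set(self.pool)) != len(self.pool):
            raise SchemaError("candidate pool contains duplicates")


@dataclass
class SelectionResult:
    """One greedy run: electrode order, accuracy trajectory, all evaluations."""

    order: tuple[str, ...]
    accuracy_trajectory: np.ndarray
    evaluations: list[dict[str, float]]
    final_model: SWLDAModel | None = None


@dataclass
class ConsensusResult:
    """Fold-consensus electrode scores and the chosen top-M subset."""

    scores: dict[str, float]
    chosen: tuple[str, ...]
    fold_orders: list[tuple[str, ...]]
    subset_size: int


class SessionEvaluator:
    """Calibration-accuracy evaluator with a cached Gram matrix.

    Precomputes the centered cross-products of the full feature matrix once
    (optionally restricted to a trial subset), so fitting an SWLDA on any
    channel subset is a cheap sliced stepwise run.  Accuracy is
    resubstitution trial accuracy on the evaluator's own trials at the full
    flash count, which is what the calibration program reports.
    """

    def __init__(
        self,
        fm: FeatureMatrix,
        swlda_cfg: SWLDAConfig | None = None,
        trials: np.ndarray | None = None,
    ) -> None:
        self.fm = fm
        self.cfg = swlda_cfg or SWLDAConfig()
        self.trials = (
            np.arange(fm.n_trials) if trials is None else np.asarray(trials, np.int64)
        )
        rows = np.isin(fm.trial, self.trials)
        self._X = fm.X[rows]
        y = fm.y[rows].astype(np.float64)
        self.n = self._X.shape[0]
        Z = np.column_stack([self._X, y])
        self._mean = Z.mean(axis=0)
        self._S = Z.T @ Z - self.n * np.outer(self._mean, self._mean)
        self._crit_enter = _f_crit_table(self.cfg.p_enter, self.n)
        self._crit_remove = _f_crit_table(self.cfg.p_remove, self.n)
        self._trial_local = np.searchsorted(self.trials, fm.trial[rows])
        self._label = fm.flashed_label[rows]
        self._rep = fm.repetition[rows]
        self.targets = fm.target_choice[self.trials]

    # ---- model fitting on a channel subset ------------------------------
    def fit(self, channel_names) -> SWLDAModel:
        cols = self.fm.columns_for(channel_names)
        ix = np.append(cols, self.fm.n_cols)
        S_sub = self._S[np.ix_(ix, ix)]
        order, w = stepwise_crossproducts(
            S_sub, self.n, self.cfg, self._crit_enter, self._crit_remove
        )
        if not order:
            raise CalibrationError(
                "no feature met the entry criterion; subset could not calibrate"
            )
        included = cols[np.asarray(order)]
        intercept = float(self._mean[-1] - self._mean[included] @ w)
        return SWLDAModel(
            included=included,
            weights=np.asarray(w),
            intercept=intercept,
            config=self.cfg,
            feature_map=self.fm.feature_map,
            n_columns=self.fm.n_cols,
        )

    # ---- scoring ---------------------------------------------------------
    def _choice_rep_tensor(self, model: SWLDAModel) -> np.ndarray:
        s = self._X[:, model.included] @ model.weights + model.intercept
        out = np.zeros(
            (len(self.trials), self.fm.n_choices, self.fm.flashes_per_choice)
        )
        out[self._trial_local, self._label, self._rep] = s
        return out

    def accuracy_of(self, model: SWLDAModel, r: int | None = None) -> float:
        r = self.fm.flashes_per_choice if r is None else r
        t = self._choice_rep_tensor(model)
        pred = np.argmax(t[:, :, :r].sum(axis=2), axis=1)
        return float((pred == self.targets).mean())

    def accuracy_by_flashes(self, model: SWLDAModel) -> np.ndarray:
        t = self._choice_rep_tensor(model)
        pred = np.argmax(np.cumsum(t, axis=2), axis=1)
        return (pred == self.targets[:, None]).mean(axis=0)

    def evaluate(self, channel_names) -> tuple[float, SWLDAModel | None]:
        """Accuracy of the subset; a non-calibrating subset scores 0."""
        try:
            model = self.fit(channel_names)
        except CalibrationError:
            return 0.0, None
        return self.accuracy_of(model), model


# ---- greedy forward search ----------------------------------------------


def _greedy(
    evaluate, pool: tuple[str, ...], subset_size: int
) -> SelectionResult:
    if not (1 <= subset_size <= len(pool)):
        raise SelectionError("subset_size must lie in 1..|pool|")
    chosen: list[str] = []
    trajectory: list[float] = []
    evaluations: list[dict[str, float]] = []
    best_model = None
    for step in range(subset_size):
        step_accs: dict[str, float] = {}
        best_name, best_acc, step_model = None, -1.0, None
        for cand in pool:
            if cand in chosen:
                continue
            acc, model = evaluate(tuple(chosen) + (cand,))
            step_accs[cand] = acc
            if acc > best_acc:  # strict: ties keep the earlier (montage order)
                best_name, best_acc, step_model = cand, acc, model
        evaluations.append(step_accs)
        if step == 0 and all(a == 0.0 for a in step_accs.values()) and step_model is None:
            raise SelectionError("every single-electrode candidate failed to calibrate")
        chosen.append(best_name)
        trajectory.append(best_acc)
        best_model = step_model
    return SelectionResult(
        order=tuple(chosen),
        accuracy_trajectory=np.asarray(trajectory),
        evaluations=evaluations,
        final_model=best_model,
    )


def _make_evaluator(
    es: EpochSet, cfg: SelectionConfig, trials: np.ndarray | None = None
) -> tuple[SessionEvaluator, tuple[str, ...]]:
    pool = tuple(cfg.pool) if cfg.pool is not None else es.channels
    if not set(pool) <= set(es.channels):
        raise SchemaError("candidate pool must be a subset of the session channels")
    es_pool = select_channels(es, pool) if pool != es.channels else es
    fm = extract_features(es_pool, cfg.feature)
    return SessionEvaluator(fm, cfg.swlda, trials=trials), pool


def forward_select(
    es: EpochSet,
    cfg: SelectionConfig | None = None,
    evaluator=None,
) -> SelectionResult:
    """Greedy forward electrode selection on one session.

    ``evaluator`` may override the default resubstitution-accuracy
    evaluator with any callable ``channels -> (accuracy, model | None)``.
    """
    cfg = cfg or SelectionConfig()
    if evaluator is None:
        ev, pool = _make_evaluator(es, cfg)
        evaluator = ev.evaluate
    else:
        pool = tuple(cfg.pool) if cfg.pool is not None else es.channels
    return _greedy(evaluator, pool, cfg.subset_size)


def exhaustive_select(
    es: EpochSet,
    subset_size: int,
    pool: tuple[str, ...] | None = None,
    cfg: SelectionConfig | None = None,
    max_combinations: int = 200_000,
) -> tuple[tuple[str, ...], float, int]:
    """Evaluate every M-subset; the validation oracle for the greedy search.

    Returns (best subset, accuracy, number of subsets evaluated); ties are
    broken lexicographically in pool (montage) order.
    """
    cfg = cfg or SelectionConfig(subset_size=subset_size, pool=pool)
    cfg = SelectionConfig(
        subset_size=subset_size, pool=pool or cfg.pool, feature=cfg.feature, swlda=cfg.swlda
    )
    ev, pool_t = _make_evaluator(es, cfg)
    n_comb = comb(len(pool_t), subset_size)
    if n_comb > max_combinations:
        raise SelectionError(
            f"{n_comb} subsets exceed the enumeration guard ({max_combinations})"
        )
    best_subset, best_acc, count = None, -1.0, 0
    for subset in itertools.combinations(pool_t, subset_size):
        acc, _ = ev.evaluate(subset)
        count += 1
        if acc > best_acc:
            best_subset, best_acc = subset, acc
    return best_subset, best_acc, count


# ---- fold-consensus scoring ----------------------------------------------


def score_fold_orders(
    fold_orders, subset_size: int, pool: tuple[str, ...]
) -> ConsensusResult:
    """Aggregate per-fold greedy orderings into consensus electrode scores.

    An electrode added at 1-based rank k in a fold contributes
    max(0, M − k + 1); unranked electrodes contribute 0.  The chosen subset
    is the top-M by total score, ties broken by the better (smaller) best
    rank across folds, then by pool order.
    """
    pool = tuple(pool)
    M = subset_size
    scores = {name: 0.0 for name in pool}
    best_rank = {name: np.inf for name in pool}
    orders = [tuple(o) for o in fold_orders]
    for fold_i, order in enumerate(orders):
        if len(set(order)) != len(order):
            raise SelectionError(f"fold {fold_i} ranks an electrode twice")
        if len(order) > M:
            raise SelectionError(f"fold {fold_i} ranks more than M electrodes")
        if not set(order) <= set(pool):
            raise SelectionError(f"fold {fold_i} ranks electrodes outside the pool")
        for k, name in enumerate(order, start=1):
            scores[name] += max(0, M - k + 1)
            best_rank[name] = min(best_rank[name], k)
    pool_index = {name: i for i, name in enumerate(pool)}
    ranked = sorted(
        pool, key=lambda e: (-scores[e], best_rank[e], pool_index[e])
    )
    return ConsensusResult(
        scores=scores,
        chosen=tuple(ranked[:M]),
        fold_orders=orders,
        subset_size=M,
    )


def consensus_select(
    es: EpochSet, cfg: SelectionConfig | None = None
) -> tuple[ConsensusResult, SWLDAModel]:
    """Leave-one-trial-out consensus selection plus the final calibration.

    Runs the greedy forward search once per fold (all trials but one),
    consensus-scores the N orderings, and fits the final SWLDA on all N
    trials restricted to the chosen subset.
    """
    cfg = cfg or SelectionConfig()
    if es.n_trials < 2:
        raise SelectionError("consensus selection needs at least 2 trials")
    pool = tuple(cfg.pool) if cfg.pool is not None else es.channels
    if not set(pool) <= set(es.channels):
        raise SchemaError("candidate pool must be a subset of the session channels")
    es_pool = select_channels(es, pool) if pool != es.channels else es
    fm = extract_features(es_pool, cfg.feature)
    all_trials = np.arange(fm.n_trials)
    orders = []
    for i in range(fm.n_trials):
        ev = SessionEvaluator(fm, cfg.swlda, trials=all_trials[all_trials != i])
        try:
            res = _greedy(ev.evaluate, pool, cfg.subset_size)
        except SelectionError as e:
            raise SelectionError(f"fold {i}: {e}") from None
        orders.append(res.order)
    consensus = score_fold_orders(orders, cfg.subset_size, pool)
    final_ev = SessionEvaluator(fm, cfg.swlda)
    model = final_ev.fit(consensus.chosen)
    return consensus, model


# ---- subset-size curves ---------------------------------------------------


@dataclass
class SubsetSizeCurve:
    sizes: np.ndarray
    accuracies: np.ndarray
    electrodes_needed: int  # smallest m reaching 95% of the full-size accuracy


def subset_size_curve(result: SelectionResult, fraction: float = 0.95) -> SubsetSizeCurve:
    """Accuracy versus subset size, and the size reaching 95% of the asymptote."""
    acc = np.asarray(result.accuracy_trajectory, dtype=float)
    threshold = fraction * acc[-1]
    needed = int(np.argmax(acc >= threshold)) + 1
    return SubsetSizeCurve(
        sizes=np.arange(1, len(acc) + 1),
        accuracies=acc,
        electrodes_needed=needed,
    )


# ---- holdout generalization ------------------------------------------------


def _first_differing_r(acc_a: np.ndarray, acc_b: np.ndarray) -> tuple[int, bool]:
    for r in range(len(acc_a), 0, -1):
        if acc_a[r - 1] != acc_b[r - 1]:
            return r, False
    return 1, True


@dataclass
class GeneralizationReport:
    """Calibration vs held-out testing accuracy for custom and default-8 subsets."""

    seed: int
    calibration_trials: np.ndarray
    test_trials: np.ndarray
    chosen: tuple[str, ...]
    consensus_scores: dict[str, float]
    cal_acc_custom: np.ndarray  # accuracy at r = 1..R
    cal_acc_default: np.ndarray
    test_acc_custom: np.ndarray
    test_acc_default: np.ndarray
    cal_r_used: int
    cal_tied: bool
    test_r_used: int
    test_tied: bool

    def to_dict(self) -> dict:
        R = len(self.cal_acc_custom)
        return {
            "seed": self.seed,
            "calibration_trials": self.calibration_trials.tolist(),
            "test_trials": self.test_trials.tolist(),
            "chosen": list(self.chosen),
            "consensus_scores": self.consensus_scores,
            "calibration": {
                "acc_custom": float(self.cal_acc_custom[self.cal_r_used - 1]),
                "acc_default": float(self.cal_acc_default[self.cal_r_used - 1]),
                "acc_custom_at_full": float(self.cal_acc_custom[R - 1]),
                "acc_default_at_full": float(self.cal_acc_default[R - 1]),
                "r_used": self.cal_r_used,
                "tied": self.cal_tied,
            },
            "testing": {
                "acc_custom": float(self.test_acc_custom[self.test_r_used - 1]),
                "acc_default": float(self.test_acc_default[self.test_r_used - 1]),
                "acc_custom_at_full": float(self.test_acc_custom[R - 1]),
                "acc_default_at_full": float(self.test_acc_default[R - 1]),
                "r_used": self.test_r_used,
                "tied": self.test_tied,
            },
        }


def generalization_experiment(
    es: EpochSet,
    seed: int,
    cfg: SelectionConfig | None = None,
    n_test: int = 20,
    min_trials: int = 60,
) -> GeneralizationReport:
    """Random holdout evaluation of the consensus-selected subset.

    ``n_test`` trials are held out at random (seeded); consensus selection
    and both final calibrations (custom and default-8) run on the remaining
    trials, and both models are then applied to the holdout.
    """
    cfg = cfg or SelectionConfig()
    if es.n_trials < min_trials:
        raise SelectionError(
            f"generalization experiment needs >= {min_trials} trials"
        )
    rng = np.random.default_rng(seed)
    test_idx = np.sort(rng.choice(es.n_trials, size=n_test, replace=False))
    cal_idx = np.setdiff1d(np.arange(es.n_trials), test_idx)

    pool = tuple(cfg.pool) if cfg.pool is not None else es.channels
    default8 = tuple(n for n in es.montage.default8 if n in pool)
    if len(default8) != len(es.montage.default8):
        raise SchemaError("default8 electrodes must be inside the candidate pool")
    es_pool = select_channels(es, pool) if pool != es.channels else es
    fm = extract_features(es_pool, cfg.feature)

    # consensus selection within the calibration trials
    orders = []
    for i in cal_idx:
        ev = SessionEvaluator(fm, cfg.swlda, trials=cal_idx[cal_idx != i])
        res = _greedy(ev.evaluate, pool, cfg.subset_size)
        orders.append(res.order)
    consensus = score_fold_orders(orders, cfg.subset_size, pool)

    cal_ev = SessionEvaluator(fm, cfg.swlda, trials=cal_idx)
    model_custom = cal_ev.fit(consensus.chosen)
    model_default = cal_ev.fit(default8)
    test_ev = SessionEvaluator(fm, cfg.swlda, trials=test_idx)

    cal_c = cal_ev.accuracy_by_flashes(model_custom)
    cal_d = cal_ev.accuracy_by_flashes(model_default)
    test_c = test_ev.accuracy_by_flashes(model_custom)
    test_d = test_ev.accuracy_by_flashes(model_default)
    cal_r, cal_tied = _first_differing_r(cal_c, cal_d)
    test_r, test_tied = _first_differing_r(test_c, test_d)
    return GeneralizationReport(
        seed=seed,
        calibration_trials=cal_idx,
        test_trials=test_idx,
        chosen=consensus.chosen,
        consensus_scores=consensus.scores,
        cal_acc_custom=cal_c,
        cal_acc_default=cal_d,
        test_acc_custom=test_c,
        test_acc_default=test_d,
        cal_r_used=cal_r,
        cal_tied=cal_tied,
        test_r_used=test_r,
        test_tied=test_tied,
    )
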