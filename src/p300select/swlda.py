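"""Stepwise linear discriminant analysis (SWLDA) and trial classification.

SWLDA is realized as classical stepwise ordinary-least-squares regression of
coded class labels (target = +1, non-target = −1) on the feature columns.
Candidate columns enter when their partial-F p-value is the smallest and
below ``p_enter``; included columns are removed when their partial-F
p-value rises above ``p_remove``; the loop stops at a fixed point, the
feature cap, or an iteration safeguard.  The discriminant weights are the
OLS coefficients of the final included set.

The stepwise loop runs on centered cross-products via the reversible sweep
operator, so selection wrappers can fit thousands of candidate models from
one precomputed Gram matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.stats import f as f_dist

from .errors import CalibrationError, SchemaError
from .features import FeatureMatrix

__all__ = [
    "SWLDAConfig",
    "SWLDAModel",
    "TrialScores",
    "fit_swlda",
    "score_trials",
    "classify",
    "accuracy",
    "accuracy_by_flashes",
    "break_tie_by_flashes",
    "TieBreakResult",
]


@dataclass(frozen=True)
class SWLDAConfig:
    """Stepwise-regression parameters (common P300 speller settings)."""

    max_features: int = 60
    p_enter: float = 0.10
    p_remove: float = 0.15
    max_iterations: int = 500

    def __post_init__(self) -> None:
        if not (0.0 < self.p_enter <= self.p_remove <= 1.0):
            raise SchemaError("require 0 < p_enter <= p_remove <= 1")
        if self.max_features < 1:
            raise SchemaError("max_features must be >= 1")


@dataclass
class SWLDAModel:
    """Fitted discriminant: ordered included columns, weights, intercept."""

    included: np.ndarray  # feature-column indices, in order of entry
    weights: np.ndarray  # one weight per included column
    intercept: float
    config: SWLDAConfig
    feature_map: tuple[tuple[str, int], ...]
    n_columns: int

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-epoch discriminant score: dot(weights, features) + intercept."""
        X = np.asarray(X)
        if X.shape[1] < self.n_columns:
            raise SchemaError("feature matrix has fewer columns than the model")
        return X[:, self.included] @ self.weights + self.intercept

    # ---- JSON serialization --------------------------------------------
    def to_dict(self) -> dict:
        return {
            "included": self.included.tolist(),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "config": {
                "max_features": self.config.max_features,
                "p_enter": self.config.p_enter,
                "p_remove": self.config.p_remove,
                "max_iterations": self.config.max_iterations,
            },
            "feature_map": [list(t) for t in self.feature_map],
            "n_columns": self.n_columns,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "SWLDAModel":
        return cls(
            included=np.asarray(d["included"], dtype=np.int64),
            weights=np.asarray(d["weights"], dtype=np.float64),
            intercept=float(d["intercept"]),
            config=SWLDAConfig(**d["config"]),
            feature_map=tuple((ch, int(b)) for ch, b in d["feature_map"]),
            n_columns=int(d["n_columns"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SWLDAModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---- sweep-operator stepwise core ---------------------------------------


def _sweep(A: np.ndarray, k: int) -> None:
    d = A[k, k]
    row = A[k].copy()
    col = A[:, k].copy()
    A -= np.outer(col, row) / d
    A[k, :] = row / d
    A[:, k] = col / d
    A[k, k] = -1.0 / d


def _unsweep(A: np.ndarray, k: int) -> None:
    d = A[k, k]
    row = A[k].copy()
    col = A[:, k].copy()
    A -= np.outer(col, row) / d
    A[k, :] = -row / d
    A[:, k] = -col / d
    A[k, k] = -1.0 / d


@lru_cache(maxsize=64)
def _f_crit_table(p_level: float, n: int) -> np.ndarray:
    """F threshold with (1, df2) dof per df2 in 0..n; index 0 is +inf."""
    out = np.full(n + 1, np.inf)
    if n >= 1:
        out[1:] = f_dist.isf(p_level, 1, np.arange(1, n + 1))
    return out


def _stepwise_python(
    A: np.ndarray,
    n: int,
    cfg: SWLDAConfig,
    crit_enter: np.ndarray,
    crit_remove: np.ndarray,
) -> list[int]:
    """Reference numpy implementation of the stepwise entry/removal loop."""
    p = A.shape[0] - 1
    diag0 = np.maximum(np.diag(A)[:p].copy(), 1.0)
    in_mask = np.zeros(p, dtype=bool)
    order: list[int] = []
    tol = 1e-10

    for _ in range(cfg.max_iterations):
        changed = False
        k = len(order)
        # --- entry: candidate with the largest partial F (smallest p)
        df2 = n - k - 2
        if k < cfg.max_features and df2 >= 1:
            d = np.diag(A)[:p]
            ok = (~in_mask) & (d > tol * diag0)
            if ok.any():
                ssr = np.where(ok, A[:p, p] ** 2 / np.where(ok, d, 1.0), -1.0)
                sse = A[p, p]
                denom = np.maximum(sse - ssr, 1e-300)
                F = np.where(ok, ssr * df2 / denom, -1.0)
                j = int(np.argmax(F))
                if F[j] > crit_enter[df2]:
                    _sweep(A, j)
                    in_mask[j] = True
                    order.append(j)
                    changed = True
        # --- removal: repeat while the worst included column fails p_remove
        while order:
            k = len(order)
            df2 = n - k - 1
            if df2 < 1:
                break
            idx = np.asarray(order)
            b = A[idx, p]
            c = np.maximum(-np.diag(A)[idx], 1e-300)
            sse = A[p, p]
            F = b * b / c / (sse / df2)
            jj = int(np.argmin(F))
            if F[jj] < crit_remove[df2]:
                _unsweep(A, idx[jj])
                in_mask[idx[jj]] = False
                order.pop(jj)
                changed = True
            else:
                break
        if not changed:
            break
    return order


try:  # optional numba fast path; bit-identical to _stepwise_python
    from ._stepwise_nb import stepwise_nb as _stepwise_fast
except ImportError:  # pragma: no cover - numba is normally available
    _stepwise_fast = None


def stepwise_crossproducts(
    S: np.ndarray,
    n: int,
    cfg: SWLDAConfig,
    crit_enter: np.ndarray | None = None,
    crit_remove: np.ndarray | None = None,
    engine: str = "auto",
) -> tuple[list[int], np.ndarray]:
    """Run the stepwise entry/removal loop on centered cross-products.

    ``S`` is the (p+1)×(p+1) centered matrix of [X, y]; the last row/column
    is the label.  Returns the included columns in entry order and their
    OLS coefficients.  Rank-deficient candidates (adjusted sum of squares
    numerically zero) are skipped.  ``engine`` selects the compiled fast
    path ("auto"/"numba") or the reference numpy loop ("python"); both give
    identical selections.
    """
    A = np.array(S, dtype=np.float64, copy=True)
    if crit_enter is None:
        crit_enter = _f_crit_table(cfg.p_enter, n)
    if crit_remove is None:
        crit_remove = _f_crit_table(cfg.p_remove, n)
    if engine == "auto":
        engine = "numba" if _stepwise_fast is not None else "python"
    if engine == "numba":
        out = _stepwise_fast(
            A, n, cfg.max_features, cfg.max_iterations, crit_enter, crit_remove
        )
        order = [int(j) for j in out]
    elif engine == "python":
        order = _stepwise_python(A, n, cfg, crit_enter, crit_remove)
    else:
        raise SchemaError(f"unknown stepwise engine {engine!r}")
    if not order:
        return [], np.empty(0)
    p = A.shape[0] - 1
    idx = np.asarray(order)
    return order, A[idx, p].copy()


def fit_swlda(fm: FeatureMatrix, cfg: SWLDAConfig | None = None) -> SWLDAModel:
    """Calibrate an SWLDA discriminant on a labeled feature matrix."""
    cfg = cfg or SWLDAConfig()
    y = np.asarray(fm.y, dtype=np.float64)
    n_pos = int((y > 0).sum())
    n_neg = int((y < 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise CalibrationError("both target and non-target epochs are required")
    if n_pos < 2 or n_neg < 2:
        raise CalibrationError("need at least 2 epochs per class")
    X = fm.X
    n = X.shape[0]
    Z = np.column_stack([X, y])
    m = Z.mean(axis=0)
    S = Z.T @ Z - n * np.outer(m, m)
    order, w = stepwise_crossproducts(S, n, cfg)
    if not order:
        raise CalibrationError(
            "no feature met the entry criterion; session could not calibrate"
        )
    intercept = float(m[-1] - m[np.asarray(order)] @ w)
    return SWLDAModel(
        included=np.asarray(order, dtype=np.int64),
        weights=np.asarray(w, dtype=np.float64),
        intercept=intercept,
        config=cfg,
        feature_map=fm.feature_map,
        n_columns=fm.n_cols,
    )


# ---- trial scoring and classification -----------------------------------


@dataclass
class TrialScores:
    """Summed per-(trial, choice) discriminant scores over the first r flashes."""

    scores: np.ndarray  # (n_trials, n_choices)
    r: int
    target_choice: np.ndarray = field(default=None)  # optional convenience

    def __post_init__(self) -> None:
        if self.r < 1:
            raise SchemaError("repetitions r must be >= 1")


def _choice_rep_tensor(model: SWLDAModel, fm: FeatureMatrix) -> np.ndarray:
    """Per-flash scores binned into a (trial, choice, repetition) tensor."""
    s = model.predict_scores(fm.X)
    out = np.zeros((fm.n_trials, fm.n_choices, fm.flashes_per_choice))
    out[fm.trial, fm.flashed_label, fm.repetition] = s
    return out


def score_trials(model: SWLDAModel, fm: FeatureMatrix, r: int | None = None) -> TrialScores:
    """Sum flash scores per (trial, choice) over each choice's first r flashes."""
    r = fm.flashes_per_choice if r is None else int(r)
    if not (1 <= r <= fm.flashes_per_choice):
        raise SchemaError("r must lie in 1..flashes_per_choice")
    t = _choice_rep_tensor(model, fm)
    return TrialScores(
        scores=t[:, :, :r].sum(axis=2), r=r, target_choice=fm.target_choice
    )


def classify(ts: TrialScores) -> np.ndarray:
    """Predicted choice per trial: argmax score, ties to the lowest index."""
    return np.argmax(ts.scores, axis=1)


def accuracy(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Fraction of trials classified correctly."""
    predictions = np.asarray(predictions)
    targets = np.asarray(targets)
    if predictions.shape != targets.shape:
        raise SchemaError("predictions and targets differ in length")
    return float((predictions == targets).mean())


def accuracy_by_flashes(model: SWLDAModel, fm: FeatureMatrix) -> np.ndarray:
    """Trial accuracy at every flash count r = 1..flashes_per_choice."""
    t = _choice_rep_tensor(model, fm)
    cum = np.cumsum(t, axis=2)  # (trial, choice, r)
    pred = np.argmax(cum, axis=1)  # (trial, r)
    return (pred == fm.target_choice[:, None]).mean(axis=0)


@dataclass
class TieBreakResult:
    acc_a: float
    acc_b: float
    r_used: int
    tied: bool


def break_tie_by_flashes(
    model_a: SWLDAModel,
    model_b: SWLDAModel,
    fm_a: FeatureMatrix,
    fm_b: FeatureMatrix,
) -> TieBreakResult:
    """Compare two calibrations, shrinking the flash count to break ties.

    Accuracies are compared at the full flash count first; on a tie the
    count is decreased (r = R−1, R−2, …, 1) and the first differing r is
    reported.  If every r ties, r_used = 1 with the tied flag set.
    """
    if fm_a.n_trials != fm_b.n_trials or not np.array_equal(
        fm_a.target_choice, fm_b.target_choice
    ):
        raise SchemaError("tie-break requires both models scored on the same trials")
    acc_a = accuracy_by_flashes(model_a, fm_a)
    acc_b = accuracy_by_flashes(model_b, fm_b)
    for r in range(fm_a.flashes_per_choice, 0, -1):
        if acc_a[r - 1] != acc_b[r - 1]:
            return TieBreakResult(float(acc_a[r - 1]), float(acc_b[r - 1]), r, False)
    return TieBreakResult(float(acc_a[0]), float(acc_b[0]), 1, True)
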