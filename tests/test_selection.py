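import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from p300select import (
    SelectionConfig,
    SelectionError,
    STANDARD_MONTAGE,
    consensus_select,
    exhaustive_select,
    forward_select,
    generalization_experiment,
    score_fold_orders,
    subset_size_curve,
)
from p300select.selection import SelectionResult, _greedy

from conftest import TOY_CHANNELS, toy_session


def fake_evaluator(table):
    """Evaluator driven by a {frozenset: accuracy} lookup (default 0)."""

    def evaluate(channels):
        return table.get(frozenset(channels), 0.0), "model"

    return evaluate


class TestGreedy:
    def test_single_informative_channel_selected_first(self):
        """One channel dominates every step-1 candidate accuracy."""
        es = toy_session(seed=1, center=(-2.0, 0.0), spread=0.4, amplitude=20.0, noise=2.0)
        cfg = SelectionConfig(subset_size=2, pool=TOY_CHANNELS)
        res = forward_select(es, cfg)
        assert res.order[0] == "C3"
        step1 = res.evaluations[0]
        assert max(step1, key=step1.get) == "C3"
        assert step1["C3"] > max(v for k, v in step1.items() if k != "C3")

    def test_full_pool_is_permutation(self):
        table = {}
        evaluate = fake_evaluator(table)
        cfg = SelectionConfig(subset_size=4, pool=("a", "b", "c", "d"))
        rng = np.random.default_rng(0)
        table.update(
            {
                frozenset(s): rng.random()
                for s in _all_subsets(("a", "b", "c", "d"))
            }
        )
        res = _greedy(evaluate, ("a", "b", "c", "d"), 4)
        assert sorted(res.order) == ["a", "b", "c", "d"]

    def test_each_step_attains_recorded_maximum(self):
        es = toy_session(seed=2)
        res = forward_select(es, SelectionConfig(subset_size=3, pool=TOY_CHANNELS))
        for step, (name, acc) in enumerate(zip(res.order, res.accuracy_trajectory)):
            assert res.evaluations[step][name] == acc
            assert acc == max(res.evaluations[step].values())

    def test_tie_prefers_earlier_pool_order(self):
        table = {frozenset({c}): 0.5 for c in "abcd"}
        res = _greedy(fake_evaluator(table), ("a", "b", "c", "d"), 1)
        assert res.order == ("a",)

    def test_all_candidates_failing_raises(self):
        def evaluate(channels):
            return 0.0, None

        with pytest.raises(SelectionError):
            _greedy(evaluate, ("a", "b"), 1)


def _all_subsets(pool):
    import itertools

    for r in range(1, len(pool) + 1):
        yield from itertools.combinations(pool, r)


class TestExhaustive:
    def test_enumerates_all_pairs(self):
        es = toy_session(seed=3, channels=("F3", "Fz", "C3", "Cz"))
        subset, acc, count = exhaustive_select(es, 2, pool=("F3", "Fz", "C3", "Cz"))
        assert count == 6

    def test_informative_channel_always_in_winner(self):
        es = toy_session(seed=4, center=(-2.0, 0.0), spread=0.4, amplitude=20.0,
                         noise=2.0, channels=("F3", "Fz", "C3", "Cz"))
        subset, acc, _ = exhaustive_select(es, 2, pool=("F3", "Fz", "C3", "Cz"))
        assert "C3" in subset

    def test_full_pool_returns_pool(self):
        es = toy_session(seed=5, channels=("F3", "Fz", "C3"))
        subset, acc, count = exhaustive_select(es, 3, pool=("F3", "Fz", "C3"))
        assert subset == ("F3", "Fz", "C3")
        assert count == 1

    def test_guard_on_combination_count(self):
        es = toy_session(seed=6)
        with pytest.raises(SelectionError):
            exhaustive_select(es, 3, pool=TOY_CHANNELS, max_combinations=5)


class TestConsensusScoring:
    def test_worked_example(self):
        """Folds [A,B] and [B,C] with M=2 over pool {A,B,C,D}:
        A scores 2, B scores 3, C scores 1, D scores 0; chosen = {B, A}."""
        res = score_fold_orders([("A", "B"), ("B", "C")], 2, ("A", "B", "C", "D"))
        assert res.scores == {"A": 2, "B": 3, "C": 1, "D": 0}
        assert set(res.chosen) == {"A", "B"}
        assert res.chosen[0] == "B"  # highest score first

    def test_identical_folds(self):
        folds = [("C", "A", "B")] * 5
        res = score_fold_orders(folds, 3, ("A", "B", "C", "D"))
        assert res.chosen == ("C", "A", "B")
        assert res.scores == {"C": 15, "A": 10, "B": 5, "D": 0}

    def test_tie_broken_by_best_rank_then_pool_order(self):
        # B and C tie on score 3; C once ranked 1st, B twice 2nd -> C wins
        res = score_fold_orders([("A", "B"), ("C",), ("A", "B")], 2, ("A", "B", "C"))
        assert res.scores == {"A": 4, "B": 2, "C": 2}
        assert res.chosen == ("A", "C")
        # equal scores and equal best rank -> pool order
        res2 = score_fold_orders([("A",), ("B",)], 1, ("A", "B"))
        assert res2.chosen == ("A",)

    def test_duplicate_in_fold_rejected(self):
        with pytest.raises(SelectionError):
            score_fold_orders([("A", "A")], 2, ("A", "B"))

    @given(st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_bruteforce_formula(self, data):
        """Scores equal a direct evaluation of sum-over-folds max(0, M-k+1)."""
        pool = tuple("ABCDEFGH"[: data.draw(st.integers(3, 8))])
        M = data.draw(st.integers(1, len(pool)))
        n_folds = data.draw(st.integers(1, 6))
        folds = []
        for _ in range(n_folds):
            k = data.draw(st.integers(0, M))
            folds.append(tuple(data.draw(st.permutations(pool))[:k]))
        res = score_fold_orders(folds, M, pool)
        for e in pool:
            expected = 0
            for order in folds:
                if e in order:
                    expected += max(0, M - (order.index(e) + 1) + 1)
            assert res.scores[e] == expected


class TestConsensusSelect:
    def test_composes_from_per_fold_orders(self):
        """Consensus on N=3 trials equals score_fold_orders applied to the
        three leave-one-out forward selections run independently."""
        es = toy_session(seed=7, n_trials=3, amplitude=8.0, noise=3.0)
        cfg = SelectionConfig(subset_size=2, pool=TOY_CHANNELS)
        cons, model = consensus_select(es, cfg)
        manual = []
        for i in range(3):
            sub = es.take_trials([t for t in range(3) if t != i])
            manual.append(forward_select(sub, cfg).order)
        expected = score_fold_orders(manual, 2, TOY_CHANNELS)
        assert cons.fold_orders == [tuple(o) for o in manual]
        assert cons.scores == expected.scores
        assert cons.chosen == expected.chosen
        assert len(model.included) >= 1

    def test_noise_free_informative_pair_recovered(self):
        """Strong planted channels with near-zero noise are the consensus
        choice in every fold."""
        es = toy_session(seed=8, n_trials=8, center=(-2.0, 0.0), spread=0.4,
                         amplitude=20.0, noise=3.0)
        cfg = SelectionConfig(subset_size=1, pool=TOY_CHANNELS)
        cons, _ = consensus_select(es, cfg)
        assert cons.chosen == ("C3",)

    def test_single_trial_rejected(self):
        es = toy_session(seed=9, n_trials=1)
        with pytest.raises(SelectionError):
            consensus_select(es, SelectionConfig(subset_size=2, pool=TOY_CHANNELS))


class TestSubsetSizeCurve:
    def test_flat_trajectory_needs_one(self):
        res = SelectionResult(("a", "b", "c"), np.array([0.8, 0.8, 0.8]), [])
        assert subset_size_curve(res).electrodes_needed == 1

    def test_worked_trajectory_needs_five(self):
        traj = np.array([0.4, 0.6, 0.8, 0.9, 0.95, 0.96, 0.96, 0.96])
        res = SelectionResult(tuple("abcdefgh"), traj, [])
        curve = subset_size_curve(res)
        assert curve.electrodes_needed == 5  # threshold 0.912
        assert np.array_equal(curve.sizes, np.arange(1, 9))

    def test_zero_final_accuracy_degenerates_to_one(self):
        res = SelectionResult(("a", "b"), np.array([0.0, 0.0]), [])
        assert subset_size_curve(res).electrodes_needed == 1


class TestGeneralization:
    def _session(self):
        return toy_session(seed=10, n_trials=24, amplitude=10.0, noise=3.0)

    def test_deterministic_given_seed(self):
        es = self._session()
        cfg = SelectionConfig(subset_size=2, pool=TOY_CHANNELS)
        a = generalization_experiment(es, seed=3, cfg=cfg, n_test=6, min_trials=24)
        b = generalization_experiment(es, seed=3, cfg=cfg, n_test=6, min_trials=24)
        assert a.to_dict() == b.to_dict()
        assert np.array_equal(a.test_trials, b.test_trials)

    def test_too_few_trials_rejected(self):
        es = toy_session(seed=11, n_trials=4)
        with pytest.raises(SelectionError):
            generalization_experiment(es, seed=0)

    def test_holdout_and_calibration_disjoint(self):
        es = self._session()
        cfg = SelectionConfig(subset_size=2, pool=TOY_CHANNELS)
        rep = generalization_experiment(es, seed=5, cfg=cfg, n_test=6, min_trials=24)
        assert len(np.intersect1d(rep.test_trials, rep.calibration_trials)) == 0
        assert len(rep.test_trials) == 6
        assert len(rep.calibration_trials) == 18
        assert len(rep.chosen) == 2
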