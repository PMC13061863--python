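import dataclasses

import numpy as np
import pytest

from p300select import (
    CalibrationError,
    FeatureConfig,
    SWLDAConfig,
    SchemaError,
    accuracy,
    accuracy_by_flashes,
    break_tie_by_flashes,
    classify,
    extract_features,
    fit_swlda,
    score_trials,
)
from p300select.features import FeatureMatrix
from p300select.swlda import SWLDAModel, stepwise_crossproducts

from conftest import toy_session


def _make_fm(X, y, n_trials, labels2d, targets):
    """Assemble a FeatureMatrix directly from arrays (single channel)."""
    n_rows, n_cols = X.shape
    n_fl = n_rows // n_trials
    rep = np.zeros((n_trials, n_fl), dtype=np.int64)
    for c in range(4):
        mask = labels2d == c
        rep[mask] = (np.cumsum(mask, axis=1) - 1)[mask]
    return FeatureMatrix(
        X=X,
        y=y,
        trial=np.repeat(np.arange(n_trials), n_fl),
        flash_event=np.tile(np.arange(n_fl), n_trials),
        flashed_label=labels2d.ravel(),
        repetition=rep.ravel(),
        target_choice=targets,
        feature_map=tuple(("X", b) for b in range(n_cols)),
        channels=("X",),
        n_choices=4,
        flashes_per_choice=n_fl // 4,
        sample_rate=256.0,
        config=FeatureConfig(),
    )


def _random_fm(rng, n_trials=5, n_cols=12, signal=0.0):
    labels2d = np.array(
        [np.concatenate([rng.permutation(4) for _ in range(10)]) for _ in range(n_trials)]
    )
    targets = rng.integers(0, 4, n_trials)
    y = np.where(labels2d == targets[:, None], 1, -1).ravel()
    X = rng.standard_normal((n_trials * 40, n_cols))
    X[:, 0] += signal * y
    return _make_fm(X, y.astype(np.int64), n_trials, labels2d, targets)


class TestFitSwlda:
    def test_full_entry_equals_ols(self):
        """With p_enter = p_remove = 1 and a full-rank design the stepwise
        fit must reproduce the direct least-squares solution."""
        rng = np.random.default_rng(7)
        fm = _random_fm(rng, n_trials=6, n_cols=10, signal=0.5)
        cfg = SWLDAConfig(max_features=20, p_enter=1.0, p_remove=1.0)
        model = fit_swlda(fm, cfg)
        assert len(model.included) == fm.n_cols
        A = np.column_stack([fm.X, np.ones(fm.n_rows)])
        beta, *_ = np.linalg.lstsq(A, fm.y.astype(float), rcond=None)
        w_full = np.zeros(fm.n_cols)
        w_full[model.included] = model.weights
        assert np.abs(w_full - beta[:-1]).max() < 1e-8
        assert abs(model.intercept - beta[-1]) < 1e-8

    def test_single_class_rejected(self):
        rng = np.random.default_rng(1)
        fm = _random_fm(rng)
        fm = dataclasses.replace(fm, y=np.ones_like(fm.y))
        with pytest.raises(CalibrationError):
            fit_swlda(fm)

    def test_no_entering_feature_is_calibration_failure(self):
        """Pure noise with a sky-high entry bar must fail to calibrate."""
        rng = np.random.default_rng(2)
        fm = _random_fm(rng, signal=0.0)
        with pytest.raises(CalibrationError):
            fit_swlda(fm, SWLDAConfig(p_enter=1e-12, p_remove=1e-11))

    def test_feature_cap_respected(self):
        rng = np.random.default_rng(3)
        fm = _random_fm(rng, n_trials=8, n_cols=40, signal=0.3)
        model = fit_swlda(fm, SWLDAConfig(max_features=5, p_enter=1.0, p_remove=1.0))
        assert len(model.included) == 5

    def test_separable_data_classifies_perfectly(self):
        """High-SNR session: resubstitution trial accuracy 1.0, confirmed
        separable by an independent LDA on the same features."""
        es = toy_session(seed=21, n_trials=6, amplitude=40.0, noise=1.0)
        fm = extract_features(es)
        model = fit_swlda(fm)
        acc = accuracy_by_flashes(model, fm)[-1]
        assert acc == 1.0
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        lda = LinearDiscriminantAnalysis().fit(fm.X, fm.y)
        assert lda.score(fm.X, fm.y) > 0.95

    def test_converged_model_is_a_stepwise_fixed_point(self):
        """At convergence no excluded column passes the entry criterion and
        no included column fails the removal criterion (checked against
        partial-F p-values recomputed independently with lstsq)."""
        from scipy.stats import f as f_dist

        rng = np.random.default_rng(8)
        fm = _random_fm(rng, n_trials=6, n_cols=15, signal=0.4)
        cfg = SWLDAConfig(p_enter=0.05, p_remove=0.05)
        model = fit_swlda(fm, cfg)
        y = fm.y.astype(float)
        n = fm.n_rows
        inc = list(model.included)

        def sse_of(cols):
            A = np.column_stack([fm.X[:, cols], np.ones(n)])
            resid = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
            return resid @ resid

        sse_inc = sse_of(inc)
        k = len(inc)
        for j in range(fm.n_cols):
            if j in inc:
                continue
            sse_j = sse_of(inc + [j])
            df2 = n - k - 2
            F = (sse_inc - sse_j) * df2 / sse_j
            assert f_dist.sf(F, 1, df2) >= cfg.p_enter
        for j in inc:
            rest = [c for c in inc if c != j]
            sse_r = sse_of(rest) if rest else np.sum((y - y.mean()) ** 2)
            df2 = n - k - 1
            F = (sse_r - sse_inc) * df2 / sse_inc
            assert f_dist.sf(F, 1, df2) <= cfg.p_remove

    def test_engines_agree(self):
        """Compiled and reference stepwise loops select identical features
        with identical weights."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            n, p = 200, 24
            X = rng.standard_normal((n, p))
            y = np.where(rng.random(n) < 0.25, 1.0, -1.0)
            X[:, 3] += 0.4 * y
            Z = np.column_stack([X, y])
            m = Z.mean(axis=0)
            S = Z.T @ Z - n * np.outer(m, m)
            cfg = SWLDAConfig()
            o1, w1 = stepwise_crossproducts(S, n, cfg, engine="python")
            o2, w2 = stepwise_crossproducts(S, n, cfg, engine="numba")
            assert o1 == o2
            assert np.array_equal(w1, w2)

    def test_model_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        fm = _random_fm(rng, signal=0.6)
        model = fit_swlda(fm)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = SWLDAModel.load(path)
        assert np.array_equal(loaded.included, model.included)
        assert np.allclose(loaded.weights, model.weights)
        assert loaded.config == model.config
        assert loaded.feature_map == model.feature_map


class TestScoring:
    def test_zero_weights_give_intercept_times_r(self):
        rng = np.random.default_rng(5)
        fm = _random_fm(rng)
        model = SWLDAModel(
            included=np.array([0]),
            weights=np.array([0.0]),
            intercept=2.5,
            config=SWLDAConfig(),
            feature_map=fm.feature_map,
            n_columns=fm.n_cols,
        )
        for r in (1, 4, 10):
            ts = score_trials(model, fm, r=r)
            assert np.allclose(ts.scores, 2.5 * r)

    def test_matches_bruteforce_accumulation(self):
        """score_trials equals a naive per-epoch loop over first-r flashes."""
        rng = np.random.default_rng(6)
        fm = _random_fm(rng, signal=0.3)
        model = fit_swlda(fm)
        s = model.predict_scores(fm.X)
        for r in (1, 3, 10):
            expected = np.zeros((fm.n_trials, 4))
            seen = {}
            for i in range(fm.n_rows):
                t, c = fm.trial[i], fm.flashed_label[i]
                k = seen.get((t, c), 0)
                if k < r:
                    expected[t, c] += s[i]
                seen[(t, c)] = k + 1
            ts = score_trials(model, fm, r=r)
            assert np.allclose(ts.scores, expected)

    def test_classify_tie_breaks_to_lowest_index(self):
        from p300select.swlda import TrialScores

        ts = TrialScores(scores=np.array([[1.0, 1.0, 0.0, 1.0]]), r=1)
        assert classify(ts)[0] == 0

    def test_classification_equivariant_under_trial_shuffle(self):
        rng = np.random.default_rng(12)
        fm = _random_fm(rng, signal=0.5)
        model = fit_swlda(fm)
        pred = classify(score_trials(model, fm))
        perm = rng.permutation(fm.n_trials)
        # shuffle trials by reordering rows
        row_order = np.concatenate([np.where(fm.trial == t)[0] for t in perm])
        fm2 = dataclasses.replace(
            fm,
            X=fm.X[row_order],
            y=fm.y[row_order],
            trial=np.repeat(np.arange(fm.n_trials), 40),
            flash_event=fm.flash_event[row_order],
            flashed_label=fm.flashed_label[row_order],
            repetition=fm.repetition[row_order],
            target_choice=fm.target_choice[perm],
        )
        pred2 = classify(score_trials(model, fm2))
        assert np.array_equal(pred2, pred[perm])

    @pytest.mark.parametrize(
        "pred,tgt,expected",
        [([0, 1, 2], [0, 1, 2], 1.0), ([0, 0, 0], [1, 1, 1], 0.0), ([0, 1, 2, 3], [0, 1, 2, 0], 0.75)],
    )
    def test_accuracy_fractions(self, pred, tgt, expected):
        assert accuracy(np.array(pred), np.array(tgt)) == expected

    def test_invalid_r_rejected(self):
        rng = np.random.default_rng(13)
        fm = _random_fm(rng, signal=0.5)
        model = fit_swlda(fm)
        with pytest.raises(SchemaError):
            score_trials(model, fm, r=11)


class TestTieBreak:
    def _scripted_pair(self, scores_a, scores_b):
        """Two single-feature models whose per-flash scores are scripted, so
        per-r accuracies are fully controlled."""
        n_trials = scores_a.shape[0]
        labels2d = np.tile(np.concatenate([np.arange(4)] * 10), (n_trials, 1))
        targets = np.zeros(n_trials, dtype=np.int64)
        y = np.where(labels2d == targets[:, None], 1, -1).ravel()

        def fm_for(scorestensor):
            # scorestensor: (trials, 4, 10) per-flash desired scores
            X = np.zeros((n_trials * 40, 1))
            flat = scorestensor.transpose(0, 2, 1).reshape(n_trials, 40)
            # labels2d blocks are 0,1,2,3 repeated; flash j in block b is choice j%4
            X[:, 0] = flat.ravel()
            return _make_fm(X, y, n_trials, labels2d, targets)

        model = SWLDAModel(
            included=np.array([0]),
            weights=np.array([1.0]),
            intercept=0.0,
            config=SWLDAConfig(),
            feature_map=(("X", 0),),
            n_columns=1,
        )
        return model, fm_for(scores_a), fm_for(scores_b)

    def test_difference_at_full_flash_count(self):
        # model A correct (choice 0 dominant), model B wrong on trial 0
        a = np.zeros((2, 4, 10)); a[:, 0, :] = 1.0
        b = np.zeros((2, 4, 10)); b[0, 1, :] = 1.0; b[1, 0, :] = 1.0
        model, fm_a, fm_b = self._scripted_pair(a, b)
        res = break_tie_by_flashes(model, model, fm_a, fm_b)
        assert (res.r_used, res.tied) == (10, False)
        assert (res.acc_a, res.acc_b) == (1.0, 0.5)

    def test_tie_at_ten_broken_at_nine(self):
        """Scores engineered to agree at r = 10 but differ at r = 9."""
        a = np.zeros((1, 4, 10)); a[0, 0, :] = 1.0          # correct at every r
        b = np.zeros((1, 4, 10))
        b[0, 1, :9] = 1.0                                    # wrong through r=9
        b[0, 0, 9] = 10.0                                    # rescued only at r=10
        model, fm_a, fm_b = self._scripted_pair(a, b)
        res = break_tie_by_flashes(model, model, fm_a, fm_b)
        assert (res.r_used, res.tied) == (9, False)
        assert (res.acc_a, res.acc_b) == (1.0, 0.0)

    def test_identical_models_tie_at_one(self):
        a = np.zeros((2, 4, 10)); a[:, 0, :] = 1.0
        model, fm_a, fm_b = self._scripted_pair(a, a.copy())
        res = break_tie_by_flashes(model, model, fm_a, fm_b)
        assert (res.r_used, res.tied) == (1, True)
        assert res.acc_a == res.acc_b

    def test_mismatched_trials_rejected(self):
        a = np.zeros((2, 4, 10)); a[:, 0, :] = 1.0
        model, fm_a, fm_b = self._scripted_pair(a, a)
        fm_b = dataclasses.replace(fm_b, target_choice=fm_b.target_choice + 1)
        with pytest.raises(SchemaError):
            break_tie_by_flashes(model, model, fm_a, fm_b)
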