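"""Cohort-level simulation studies reproducing the qualitative findings.

These are the end-to-end experiments the package exists to support, run on
synthetic cohorts at desk scale:

* ``severe_recovery_study`` — spatially atypical (severe) subjects: does
  leave-one-trial-out consensus selection recover the planted informative
  electrodes, and does the custom subset beat the default-8 calibration
  accuracy, individually confirmed by the binomial test?
* ``typical_null_study`` — typical subjects with broad topographies: the
  custom subset should give no systematic calibration gain, and held-out
  testing differences should center near zero.
* ``chance_level_study`` — amplitude-0 (pure noise) subjects: held-out
  trial accuracy must sit at the 1/4 chance level.  Resubstitution accuracy
  is *not* used here: stepwise feature selection makes in-sample accuracy
  optimistically biased even on noise, so only out-of-sample accuracy is an
  unbiased chance check.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .errors import CalibrationError
from .features import extract_features
from .montage import STANDARD_MONTAGE
from .pipeline import PipelineConfig, run_calibration_comparison
from .selection import SessionEvaluator, consensus_select, generalization_experiment
from .simulate import (
    SimulationConfig,
    get_preset,
    informative_channels,
    make_cohort,
    simulate_subject,
)
from .sessions import ProtocolSpec
from .stats import binomial_improvement_test

__all__ = ["severe_recovery_study", "typical_null_study", "chance_level_study"]


def severe_recovery_study(
    n_subjects: int = 20,
    base_seed: int = 42,
    n_trials: int = 30,
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Consensus selection on severe-atypical subjects vs the default 8.

    Per subject: simulate a 30-trial session, run leave-one-trial-out
    consensus selection (M = 8 from all 32 channels), fit the final custom
    SWLDA and the default-8 SWLDA on all trials, and compare calibration
    accuracies with the binomial improvement test.  Recovery means the
    preset's planted informative channels (disjoint from the default 8)
    all appear in the chosen subset.
    """
    cfg = cfg or PipelineConfig()
    planted = set(informative_channels(get_preset("severe_atypical"), STANDARD_MONTAGE))
    members = make_cohort({"severe_atypical": n_subjects}, base_seed, n_trials=n_trials)
    rows = []
    for m in members:
        es = m.simulate()
        fm = extract_features(es, cfg.feature)
        ev = SessionEvaluator(fm, cfg.swlda)
        acc_default, _ = ev.evaluate(es.montage.default8)
        consensus, model = consensus_select(es, cfg.selection())
        acc_custom = ev.accuracy_of(model)
        n = es.n_trials
        test = binomial_improvement_test(
            n, round(acc_default * n), round(acc_custom * n)
        )
        rows.append(
            {
                "subject": m.subject_id,
                "acc_default": acc_default,
                "acc_custom": acc_custom,
                "improvement": acc_custom - acc_default,
                "p_value": test.p_value,
                "recovered": planted <= set(consensus.chosen),
                "chosen": ",".join(consensus.chosen),
            }
        )
    df = pd.DataFrame(rows)
    summary = {
        "n_subjects": n_subjects,
        "planted": sorted(planted),
        "recovery_rate": float(df["recovered"].mean()),
        "mean_improvement": float(df["improvement"].mean()),
        "frac_significant": float((df["p_value"] < 0.05).mean()),
        "mean_acc_default": float(df["acc_default"].mean()),
        "mean_acc_custom": float(df["acc_custom"].mean()),
    }
    return df, summary


def typical_null_study(
    n_subjects: int = 20,
    base_seed: int = 42,
    n_trials: int = 60,
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Typical-profile control: calibration and held-out null comparisons.

    Each subject gets a 60-trial session.  The first 30 trials feed the
    standard calibration comparison (forward-selected custom 8 vs default
    8); the full session feeds the 20-trial-holdout generalization
    experiment (consensus subset vs default 8 applied to unseen trials).
    Differences are custom minus default at the full flash count.
    """
    cfg = cfg or PipelineConfig()
    members = make_cohort({"typical": n_subjects}, base_seed, n_trials=n_trials)
    rows = []
    ss = np.random.SeedSequence(base_seed)
    holdout_seeds = ss.generate_state(n_subjects) % (2**31 - 1)
    for m, holdout_seed in zip(members, holdout_seeds):
        es = m.simulate()
        rep = run_calibration_comparison(es, cfg)
        gen = generalization_experiment(es, int(holdout_seed), cfg.selection())
        R = len(gen.cal_acc_custom)
        rows.append(
            {
                "subject": m.subject_id,
                "cal_diff": rep["acc_custom_at_full"] - rep["acc_default_at_full"],
                "test_diff": float(gen.test_acc_custom[R - 1] - gen.test_acc_default[R - 1]),
                "test_acc_custom": float(gen.test_acc_custom[R - 1]),
                "test_acc_default": float(gen.test_acc_default[R - 1]),
                "p_value": rep["p_value"],
            }
        )
    df = pd.DataFrame(rows)
    summary = {
        "n_subjects": n_subjects,
        "mean_cal_diff": float(df["cal_diff"].mean()),
        "mean_test_diff": float(df["test_diff"].mean()),
        "frac_significant": float((df["p_value"] < 0.05).mean()),
    }
    return df, summary


def chance_level_study(
    n_subjects: int = 200,
    base_seed: int = 42,
    n_cal: int = 20,
    n_test: int = 20,
    sample_rate: float = 256.0,
    cfg: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Out-of-sample accuracy of noise-only (amplitude-0) subjects.

    Simulates the default-8 channels only (the subset under test), fits
    SWLDA on a calibration block and scores an independent test block from
    the same generative profile.  Subjects whose calibration fails (no
    feature passes the entry criterion) contribute no accuracy; their count
    is reported separately.
    """
    cfg = cfg or PipelineConfig()
    profile = replace(get_preset("typical"), artifact_rate=0.0).scale_amplitudes(0.0)
    proto = ProtocolSpec(sample_rate=sample_rate)
    channels = STANDARD_MONTAGE.default8
    ss = np.random.SeedSequence(base_seed)
    seeds = ss.generate_state(2 * n_subjects) % (2**31 - 1)
    rows = []
    for i in range(n_subjects):
        es_cal = SimulationConfig(
            profile=profile, n_trials=n_cal, protocol=proto,
            seed=int(seeds[2 * i]), channels=channels,
        )
        es_test = SimulationConfig(
            profile=profile, n_trials=n_test, protocol=proto,
            seed=int(seeds[2 * i + 1]), channels=channels,
        )
        fm_cal = extract_features(simulate_subject(es_cal), cfg.feature)
        ev_cal = SessionEvaluator(fm_cal, cfg.swlda)
        try:
            model = ev_cal.fit(channels)
        except CalibrationError:
            rows.append({"subject": i, "calibrated": False, "accuracy": np.nan})
            continue
        fm_test = extract_features(simulate_subject(es_test), cfg.feature)
        ev_test = SessionEvaluator(fm_test, cfg.swlda)
        rows.append(
            {
                "subject": i,
                "calibrated": True,
                "accuracy": ev_test.accuracy_of(model),
            }
        )
    df = pd.DataFrame(rows)
    acc = df.loc[df["calibrated"], "accuracy"]
    summary = {
        "n_subjects": n_subjects,
        "n_calibrated": int(df["calibrated"].sum()),
        "mean_accuracy": float(acc.mean()),
        "se_accuracy": float(acc.std(ddof=1) / np.sqrt(len(acc))),
        "chance_level": 0.25,
    }
    return df, summary
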