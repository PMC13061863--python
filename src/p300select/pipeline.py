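"""End-to-end orchestration: per-subject comparison and cohort studies.

``run_calibration_comparison`` reproduces the per-participant offline
analysis: fit SWLDA with the fixed default-8 subset and with a greedy
forward-selected custom-8 subset on the same calibration trials, compare
accuracies with the flash-count tie-break, and test individual improvement
with the exact binomial test.  If neither subset calibrates, the session is
retried after common-average referencing; if it still fails the subject is
reported as non-calibrating rather than raising.

``run_study`` maps the comparison over a cohort and adds group-level
descriptive summaries and the subset-size table (share of subjects within
95% of their own 8-electrode accuracy at each size).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CalibrationError, SchemaError, SelectionError
from .features import FeatureConfig, extract_features
from .selection import (
    SelectionConfig,
    SessionEvaluator,
    _first_differing_r,
    _greedy,
    subset_size_curve,
)
from .sessions import EpochSet, apply_car, average_erp, load_session_bundle, select_channels
from .simulate import CohortMember
from .stats import binomial_improvement_test, summarize_groups
from .swlda import SWLDAConfig

log = logging.getLogger("p300select")

__all__ = ["PipelineConfig", "run_calibration_comparison", "run_study", "StudyReport"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the offline analysis in one serializable block."""

    feature: FeatureConfig = field(default_factory=FeatureConfig)
    swlda: SWLDAConfig = field(default_factory=SWLDAConfig)
    subset_size: int = 8
    pool: tuple[str, ...] | None = None  # None: all recorded channels
    n_calibration_trials: int = 30
    car: str = "auto"  # "auto": fallback when neither subset calibrates
    seed: int = 0
    n_boot: int = 2000

    def __post_init__(self) -> None:
        if self.car not in ("auto", "always", "never"):
            raise SchemaError("car must be auto, always or never")

    def selection(self) -> SelectionConfig:
        return SelectionConfig(
            subset_size=self.subset_size,
            pool=self.pool,
            feature=self.feature,
            swlda=self.swlda,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "feature" in d:
            f = dict(d["feature"])
            if "window_ms" in f:
                f["window_ms"] = tuple(f["window_ms"])
            d["feature"] = FeatureConfig(**f)
        if "swlda" in d:
            d["swlda"] = SWLDAConfig(**d["swlda"])
        if d.get("pool") is not None:
            d["pool"] = tuple(d["pool"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _attempt_arms(es: EpochSet, cfg: PipelineConfig):
    """Fit the default-8 and the forward-selected custom arms on one session."""
    pool = tuple(cfg.pool) if cfg.pool is not None else es.channels
    default8 = es.montage.default8
    es_pool = select_channels(es, pool) if pool != es.channels else es
    fm = extract_features(es_pool, cfg.feature)
    ev = SessionEvaluator(fm, cfg.swlda)
    try:
        model_default = ev.fit(default8)
    except (CalibrationError, SchemaError) as e:
        log.info("default-8 arm failed to calibrate: %s", e)
        model_default = None
    try:
        sel = _greedy(ev.evaluate, pool, cfg.subset_size)
        model_custom = sel.final_model
    except SelectionError as e:
        log.info("custom arm failed to calibrate: %s", e)
        sel, model_custom = None, None
    return ev, model_default, sel, model_custom


def run_calibration_comparison(
    es: EpochSet | str | Path, cfg: PipelineConfig | None = None
) -> dict:
    """Default-8 vs custom-8 calibration comparison on one session."""
    cfg = cfg or PipelineConfig()
    if not isinstance(es, EpochSet):
        es = load_session_bundle(es)
    if es.n_trials > cfg.n_calibration_trials:
        es = es.take_trials(np.arange(cfg.n_calibration_trials))
    n = es.n_trials

    car_used = cfg.car == "always"
    if car_used:
        es = apply_car(es)
    ev, model_default, sel, model_custom = _attempt_arms(es, cfg)
    if model_default is None and model_custom is None and cfg.car == "auto":
        log.info("neither subset calibrated; retrying with CAR")
        car_used = True
        es = apply_car(es)
        ev, model_default, sel, model_custom = _attempt_arms(es, cfg)

    report: dict = {
        "n_trials": n,
        "car_used": car_used,
        "default_subset": list(es.montage.default8),
        "status": "ok",
    }
    if model_default is None and model_custom is None:
        report["status"] = "non_calibrating"
        return report

    R = es.protocol.flashes_per_choice
    zeros = np.zeros(R)
    acc_d = ev.accuracy_by_flashes(model_default) if model_default else zeros
    acc_c = ev.accuracy_by_flashes(model_custom) if model_custom else zeros
    r_used, tied = _first_differing_r(acc_c, acc_d)
    k_default = int(round(acc_d[r_used - 1] * n))
    k_custom = int(round(acc_c[r_used - 1] * n))
    test = binomial_improvement_test(n, k_default, k_custom)
    report.update(
        {
            "custom_subset": list(sel.order) if sel else [],
            "accuracy_trajectory": [float(a) for a in sel.accuracy_trajectory]
            if sel
            else [],
            "acc_default": float(acc_d[r_used - 1]),
            "acc_custom": float(acc_c[r_used - 1]),
            "acc_default_at_full": float(acc_d[R - 1]),
            "acc_custom_at_full": float(acc_c[R - 1]),
            "r_used": int(r_used),
            "tied": bool(tied),
            "k_default": k_default,
            "k_custom": k_custom,
            "p_value": float(test.p_value),
            "default_calibrated": model_default is not None,
            "custom_calibrated": model_custom is not None,
        }
    )
    if sel is not None:
        curve = subset_size_curve(sel)
        report["electrodes_needed"] = int(curve.electrodes_needed)
    log.info(
        "comparison: default %.2f custom %.2f (r=%d%s, p=%.3g)",
        report["acc_default"],
        report["acc_custom"],
        r_used,
        ", tied" if tied else "",
        test.p_value,
    )
    return report


@dataclass
class StudyReport:
    subjects: pd.DataFrame  # one row per subject
    groups: pd.DataFrame  # descriptive per-group summary
    curve_table: pd.DataFrame  # share of subjects covered at each subset size
    erp_examples: dict  # group -> ErpAverage of a representative subject

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.subjects.to_csv(out / "subjects.csv", index=False)
        self.groups.to_json(out / "groups.json", orient="records", indent=1)
        self.curve_table.to_csv(out / "subset_size_table.csv", index=False)
        for group, erp in self.erp_examples.items():
            erp.to_frame().to_csv(out / f"erp_{group}.csv", index=False)


def run_study(
    cohort: list[CohortMember] | str | Path,
    cfg: PipelineConfig | None = None,
) -> StudyReport:
    """Per-subject comparisons plus group summaries over a cohort.

    ``cohort`` is either a list of synthetic cohort members or a directory
    of session bundles (group labels then come from bundle provenance).
    """
    cfg = cfg or PipelineConfig()
    rows = []
    erp_examples: dict = {}
    sessions = _iter_cohort(cohort)
    n_subjects = 0
    for subject_id, group, es in sessions:
        n_subjects += 1
        rep = run_calibration_comparison(es, cfg)
        rep["subject"] = subject_id
        rep["group"] = group
        rows.append(rep)
        if group not in erp_examples:
            erp_examples[group] = average_erp(es)
    if n_subjects == 0:
        raise SchemaError("cohort is empty")
    subjects = pd.DataFrame(rows)
    ok = subjects[subjects["status"] == "ok"].rename(
        columns={"acc_default": "acc_default", "acc_custom": "acc_custom"}
    )
    groups = summarize_groups(
        ok[["subject", "group", "acc_default", "acc_custom", "p_value"]],
        n_boot=cfg.n_boot,
        seed=cfg.seed,
    )
    curve_rows = []
    for group, g in ok.groupby("group", sort=False):
        needed = g["electrodes_needed"].to_numpy(float)
        for m in range(1, cfg.subset_size + 1):
            curve_rows.append(
                {
                    "group": group,
                    "subset_size": m,
                    "share_reaching_95pct": float((needed <= m).mean()),
                }
            )
    return StudyReport(
        subjects=subjects,
        groups=groups,
        curve_table=pd.DataFrame(curve_rows),
        erp_examples=erp_examples,
    )


def _iter_cohort(cohort):
    if isinstance(cohort, (str, Path)):
        root = Path(cohort)
        bundles = sorted(p.parent for p in root.glob("*/metadata.json"))
        for b in bundles:
            es = load_session_bundle(b)
            group = es.provenance.get("profile", "unknown")
            yield b.name, group, es
    else:
        for member in cohort:
            yield member.subject_id, member.group, member.simulate()
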