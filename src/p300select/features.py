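"""Feature extraction: crop, detrend, and decimate epochs for SWLDA.

Each flash epoch is cropped to the response window (default 0–800 ms
post-stimulus), linearly detrended per channel, then decimated to a low
feature rate (default 20 Hz) by non-overlapping block means with integer
factor ``round(sample_rate / target_rate)``; a trailing partial block is
dropped.  Features are concatenated channel-major: all time bins of the
first channel, then the second, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError
from .sessions import EpochSet, detrend_and_center, n_window_samples

__all__ = ["FeatureConfig", "FeatureMatrix", "detrend_epoch", "extract_features"]


@dataclass(frozen=True)
class FeatureConfig:
    window_ms: tuple[float, float] = (0.0, 800.0)
    target_rate: float = 20.0
    #: "mean": block-average decimation (default); "subsample": keep every
    #: f-th sample (first of each block) for sensitivity checks.
    method: str = "mean"

    def __post_init__(self) -> None:
        if self.window_ms[0] >= self.window_ms[1]:
            raise SchemaError("feature window start must precede end")
        if self.target_rate <= 0:
            raise SchemaError("target_rate must be positive")
        if self.method not in ("mean", "subsample"):
            raise SchemaError("decimation method must be 'mean' or 'subsample'")

    def decimation_factor(self, sample_rate: float) -> int:
        f = int(round(sample_rate / self.target_rate))
        if f < 1:
            raise SchemaError("target_rate exceeds the sampling rate")
        return f

    def n_bins(self, sample_rate: float) -> int:
        f = self.decimation_factor(sample_rate)
        return n_window_samples(self.window_ms, sample_rate) // f


def detrend_epoch(x: np.ndarray) -> np.ndarray:
    """Least-squares linear detrend (removes mean and slope) along last axis."""
    return detrend_and_center(x)


@dataclass
class FeatureMatrix:
    """Decimated feature vectors, one row per flash epoch.

    ``feature_map[j] = (channel_name, bin)`` identifies column ``j``.  Row
    bookkeeping (trial, flash event, flashed label, repetition number and
    the per-trial attended choice) is carried so trial-level scoring can be
    done downstream without the original epochs.
    """

    X: np.ndarray  # (n_rows, n_cols) float64
    y: np.ndarray  # (n_rows,) +1 target / -1 non-target
    trial: np.ndarray  # (n_rows,)
    flash_event: np.ndarray  # (n_rows,)
    flashed_label: np.ndarray  # (n_rows,)
    repetition: np.ndarray  # (n_rows,) 0-based repetition of that label
    target_choice: np.ndarray  # (n_trials,)
    feature_map: tuple[tuple[str, int], ...]
    channels: tuple[str, ...]
    n_choices: int
    flashes_per_choice: int
    sample_rate: float
    config: FeatureConfig = field(default_factory=FeatureConfig)

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]

    @property
    def n_trials(self) -> int:
        return len(self.target_choice)

    @property
    def n_bins(self) -> int:
        return self.n_cols // len(self.channels)

    def columns_for(self, channel_names) -> np.ndarray:
        """Feature-column indices of ``channel_names`` (channel-major blocks)."""
        nb = self.n_bins
        out = []
        for name in channel_names:
            try:
                c = self.channels.index(name)
            except ValueError:
                raise SchemaError(f"channel {name!r} not in feature matrix") from None
            out.extend(range(c * nb, (c + 1) * nb))
        return np.asarray(out, dtype=np.int64)

    def column_names(self) -> list[str]:
        return [f"CH{ch}_T{b}" for ch, b in self.feature_map]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.column_names())
        df.insert(0, "label", self.y)
        df.insert(0, "flash_event", self.flash_event)
        df.insert(0, "trial", self.trial)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def extract_features(es: EpochSet, cfg: FeatureConfig | None = None) -> FeatureMatrix:
    """Build the SWLDA feature matrix from a labeled epoch session."""
    cfg = cfg or FeatureConfig()
    fs = es.protocol.sample_rate
    if cfg.window_ms[0] < es.window_ms[0] or cfg.window_ms[1] > es.window_ms[1]:
        raise SchemaError("feature window not covered by the epoch window")
    f = cfg.decimation_factor(fs)
    offset = int(round((cfg.window_ms[0] - es.window_ms[0]) * fs / 1000.0))
    n = n_window_samples(cfg.window_ms, fs)
    n_bins = n // f
    x = detrend_and_center(es.epochs[..., offset : offset + n])
    if cfg.method == "mean":
        dec = x[..., : n_bins * f].reshape(*x.shape[:-1], n_bins, f).mean(axis=-1)
    else:
        dec = x[..., : n_bins * f : f]
    n_tr, n_fl, n_ch, _ = dec.shape
    X = dec.transpose(0, 1, 2, 3).reshape(n_tr * n_fl, n_ch * n_bins)

    labels = es.flashed_label
    is_tgt = es.is_target().ravel()
    trial = np.repeat(np.arange(n_tr), n_fl)
    flash = np.tile(np.arange(n_fl), n_tr)
    flashed = labels.ravel()
    # repetition number: how many earlier flashes of the same label in trial
    rep = np.zeros((n_tr, n_fl), dtype=np.int64)
    for c in range(es.protocol.n_choices):
        mask = labels == c
        rep[mask] = (np.cumsum(mask, axis=1) - 1)[mask]
    feature_map = tuple(
        (ch, b) for ch in es.channels for b in range(n_bins)
    )
    return FeatureMatrix(
        X=np.ascontiguousarray(X, dtype=np.float64),
        y=np.where(is_tgt, 1, -1).astype(np.int64),
        trial=trial,
        flash_event=flash,
        flashed_label=flashed,
        repetition=rep.ravel(),
        target_choice=es.target_choice.copy(),
        feature_map=feature_map,
        channels=es.channels,
        n_choices=es.protocol.n_choices,
        flashes_per_choice=es.protocol.flashes_per_choice,
        sample_rate=fs,
        config=cfg,
    )
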