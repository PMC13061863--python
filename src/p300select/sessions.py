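"""Stimulus-locked epoch sessions: containers, referencing, ERP averaging, I/O.

A session holds every flash-locked epoch of one calibration recording from a
4-choice oddball speller: per trial the participant attends one of
``n_choices`` pictures while each picture's label flashes
``flashes_per_choice`` times.  Epochs whose flashed label matches the
attended choice are targets; the remainder are non-targets.

The on-disk form is a "session bundle": a directory with ``metadata.json``
(montage, protocol, labels, window, provenance) and the epoch array either
as HDF5 (``epochs.h5``, dataset ``epochs``, float32) or, for small text
fixtures, a long-format CSV (``epochs.csv``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import detrend as _scipy_detrend

from .errors import SchemaError
from .montage import Montage

__all__ = [
    "ProtocolSpec",
    "EpochSet",
    "ErpAverage",
    "apply_car",
    "select_channels",
    "average_erp",
    "save_session_bundle",
    "load_session_bundle",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """Paradigm timing: a 4-choice speller, 10 flashes per choice per trial.

    ``sample_rate`` is 600 Hz for the laboratory protocol and 256 Hz for the
    home-amplifier protocol; flash timing defaults to the 62.5 ms flash /
    93.75 ms gap duty cycle of the latter.
    """

    n_choices: int = 4
    flashes_per_choice: int = 10
    sample_rate: float = 600.0
    flash_duration_ms: float = 62.5
    inter_flash_interval_ms: float = 93.75

    def __post_init__(self) -> None:
        if self.n_choices < 2:
            raise SchemaError("protocol needs at least 2 choices")
        if self.flashes_per_choice < 1:
            raise SchemaError("flashes_per_choice must be >= 1")
        if self.sample_rate <= 0:
            raise SchemaError("sample_rate must be positive")

    @property
    def flashes_per_trial(self) -> int:
        return self.n_choices * self.flashes_per_choice

    def to_dict(self) -> dict:
        return {
            "n_choices": self.n_choices,
            "flashes_per_choice": self.flashes_per_choice,
            "sample_rate": self.sample_rate,
            "flash_duration_ms": self.flash_duration_ms,
            "inter_flash_interval_ms": self.inter_flash_interval_ms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        return cls(**d)


def n_window_samples(window_ms: tuple[float, float], sample_rate: float) -> int:
    """Sample count of a half-open [start, end) ms window at ``sample_rate``."""
    start, end = window_ms
    return int(np.floor((end - start) * sample_rate / 1000.0))


@dataclass
class EpochSet:
    """Labeled stimulus-locked epochs of one session.

    ``epochs`` has shape (trials, flash_events, channels, samples) in µV,
    with sample index 0 at flash onset and a half-open [start_ms, end_ms)
    window.  ``channels`` lists the channel names along axis 2 (a subset of
    the montage, in montage order unless re-ordered by
    :func:`select_channels`).
    """

    montage: Montage
    protocol: ProtocolSpec
    epochs: np.ndarray
    flashed_label: np.ndarray  # (trials, flash_events) choice index per flash
    target_choice: np.ndarray  # (trials,) attended choice per trial
    window_ms: tuple[float, float] = (0.0, 1000.0)
    channels: tuple[str, ...] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs)
        self.flashed_label = np.asarray(self.flashed_label, dtype=np.int64)
        self.target_choice = np.asarray(self.target_choice, dtype=np.int64)
        if self.channels is None:
            self.channels = self.montage.names
        else:
            self.channels = tuple(self.channels)
        self.validate()

    # ---- invariants -----------------------------------------------------
    def validate(self) -> None:
        ep = self.epochs
        if ep.ndim != 4:
            raise SchemaError("epochs must be 4-D (trial, flash, channel, sample)")
        n_tr, n_fl, n_ch, n_sa = ep.shape
        if n_tr < 1:
            raise SchemaError("session must contain at least one trial")
        if len(set(self.channels)) != len(self.channels):
            raise SchemaError("channel list contains duplicates")
        unknown = set(self.channels) - set(self.montage.names)
        if unknown:
            raise SchemaError(f"channels not in montage: {sorted(unknown)}")
        if n_ch != len(self.channels):
            raise SchemaError("channel axis does not match channel list")
        proto = self.protocol
        if n_fl != proto.flashes_per_trial:
            raise SchemaError(
                "flash-event axis must equal n_choices * flashes_per_choice"
            )
        if self.flashed_label.shape != (n_tr, n_fl):
            raise SchemaError("flashed_label must be (trials, flash_events)")
        if self.target_choice.shape != (n_tr,):
            raise SchemaError("target_choice must have one entry per trial")
        if self.target_choice.min() < 0 or self.target_choice.max() >= proto.n_choices:
            raise SchemaError("target_choice out of range")
        counts = np.apply_along_axis(
            np.bincount, 1, self.flashed_label, minlength=proto.n_choices
        )
        if not (counts == proto.flashes_per_choice).all():
            raise SchemaError(
                "each choice must be flashed exactly flashes_per_choice "
                "times per trial"
            )
        expected = n_window_samples(self.window_ms, proto.sample_rate)
        if n_sa != expected:
            raise SchemaError(
                f"sample axis ({n_sa}) inconsistent with window "
                f"{self.window_ms} at {proto.sample_rate} Hz ({expected})"
            )

    # ---- convenience ----------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[2]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[3]

    def is_target(self) -> np.ndarray:
        """Boolean (trials, flash_events): flash matched the attended choice."""
        return self.flashed_label == self.target_choice[:, None]

    def times_ms(self) -> np.ndarray:
        start = self.window_ms[0]
        return start + np.arange(self.n_samples) * 1000.0 / self.protocol.sample_rate

    def take_trials(self, idx: np.ndarray | list[int]) -> "EpochSet":
        idx = np.asarray(idx, dtype=np.int64)
        return replace(
            self,
            epochs=self.epochs[idx],
            flashed_label=self.flashed_label[idx],
            target_choice=self.target_choice[idx],
        )


@dataclass
class ErpAverage:
    """Per-channel mean target and non-target waveforms on a common window."""

    channels: tuple[str, ...]
    times_ms: np.ndarray
    target: np.ndarray  # (channels, samples)
    nontarget: np.ndarray  # (channels, samples)
    n_target: int
    n_nontarget: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ch in enumerate(self.channels):
            rows.append(
                pd.DataFrame(
                    {
                        "channel": ch,
                        "time_ms": self.times_ms,
                        "target": self.target[i],
                        "nontarget": self.nontarget[i],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


# ---- referencing and subsetting ----------------------------------------


def apply_car(es: EpochSet) -> EpochSet:
    """Common average reference: subtract the across-channel mean per sample.

    Meant to be applied to the full recorded montage before any channel
    subsetting.  Idempotent; the post-CAR per-sample channel mean is 0.
    """
    if es.n_channels < 2:
        raise SchemaError("CAR needs at least 2 channels")
    ref = es.epochs.mean(axis=2, keepdims=True)
    out = (es.epochs - ref).astype(es.epochs.dtype)
    return replace(es, epochs=out)


def select_channels(es: EpochSet, subset: list[str] | tuple[str, ...]) -> EpochSet:
    """Restrict (and reorder) the channel axis to ``subset`` order."""
    subset = tuple(subset)
    if len(set(subset)) != len(subset):
        raise SchemaError("channel subset contains duplicates")
    try:
        idx = [es.channels.index(name) for name in subset]
    except ValueError as e:
        raise SchemaError(f"unknown channel in subset: {e}") from None
    return replace(es, epochs=es.epochs[:, :, idx, :], channels=subset)


# ---- ERP averaging ------------------------------------------------------


def detrend_and_center(x: np.ndarray) -> np.ndarray:
    """Remove the least-squares straight line (incl. mean) along the last axis."""
    if x.shape[-1] < 2:
        raise SchemaError("detrending needs at least 2 samples")
    return _scipy_detrend(np.asarray(x, dtype=np.float64), axis=-1, type="linear")


def average_erp(
    es: EpochSet, window_ms: tuple[float, float] = (0.0, 1000.0)
) -> ErpAverage:
    """Target / non-target grand averages after per-epoch linear detrending.

    Each epoch is cropped to ``window_ms``, linearly detrended and
    mean-centered per channel, then averaged separately over target and
    non-target flashes.
    """
    fs = es.protocol.sample_rate
    if window_ms[0] < es.window_ms[0] or window_ms[1] > es.window_ms[1]:
        raise SchemaError("requested ERP window not covered by the epochs")
    offset = int(round((window_ms[0] - es.window_ms[0]) * fs / 1000.0))
    n = n_window_samples(window_ms, fs)
    x = detrend_and_center(es.epochs[..., offset : offset + n])
    tgt = es.is_target()
    n_t = int(tgt.sum())
    n_nt = int((~tgt).sum())
    target = x[tgt].mean(axis=0)
    nontarget = x[~tgt].mean(axis=0)
    times = window_ms[0] + np.arange(n) * 1000.0 / fs
    return ErpAverage(
        channels=es.channels,
        times_ms=times,
        target=target,
        nontarget=nontarget,
        n_target=n_t,
        n_nontarget=n_nt,
    )


# ---- bundle I/O ---------------------------------------------------------

_H5_NAME = "epochs.h5"
_CSV_NAME = "epochs.csv"
_META_NAME = "metadata.json"


def save_session_bundle(
    es: EpochSet, path: str | Path, payload: str = "h5"
) -> Path:
    """Write a session bundle directory (``payload``: ``"h5"`` or ``"csv"``).

    The numeric payload is stored as float32 and round-trips bit-exactly.
    """
    es.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": "p300select-session-bundle",
        "version": 1,
        "montage": es.montage.to_dict(),
        "channels": list(es.channels),
        "protocol": es.protocol.to_dict(),
        "window_ms": list(es.window_ms),
        "target_choice": es.target_choice.tolist(),
        "flashed_label": es.flashed_label.tolist(),
        "payload": payload,
        "provenance": es.provenance,
    }
    (path / _META_NAME).write_text(json.dumps(meta, indent=1))
    data = np.ascontiguousarray(es.epochs, dtype=np.float32)
    if payload == "h5":
        import h5py

        with h5py.File(path / _H5_NAME, "w") as f:
            f.create_dataset("epochs", data=data)
    elif payload == "csv":
        n_tr, n_fl, n_ch, n_sa = data.shape
        idx = np.indices(data.shape).reshape(4, -1)
        df = pd.DataFrame(
            {
                "trial": idx[0],
                "flash_event": idx[1],
                "channel": idx[2],
                "sample": idx[3],
                "value": data.ravel(),
            }
        )
        df.to_csv(path / _CSV_NAME, index=False)
    else:
        raise SchemaError(f"unknown payload format {payload!r}")
    return path


def load_session_bundle(path: str | Path) -> EpochSet:
    """Load a session bundle, validating every container invariant."""
    path = Path(path)
    meta_path = path / _META_NAME
    if not meta_path.exists():
        raise SchemaError(f"no {_META_NAME} in {path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"corrupt metadata.json: {e}") from None
    montage = Montage.from_dict(meta["montage"])
    protocol = ProtocolSpec.from_dict(meta["protocol"])
    if (path / _H5_NAME).exists():
        import h5py

        with h5py.File(path / _H5_NAME, "r") as f:
            epochs = f["epochs"][...]
    elif (path / _CSV_NAME).exists():
        df = pd.read_csv(path / _CSV_NAME)
        shape = tuple(int(df[c].max()) + 1 for c in ("trial", "flash_event", "channel", "sample"))
        if len(df) != int(np.prod(shape)):
            raise SchemaError("CSV payload does not cover a full dense array")
        epochs = np.zeros(shape, dtype=np.float32)
        epochs[
            df["trial"].to_numpy(),
            df["flash_event"].to_numpy(),
            df["channel"].to_numpy(),
            df["sample"].to_numpy(),
        ] = df["value"].to_numpy(dtype=np.float32)
    else:
        raise SchemaError(f"bundle {path} has neither {_H5_NAME} nor {_CSV_NAME}")
    return EpochSet(
        montage=montage,
        protocol=protocol,
        epochs=epochs,
        flashed_label=np.asarray(meta["flashed_label"]),
        target_choice=np.asarray(meta["target_choice"]),
        window_ms=tuple(meta["window_ms"]),
        channels=tuple(meta["channels"]),
        provenance=meta.get("provenance", {}),
    )
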