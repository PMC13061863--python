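"""Electrode montage: names, schematic scalp positions, and standard subsets.

The default cap is a 32-location 10-10-style wet-electrode montage.  Positions
are schematic 2-D grid coordinates (left negative x, anterior positive y),
unitless; they are used only for simulated topographies and plotting layout,
never for any biophysical computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import SchemaError

# Schematic 10-10 grid: x = signed lateral index (odd labels left, even
# right, z on the midline), y = anterior-posterior row (F=2 ... O=-4).
_COORDS: dict[str, tuple[float, float]] = {
    "F3": (-2, 2), "Fz": (0, 2), "F4": (2, 2),
    "FC5": (-3, 1), "FC3": (-2, 1), "FC1": (-1, 1), "FCz": (0, 1),
    "FC2": (1, 1), "FC4": (2, 1), "FC6": (3, 1),
    "T7": (-4, 0), "C5": (-3, 0), "C3": (-2, 0), "C1": (-1, 0),
    "Cz": (0, 0), "C2": (1, 0), "C4": (2, 0), "C6": (3, 0), "T8": (4, 0),
    "CP5": (-3, -1), "CP3": (-2, -1), "CP1": (-1, -1), "CPz": (0, -1),
    "CP2": (1, -1), "CP4": (2, -1), "CP6": (3, -1),
    "P3": (-2, -2), "Pz": (0, -2), "P4": (2, -2),
    "PO7": (-3, -3), "PO8": (3, -3),
    "Oz": (0, -4),
}

#: Cap order of the 32 recorded locations.
CAP32: tuple[str, ...] = tuple(_COORDS)

#: The 16 electrodes used for in-session calibration by laboratory systems.
DEFAULT16: tuple[str, ...] = (
    "F3", "Fz", "F4", "T7", "C3", "Cz", "C4", "T8",
    "CP3", "CP4", "P3", "Pz", "P4", "PO7", "PO8", "Oz",
)

#: The canonical home-use 8-electrode set (overridable via Montage()).
DEFAULT8: tuple[str, ...] = ("Fz", "Cz", "P3", "Pz", "P4", "PO7", "PO8", "Oz")


@dataclass(frozen=True)
class Montage:
    """An ordered electrode layout with its standard default subsets.

    Invariants: names unique, ``default8 ⊆ default16 ⊆ names``, and one
    2-D position per name.
    """

    names: tuple[str, ...] = CAP32
    positions: tuple[tuple[float, float], ...] = field(
        default_factory=lambda: tuple(_COORDS[n] for n in CAP32)
    )
    default16: tuple[str, ...] = DEFAULT16
    default8: tuple[str, ...] = DEFAULT8

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise SchemaError("montage names must be unique")
        if len(self.positions) != len(self.names):
            raise SchemaError("montage needs one position per electrode name")
        if not set(self.default16) <= set(self.names):
            raise SchemaError("default16 must be a subset of montage names")
        if not set(self.default8) <= set(self.default16):
            raise SchemaError("default8 must be a subset of default16")

    @property
    def size(self) -> int:
        """Cap size S (32 for the standard cap)."""
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise SchemaError(f"electrode {name!r} not in montage") from None

    def position(self, name: str) -> np.ndarray:
        return np.asarray(self.positions[self.index(name)], dtype=float)

    def position_array(self, names: tuple[str, ...] | None = None) -> np.ndarray:
        names = self.names if names is None else names
        return np.array([self.positions[self.index(n)] for n in names], float)

    # ---- JSON I/O -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "names": list(self.names),
            "positions": [list(p) for p in self.positions],
            "default16": list(self.default16),
            "default8": list(self.default8),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Montage":
        return cls(
            names=tuple(d["names"]),
            positions=tuple(tuple(p) for p in d["positions"]),
            default16=tuple(d["default16"]),
            default8=tuple(d["default8"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Montage":
        return cls.from_dict(json.loads(Path(path).read_text()))


#: Ready-made standard montage instance.
STANDARD_MONTAGE = Montage()
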