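"""Tank, electrode and virtual-fish geometry.

All coordinates are 2-D and in centimetres: ``x`` runs along the short tank
side (width, default 66 cm), ``y`` along the long side (default 72 cm), with
the origin in one tank corner.  Electrodes sit on (or inside) the tank walls
in the horizontal recording plane; the water is shallow enough that the field
model is purely two-dimensional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import math
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "TankGeometry",
    "ElectrodeConfiguration",
    "VirtualFish",
    "GeometryError",
    "standard_setup",
    "STANDARD_CONFIG_IDS",
]


class GeometryError(ValueError):
    """Raised for invalid tank/electrode/fish geometry."""


@dataclass
class TankGeometry:
    """Rectangular experimental tank with wall-mounted electrodes.

    Parameters
    ----------
    width : float
        Tank extent along x, cm.
    depth_y : float
        Tank extent along y, cm.
    wall_margin : float
        Minimum distance (cm) every part of a simulated fish must keep from
        all four walls; limits boundary artefacts of the wall-free dipole
        model.
    electrode_positions : list of (x, y)
        Electrode tip positions, cm.
    """

    width: float = 66.0
    depth_y: float = 72.0
    wall_margin: float = 10.0
    electrode_positions: list = field(default_factory=list)

    def __post_init__(self):
        if self.width <= 0 or self.depth_y <= 0:
            raise GeometryError("tank dimensions must be positive")
        if not (0 <= self.wall_margin < min(self.width, self.depth_y) / 2):
            raise GeometryError(
                f"wall_margin {self.wall_margin} must lie in "
                f"[0, {min(self.width, self.depth_y) / 2})"
            )
        self.electrode_positions = [
            (float(x), float(y)) for x, y in self.electrode_positions
        ]
        eps = 1e-9
        for x, y in self.electrode_positions:
            if not (-eps <= x <= self.width + eps and -eps <= y <= self.depth_y + eps):
                raise GeometryError(f"electrode ({x}, {y}) outside the tank")

    @property
    def center(self) -> tuple:
        return (self.width / 2.0, self.depth_y / 2.0)

    def contains(self, point, margin: float = 0.0) -> bool:
        x, y = point
        return (
            margin <= x <= self.width - margin
            and margin <= y <= self.depth_y - margin
        )

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "depth_y": self.depth_y,
            "wall_margin": self.wall_margin,
            "electrode_positions": [list(p) for p in self.electrode_positions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TankGeometry":
        return cls(
            width=d.get("width", 66.0),
            depth_y=d.get("depth_y", 72.0),
            wall_margin=d.get("wall_margin", 10.0),
            electrode_positions=d.get("electrode_positions", []),
        )

    @classmethod
    def from_file(cls, path) -> "TankGeometry":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


@dataclass
class ElectrodeConfiguration:
    """Wiring of tank electrodes into recording channels.

    ``differential`` channels are (positive electrode index, negative
    electrode index) pairs; ``single_ended`` channels are electrode indices
    measured against a single reference point (tank centre by default).
    """

    config_id: int
    mode: str  # "differential" | "single_ended"
    channels: list
    reference: tuple | None = None

    def __post_init__(self):
        if self.mode not in ("differential", "single_ended"):
            raise GeometryError(f"unknown mode {self.mode!r}")
        if self.mode == "differential":
            for pos, neg in self.channels:
                if pos == neg:
                    raise GeometryError("channel pairs an electrode with itself")
            if self.reference is not None:
                raise GeometryError("differential mode takes no reference point")
        else:
            if self.reference is None:
                raise GeometryError("single_ended mode requires a reference point")
            self.channels = [int(c) for c in self.channels]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def to_dict(self) -> dict:
        return {
            "config_id": self.config_id,
            "mode": self.mode,
            "channels": [list(c) if self.mode == "differential" else c
                         for c in self.channels],
            "reference": list(self.reference) if self.reference else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElectrodeConfiguration":
        channels = d["channels"]
        if d["mode"] == "differential":
            channels = [tuple(c) for c in channels]
        ref = d.get("reference")
        return cls(
            config_id=d["config_id"],
            mode=d["mode"],
            channels=channels,
            reference=tuple(ref) if ref else None,
        )

    @classmethod
    def from_file(cls, path) -> "ElectrodeConfiguration":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


@dataclass
class VirtualFish:
    """A dipole fish mimic: point charges of opposite sign at head and tail.

    ``charge_scale`` is the product k*q of the dipole-potential formula; the
    default 1 corresponds to setting the charge to the reciprocal of the
    proportionality constant, which keeps all simulated electrode voltages
    within roughly +/-1 V for the default tank.
    """

    length: float
    center: tuple
    sin_theta: float
    cos_theta: float
    charge_scale: float = 1.0

    def __post_init__(self):
        if abs(self.sin_theta**2 + self.cos_theta**2 - 1.0) > 1e-9:
            raise GeometryError("(sin, cos) heading must be unit-normalised")
        if self.length <= 0:
            raise GeometryError("fish length must be positive")

    @classmethod
    def from_angle(cls, length, center, theta, charge_scale=1.0) -> "VirtualFish":
        return cls(length, tuple(center), math.sin(theta), math.cos(theta),
                   charge_scale)

    @property
    def head_pos(self) -> np.ndarray:
        c = np.asarray(self.center, dtype=float)
        return c + 0.5 * self.length * np.array([self.cos_theta, self.sin_theta])

    @property
    def tail_pos(self) -> np.ndarray:
        c = np.asarray(self.center, dtype=float)
        return c - 0.5 * self.length * np.array([self.cos_theta, self.sin_theta])


def _perimeter_frames(tank: TankGeometry, n: int, offset: float = 0.0) -> list:
    """(point, wall tangent, inward normal) for n evenly spaced wall points."""
    w, d = tank.width, tank.depth_y
    per = 2 * (w + d)
    out = []
    for i in range(n):
        s = (offset + i * per / n) % per
        if s < w:
            out.append(((s, 0.0), (1.0, 0.0), (0.0, 1.0)))
        elif s < w + d:
            out.append(((w, s - w), (0.0, 1.0), (-1.0, 0.0)))
        elif s < 2 * w + d:
            out.append(((2 * w + d - s, d), (-1.0, 0.0), (0.0, -1.0)))
        else:
            out.append(((0.0, per - s), (0.0, -1.0), (1.0, 0.0)))
    return out


def _perimeter_points(tank: TankGeometry, n: int, offset: float = 0.0) -> list:
    """n points evenly spaced (by arc length) around the tank perimeter."""
    return [p for p, _, _ in _perimeter_frames(tank, n, offset)]


def _short_pairs(tank: TankGeometry, orientation: str,
                 baseline: float = 10.0) -> tuple:
    """Seven short-baseline differential pairs evenly around the perimeter.

    Each pair sits on one rod position; its axis is the local wall tangent,
    the inward normal, or alternates between the two.
    """
    w, d = tank.width, tank.depth_y
    electrodes, channels = [], []
    for i, (c, t, nv) in enumerate(
            _perimeter_frames(tank, 7, offset=(w + d) / 7)):
        c, t, nv = np.asarray(c), np.asarray(t), np.asarray(nv)
        if orientation == "tangential" or (orientation == "mixed"
                                           and i % 2 == 0):
            axis = t
        else:
            axis = nv
        e1 = np.clip(c + 0.5 * baseline * axis, [0, 0], [w, d])
        e2 = np.clip(c - 0.5 * baseline * axis, [0, 0], [w, d])
        electrodes += [tuple(e1), tuple(e2)]
        channels.append((2 * i, 2 * i + 1))
    return electrodes, channels


STANDARD_CONFIG_IDS = (1, 2, 3, 4, 5, 6)


def standard_setup(config_id: int, tank: TankGeometry | None = None):
    """Return ``(tank, config)`` for one of the six benchmark electrode layouts.

    The layouts span the design space compared in the electrode-placement
    study: short-baseline wall-rod pairs around the whole perimeter with
    alternating (1) or uniform (4) pair axes, diametrically opposite pairs
    whose differential axis rotates from one pair to the next (2), perimeter
    electrodes recorded single-ended against a tank-centre ground (3),
    pairs clustered on the two short walls (5), and a perpendicular net of
    tank-spanning pairs plus two corner-to-corner diagonals (6).
    """
    if tank is None:
        tank = TankGeometry()
    w, d = tank.width, tank.depth_y

    if config_id == 1:
        # 7 short-baseline pairs around the perimeter, axes alternating
        # between wall-tangential and inward-normal
        electrodes, channels = _short_pairs(tank, "mixed")
        mode, ref = "differential", None
    elif config_id == 2:
        # 14 perimeter electrodes paired diametrically: the differential
        # axis rotates from one pair to the next and every axis crosses the
        # middle of the tank (no central reference)
        electrodes = _perimeter_points(tank, 14, offset=(w + d) / 14)
        channels = [(i, i + 7) for i in range(7)]
        mode, ref = "differential", None
    elif config_id == 3:
        # perimeter electrodes recorded single-ended against a ground
        # electrode in the middle of the tank
        electrodes = _perimeter_points(tank, 7, offset=(w + d) / 7)
        channels = list(range(7))
        mode, ref = "single_ended", tank.center
    elif config_id == 4:
        # like 1 but with all pair axes wall-tangential
        electrodes, channels = _short_pairs(tank, "tangential")
        mode, ref = "differential", None
    elif config_id == 5:
        # pairs clustered on the two short walls; long walls uncovered
        b = 10.0  # baseline, cm
        xs = [w / 6, w / 3, w / 2, 2 * w / 3]
        electrodes = []
        for x in xs[:4]:
            electrodes += [(max(x - b / 2, 0.0), 0.0), (x + b / 2, 0.0)]
        for x in xs[:3]:
            electrodes += [(max(x - b / 2, 0.0), d), (x + b / 2, d)]
        channels = [(0, 1), (2, 3), (4, 5), (6, 7), (8, 9), (10, 11), (12, 13)]
        mode, ref = "differential", None
    elif config_id == 6:
        # five pairs forming a perpendicular net + two corner diagonals
        electrodes = [
            (0.0, d / 4), (w, d / 4),
            (0.0, 3 * d / 4), (w, 3 * d / 4),
            (w / 4, 0.0), (w / 4, d),
            (w / 2, 0.0), (w / 2, d),
            (3 * w / 4, 0.0), (3 * w / 4, d),
            (0.0, 0.0), (w, d),
            (w, 0.0), (0.0, d),
        ]
        channels = [(0, 1), (2, 3), (4, 5), (6, 7), (8, 9), (10, 11), (12, 13)]
        mode, ref = "differential", None
    else:
        raise GeometryError(f"unknown configuration id {config_id}")

    tank = TankGeometry(tank.width, tank.depth_y, tank.wall_margin, electrodes)
    config = ElectrodeConfiguration(config_id=config_id, mode=mode,
                                    channels=channels, reference=ref)
    return tank, config
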