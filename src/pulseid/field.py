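"""Dipole field model for virtual fish and simulated electrode recordings.

The electric field of a fish mimic is a simple two-point dipole: charges of
equal magnitude and opposite polarity at the head and the tail.  The potential
at a point is

    V = kq * (1/R1 - 1/R2)

with R1, R2 the distances (cm) of the point to the head and tail pole and kq
a single proportionality constant (default 1, i.e. the charge is set to the
reciprocal of the constant so only relative amplitudes matter).  With kq = 1
and a 10 cm wall margin, every simulated channel stays within +/-1 V.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    ElectrodeConfiguration,
    GeometryError,
    TankGeometry,
    VirtualFish,
)

__all__ = [
    "dipole_potential",
    "record_channels",
    "sample_placements",
    "LabeledFieldDataset",
    "TARGET_NAMES",
]

TARGET_NAMES = ("x", "y", "sin", "cos", "length")

_MIN_POLE_DISTANCE = 1e-9


def dipole_potential(fish: VirtualFish, point) -> float:
    """Potential (V) of a dipole fish at a 2-D point (cm).

    Raises :class:`GeometryError` if the point coincides with either pole.
    """
    point = np.asarray(point, dtype=float)
    r1 = np.linalg.norm(point - fish.head_pos)
    r2 = np.linalg.norm(point - fish.tail_pos)
    if r1 < _MIN_POLE_DISTANCE or r2 < _MIN_POLE_DISTANCE:
        raise GeometryError("evaluation point coincides with a dipole pole")
    return fish.charge_scale * (1.0 / r1 - 1.0 / r2)


def _potentials_at(fish: VirtualFish, points: np.ndarray) -> np.ndarray:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    r1 = np.linalg.norm(points - fish.head_pos, axis=1)
    r2 = np.linalg.norm(points - fish.tail_pos, axis=1)
    if np.any(r1 < _MIN_POLE_DISTANCE) or np.any(r2 < _MIN_POLE_DISTANCE):
        raise GeometryError("evaluation point coincides with a dipole pole")
    return fish.charge_scale * (1.0 / r1 - 1.0 / r2)


def record_channels(
    fish: VirtualFish, tank: TankGeometry, config: ElectrodeConfiguration
) -> np.ndarray:
    """Simulated channel potentials (V) for one fish placement.

    Differential channels are potential differences of electrode pairs;
    single-ended channels are measured against the reference point.
    """
    for pole in (fish.head_pos, fish.tail_pos):
        if not tank.contains(pole):
            raise GeometryError(f"fish pole {tuple(pole)} outside the tank")
    electrodes = np.asarray(tank.electrode_positions, dtype=float)
    if electrodes.size == 0:
        raise GeometryError("tank has no electrodes")
    v = _potentials_at(fish, electrodes)
    if config.mode == "differential":
        out = np.array([v[p] - v[n] for p, n in config.channels])
    else:
        v_ref = dipole_potential(fish, config.reference)
        out = np.array([v[c] - v_ref for c in config.channels])
    if not np.all(np.isfinite(out)):
        raise GeometryError("non-finite channel potential")
    return out


@dataclass
class LabeledFieldDataset:
    """Simulated channel potentials with ground-truth placement targets.

    ``features`` is (n, n_channels) in volts; ``targets`` is (n, 5) with
    columns (x cm, y cm, sin heading, cos heading, length cm).
    """

    features: np.ndarray
    targets: np.ndarray
    seed: int

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.targets = np.asarray(self.targets, dtype=float)
        if self.features.shape[0] != self.targets.shape[0]:
            raise ValueError("feature/target row counts differ")
        if not (np.all(np.isfinite(self.features))
                and np.all(np.isfinite(self.targets))):
            raise ValueError("dataset contains non-finite entries")

    def __len__(self) -> int:
        return self.features.shape[0]

    def to_csv(self, path, tank: TankGeometry | None = None,
               config: ElectrodeConfiguration | None = None) -> None:
        """Write features+targets as CSV with a JSON sidecar for provenance."""
        path = Path(path)
        n_ch = self.features.shape[1]
        cols = [f"ch{i + 1}" for i in range(n_ch)] + list(TARGET_NAMES)
        df = pd.DataFrame(np.hstack([self.features, self.targets]), columns=cols)
        df.to_csv(path, index=False)
        sidecar = {"seed": self.seed, "n": len(self)}
        if tank is not None:
            sidecar["tank"] = tank.to_dict()
        if config is not None:
            sidecar["config"] = config.to_dict()
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path) -> "LabeledFieldDataset":
        path = Path(path)
        df = pd.read_csv(path)
        tcols = list(TARGET_NAMES)
        fcols = [c for c in df.columns if c not in tcols]
        sidecar_path = path.with_suffix(path.suffix + ".json")
        seed = -1
        if sidecar_path.exists():
            seed = json.loads(sidecar_path.read_text()).get("seed", -1)
        return cls(df[fcols].to_numpy(), df[tcols].to_numpy(), seed)


def sample_fish(
    n: int,
    tank: TankGeometry,
    n_fish: int = 20,
    length_range: tuple = (8.0, 15.0),
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> list:
    """Draw ``n`` random fish placements respecting the whole-fish wall margin.

    Lengths are drawn uniformly among ``n_fish`` fixed values spanning
    ``length_range``; orientation is uniform on [0, 2pi); both dipole poles
    keep at least ``tank.wall_margin`` from every wall.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    lengths = np.linspace(length_range[0], length_range[1], n_fish)
    margin = tank.wall_margin
    max_len = lengths.max()
    if (tank.width - 2 * margin <= 0 or tank.depth_y - 2 * margin <= 0
            or tank.width - 2 * margin < 1e-9 or max_len / 2 > (
                max(tank.width, tank.depth_y) / 2 - margin)):
        raise GeometryError("wall margin leaves no room for fish placement")
    fish = []
    attempts = 0
    max_attempts = 1000 * n
    while len(fish) < n:
        if attempts > max_attempts:
            raise GeometryError("could not place fish within the wall margin")
        attempts += 1
        length = float(rng.choice(lengths))
        cx = rng.uniform(margin, tank.width - margin)
        cy = rng.uniform(margin, tank.depth_y - margin)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        cand = VirtualFish.from_angle(length, (cx, cy), theta)
        if tank.contains(cand.head_pos, margin) and tank.contains(
                cand.tail_pos, margin):
            fish.append(cand)
    return fish


def sample_placements(
    n: int,
    tank: TankGeometry,
    config: ElectrodeConfiguration,
    n_fish: int = 20,
    length_range: tuple = (8.0, 15.0),
    seed: int = 0,
    fish: list | None = None,
) -> LabeledFieldDataset:
    """Simulate ``n`` random placements and their channel potentials.

    Identical seeds give bit-identical datasets.  A precomputed ``fish`` list
    (e.g. shared across electrode configurations) overrides the sampling.
    """
    if fish is None:
        fish = sample_fish(n, tank, n_fish, length_range, seed)
    features = np.empty((len(fish), config.n_channels))
    targets = np.empty((len(fish), 5))
    for i, f in enumerate(fish):
        features[i] = record_channels(f, tank, config)
        targets[i] = (f.center[0], f.center[1], f.sin_theta, f.cos_theta,
                      f.length)
    return LabeledFieldDataset(features, targets, seed)
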