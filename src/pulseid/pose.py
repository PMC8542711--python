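"""Skeleton-tracking import, pixel->cm conversion, and video/recording sync.

Tracking files follow the analysis HDF5 layout of common multi-animal pose
estimators: a ``tracks`` array of shape (n_tracks, 2, n_nodes, n_frames)
holding x/y per node per frame (NaN where undetected), a ``node_names`` list
and a ``track_occupancy`` array.  The canonical fish skeleton has six
midline nodes from snout to tail; "head2" (midpoint between the pectoral
fins) is the anchor used to localize an animal.

Video frames are synchronized to the electrode recording through the TTL
channel: one logic pulse per camera exposure, recorded alongside the voltage
channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import h5py
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "NODE_NAMES",
    "ANCHOR_INDEX",
    "SkeletonPose",
    "TrackedSequence",
    "FrameClock",
    "load_tracking",
    "write_tracking",
    "sync_frames",
    "pose_at_time",
    "SchemaError",
    "SyncError",
]

NODE_NAMES = ("Schnauzenorgan", "head1", "head2", "mid1", "mid2", "tail")
ANCHOR_INDEX = 2  # head2


class SchemaError(ValueError):
    """Tracking file does not follow the documented layout."""


class SyncError(RuntimeError):
    """TTL pulse count does not match the video frame count."""


@dataclass
class SkeletonPose:
    """Six-node fish midline (cm) with per-node visibility."""

    nodes: np.ndarray  # (6, 2) cm; NaN allowed where invisible
    visibility: np.ndarray | None = None

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.shape != (6, 2):
            raise ValueError(f"expected (6, 2) nodes, got {self.nodes.shape}")
        if self.visibility is None:
            self.visibility = np.all(np.isfinite(self.nodes), axis=1)
        self.visibility = np.asarray(self.visibility, dtype=bool)
        if self.visibility.shape != (6,):
            raise ValueError("visibility must have 6 entries")

    @property
    def anchor(self) -> np.ndarray:
        return self.nodes[ANCHOR_INDEX]

    @property
    def anchor_visible(self) -> bool:
        return bool(self.visibility[ANCHOR_INDEX])

    def flat(self) -> np.ndarray:
        """Nodes flattened to (12,) in (x0, y0, x1, y1, ...) order."""
        return self.nodes.ravel()

    @classmethod
    def from_flat(cls, values) -> "SkeletonPose":
        return cls(np.asarray(values, dtype=float).reshape(6, 2))


@dataclass
class TrackedSequence:
    """Per-frame, per-animal skeletons time-aligned to the recording clock."""

    poses: np.ndarray          # (n_frames, n_animals, 6, 2) cm, NaN = invisible
    frame_rate: float = 30.0
    px_to_cm: float = 1.0
    frame_times: np.ndarray | None = None  # s, strictly increasing

    def __post_init__(self):
        self.poses = np.asarray(self.poses, dtype=float)
        if self.poses.ndim != 4 or self.poses.shape[2:] != (6, 2):
            raise ValueError("poses must be (n_frames, n_animals, 6, 2)")
        if self.poses.shape[1] > 2:
            raise ValueError("at most 2 animals are supported")
        if self.frame_times is None:
            self.frame_times = np.arange(self.n_frames) / self.frame_rate
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.shape != (self.n_frames,):
            raise ValueError("one frame time per frame required")
        if self.n_frames > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.poses.shape[0]

    @property
    def n_animals(self) -> int:
        return self.poses.shape[1]

    def pose(self, frame: int, animal: int) -> SkeletonPose:
        return SkeletonPose(self.poses[frame, animal])

    def check_continuity(self, max_jump_cm: float = 15.0) -> list:
        """Warn about per-frame anchor jumps suggesting identity swaps."""
        warnings = []
        anchors = self.poses[:, :, ANCHOR_INDEX, :]
        jumps = np.linalg.norm(np.diff(anchors, axis=0), axis=2)
        for f, a in zip(*np.nonzero(jumps > max_jump_cm)):
            warnings.append((int(f) + 1, int(a), float(jumps[f, a])))
            logger.warning(
                "anchor of animal %d jumps %.1f cm into frame %d",
                a, jumps[f, a], f + 1)
        return warnings


@dataclass
class FrameClock:
    """Exposure times (s, recording clock) recovered from the TTL channel."""

    ttl_times: np.ndarray
    offset: float = 0.0

    def __post_init__(self):
        self.ttl_times = np.asarray(self.ttl_times, dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.ttl_times)

    def frame_times(self) -> np.ndarray:
        return self.ttl_times + self.offset


def load_tracking(path, px_to_cm: float = 1.0,
                  frame_rate: float = 30.0,
                  frame_times=None) -> TrackedSequence:
    """Load a multi-animal tracking HDF5 export.

    Missing detections (NaN coordinates) become invisible nodes; node order
    is remapped to the canonical six-name order regardless of file order.
    """
    with h5py.File(path, "r") as f:
        if "tracks" not in f or "node_names" not in f:
            raise SchemaError("tracking file lacks 'tracks'/'node_names'")
        tracks = np.asarray(f["tracks"])  # (n_tracks, 2, n_nodes, n_frames)
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in f["node_names"][()]]
    if tracks.ndim != 4 or tracks.shape[1] != 2:
        raise SchemaError(f"unexpected tracks shape {tracks.shape}")
    n_tracks = tracks.shape[0]
    if n_tracks > 2:
        raise SchemaError(f"{n_tracks} animals found; at most 2 supported")
    missing = set(NODE_NAMES) - set(names)
    if missing:
        raise SchemaError(f"missing skeleton nodes: {sorted(missing)}")
    order = [names.index(n) for n in NODE_NAMES]
    # -> (n_frames, n_animals, 6, 2)
    poses = tracks[:, :, order, :].transpose(3, 0, 2, 1) * px_to_cm
    return TrackedSequence(poses, frame_rate=frame_rate, px_to_cm=px_to_cm,
                           frame_times=frame_times)


def write_tracking(path, seq: TrackedSequence, node_order=NODE_NAMES) -> None:
    """Write a TrackedSequence in the analysis HDF5 layout (fixture writer)."""
    order = [NODE_NAMES.index(n) for n in node_order]
    tracks = (seq.poses / seq.px_to_cm)[:, :, order, :].transpose(1, 3, 2, 0)
    occupancy = np.all(np.isfinite(seq.poses[:, :, ANCHOR_INDEX, :]),
                       axis=2).astype(np.int8)
    with h5py.File(path, "w") as f:
        f.create_dataset("tracks", data=tracks)
        f.create_dataset("node_names",
                         data=np.array([n.encode() for n in node_order]))
        f.create_dataset("track_names",
                         data=np.array([f"fish{i}".encode()
                                        for i in range(seq.n_animals)]))
        f.create_dataset("track_occupancy", data=occupancy)


def sync_frames(ttl: np.ndarray, sampling_rate: float, n_video_frames: int,
                threshold: float | None = None) -> FrameClock:
    """Detect TTL rising edges and check the count against the video.

    Returns a :class:`FrameClock` with one time (s) per exposure; raises
    :class:`SyncError` (reporting both counts) on mismatch.
    """
    ttl = np.asarray(ttl, dtype=float).ravel()
    if threshold is None:
        threshold = 0.5 * ttl.max()
    if threshold <= 0:
        raise SyncError("TTL channel contains no pulses")
    high = ttl > threshold
    edges = np.flatnonzero(high[1:] & ~high[:-1]) + 1
    if high[0]:
        edges = np.concatenate([[0], edges])
    if len(edges) != n_video_frames:
        raise SyncError(
            f"TTL pulse count {len(edges)} != video frame count "
            f"{n_video_frames}")
    return FrameClock(edges / sampling_rate)


def _interp_animal(seq: TrackedSequence, t: float, animal: int,
                   i0: int, i1: int, w: float) -> SkeletonPose:
    p0 = seq.poses[i0, animal]
    p1 = seq.poses[i1, animal]
    v0 = np.all(np.isfinite(p0), axis=1)
    v1 = np.all(np.isfinite(p1), axis=1)
    nodes = np.full((6, 2), np.nan)
    both = v0 & v1
    nodes[both] = (1 - w) * p0[both] + w * p1[both]
    only0 = v0 & ~v1
    nodes[only0] = p0[only0]
    only1 = v1 & ~v0
    nodes[only1] = p1[only1]
    return SkeletonPose(nodes)


def pose_at_time(seq: TrackedSequence, t: float) -> list:
    """Per-animal skeletons at time ``t`` by nodewise linear interpolation.

    Nodes invisible on either flanking frame fall back to the nearest frame
    where they are visible (of the two); raises ``ValueError`` outside the
    tracked time range.
    """
    times = seq.frame_times
    if t < times[0] or t > times[-1]:
        raise ValueError(f"t = {t} s outside tracked range "
                         f"[{times[0]}, {times[-1]}]")
    i1 = int(np.searchsorted(times, t, side="left"))
    if times[i1] == t:
        i0, w = i1, 0.0
    else:
        i0 = i1 - 1
        w = (t - times[i0]) / (times[i1] - times[i0])
    return [_interp_animal(seq, t, a, i0, i1, w)
            for a in range(seq.n_animals)]
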