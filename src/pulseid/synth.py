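"""Ground-truthed synthetic fixtures for every pipeline stage.

Emulates the acquisition chain end to end with no external data: smooth
two-fish trajectories in the experimental tank, biphasic EOD pulses fired by
a gamma renewal process, channel potentials from the dipole field model plus
Gaussian noise, a TTL frame-sync channel, tracking files in the analysis
HDF5 layout, and meshed two-fish scenes for the electric-image solver.
Every generator is deterministic given its seed and emits ground-truth
tables alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bem import ConductivityScene, SceneBody, eod_sources
from .eod import MultichannelRecording
from .field import record_channels
from .geometry import TankGeometry, VirtualFish
from .mesh import build_mesh, default_profile, fit_midline
from .pose import SkeletonPose, TrackedSequence

__all__ = [
    "FishSpec",
    "SyntheticScenario",
    "make_biphasic_pulse",
    "make_trajectories",
    "make_recording",
    "make_dyad_scene",
]


@dataclass
class FishSpec:
    """Per-fish parameters of a synthetic scenario."""

    fish_id: int
    length_cm: float = 12.0
    amplitude_scale: float = 1.0
    mean_ipi_s: float = 0.05          # mean inter-pulse interval
    pulse_width_factor: float = 1.0   # individual second-phase width (+/-10%)


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic session.

    Defaults mirror the experimental conditions: a 66 x 72 cm tank with a
    10 cm wall margin, 125 kHz acquisition, 30 Hz video, gamma-distributed
    (shape 3) inter-pulse intervals with mean tens of milliseconds, and
    channel noise set for a peak signal-to-noise ratio of 10.
    """

    seed: int = 0
    tank: TankGeometry = field(default_factory=TankGeometry)
    fish: list = field(default_factory=lambda: [
        FishSpec(1, 12.0, 1.0, 0.05, 1.0),
        FishSpec(2, 12.0, 1.0, 0.06, 1.1),
    ])
    speed_cm_s: float = 8.0
    heading_diffusion: float = 1.5    # rad / sqrt(s)
    gamma_shape: float = 3.0
    snr: float = 10.0
    noise_sigma: float | None = None  # V; overrides snr when set
    duration_s: float = 20.0
    frame_rate: float = 30.0
    sampling_rate: float = 125_000.0


def make_biphasic_pulse(fs: float = 125_000.0, duration_us: float = 400.0,
                        width_factor: float = 1.0) -> np.ndarray:
    """Zero-mean biphasic EOD template (difference of two Gaussians), peak 1.

    ``width_factor`` widens the second phase to mimic small individual
    waveform differences.
    """
    n = int(round(duration_us * 1e-6 * fs))
    if n < 4:
        raise ValueError("pulse too short at this sampling rate")
    t = np.arange(n) - n / 2.0
    s1 = n / 10.0
    s2 = n / 7.0 * width_factor
    g1 = np.exp(-((t + n / 12.0) ** 2) / (2 * s1**2))
    g2 = np.exp(-((t - n / 12.0) ** 2) / (2 * s2**2))
    pulse = g1 - g2 * (g1.sum() / g2.sum())  # exact zero mean
    return pulse / np.max(np.abs(pulse))


def _skeleton_from_track(anchor, theta, length) -> np.ndarray:
    """Six nodes laid along the heading; snout leads, anchor at head2."""
    rel = np.array([0.4, 0.2, 0.0, -0.2, -0.4, -0.6]) * length
    d = np.array([np.cos(theta), np.sin(theta)])
    return np.asarray(anchor) + np.outer(rel, d)


def make_trajectories(scenario: SyntheticScenario,
                      rng: np.random.Generator | None = None
                      ) -> TrackedSequence:
    """Smooth heading-random-walk trajectories, reflected at the wall margin."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    tank = scenario.tank
    dt = 1.0 / scenario.frame_rate
    n_frames = int(round(scenario.duration_s * scenario.frame_rate))
    margin = tank.wall_margin
    lo = np.array([margin, margin])
    hi = np.array([tank.width - margin, tank.depth_y - margin])
    poses = np.empty((n_frames, len(scenario.fish), 6, 2))
    for a, spec in enumerate(scenario.fish):
        pos = rng.uniform(lo + 2, hi - 2)
        theta = rng.uniform(0, 2 * np.pi)
        for f in range(n_frames):
            theta += scenario.heading_diffusion * np.sqrt(dt) * rng.normal()
            step = scenario.speed_cm_s * dt * np.array(
                [np.cos(theta), np.sin(theta)])
            pos = pos + step
            for d in range(2):  # reflect at the margin box
                if pos[d] < lo[d]:
                    pos[d] = 2 * lo[d] - pos[d]
                    theta = np.pi - theta if d == 0 else -theta
                elif pos[d] > hi[d]:
                    pos[d] = 2 * hi[d] - pos[d]
                    theta = np.pi - theta if d == 0 else -theta
            poses[f, a] = _skeleton_from_track(pos, theta, spec.length_cm)
    return TrackedSequence(poses, frame_rate=scenario.frame_rate)


def _gamma_renewal_times(rng, mean_ipi, shape, duration):
    times = []
    t = rng.gamma(shape, mean_ipi / shape)
    while t < duration:
        times.append(t)
        t += rng.gamma(shape, mean_ipi / shape)
    return np.asarray(times)


def _fish_state_at(seq: TrackedSequence, spec: FishSpec, t: float,
                   animal_index: int = 0):
    """Interpolated anchor/heading as a VirtualFish for the field model."""
    times = seq.frame_times
    i = np.clip(np.searchsorted(times, t) - 1, 0, seq.n_frames - 2)
    w = (t - times[i]) / (times[i + 1] - times[i])
    w = float(np.clip(w, 0.0, 1.0))
    nodes = (1 - w) * seq.poses[i, animal_index] \
        + w * seq.poses[i + 1, animal_index]
    head_dir = nodes[0] - nodes[5]
    theta = float(np.arctan2(head_dir[1], head_dir[0]))
    center = nodes.mean(axis=0)
    return VirtualFish.from_angle(spec.length_cm, tuple(center), theta,
                                  charge_scale=spec.amplitude_scale), nodes


def make_recording(scenario: SyntheticScenario, config,
                   tracks: TrackedSequence | None = None):
    """Synthesize the full acquisition: channels, TTL and truth tables.

    Each fish fires at gamma-renewal times; every EOD injects the fish's
    biphasic template scaled per channel by the dipole field model at its
    interpolated pose.  Gaussian channel noise is set from the scenario SNR
    (peak amplitude of the weakest event's strongest channel over sigma)
    unless ``noise_sigma`` is given.  Returns ``(recording, ttl, tracks,
    truth)`` where ``truth`` is a DataFrame listing every planted EOD (time,
    fish id, channel amplitudes, skeleton nodes) plus a ``doublet`` column
    marking cross-fish overlaps within 400 us.
    """
    rng = np.random.default_rng(scenario.seed)
    if tracks is None:
        tracks = make_trajectories(scenario, rng)
    fs = scenario.sampling_rate
    n_samples = int(round(scenario.duration_s * fs))
    tank = scenario.tank
    n_ch = config.n_channels

    events = []  # (time, spec, channel_amps, nodes)
    for animal_index, spec in enumerate(scenario.fish):
        t_margin = 600e-6
        times = _gamma_renewal_times(rng, spec.mean_ipi_s,
                                     scenario.gamma_shape,
                                     scenario.duration_s - t_margin)
        times = times[times > t_margin]
        for t in times:
            fish, nodes = _fish_state_at(tracks, spec, t, animal_index)
            amps = record_channels(fish, tank, config)
            events.append((float(t), spec, amps, nodes))
    events.sort(key=lambda e: e[0])

    if scenario.noise_sigma is not None:
        sigma = scenario.noise_sigma
    else:
        peak = min(np.max(np.abs(e[2])) for e in events) if events else 1.0
        sigma = peak / scenario.snr

    samples = rng.normal(0.0, sigma, size=(n_ch, n_samples))
    templates = {spec.fish_id: make_biphasic_pulse(
        fs, width_factor=spec.pulse_width_factor) for spec in scenario.fish}
    rows = []
    for t, spec, amps, nodes in events:
        tpl = templates[spec.fish_id]
        start = int(round(t * fs)) - len(tpl) // 2
        stop = start + len(tpl)
        if start < 0 or stop > n_samples:
            continue
        samples[:, start:stop] += np.outer(amps, tpl)
        row = {"eod_time": t, "fish_id": spec.fish_id,
               "peak_sample": start + int(np.argmax(np.abs(tpl)))}
        row.update({f"amp_ch{i + 1}": a for i, a in enumerate(amps)})
        row.update({f"node{j}_{c}": nodes[j, d]
                    for j in range(6) for d, c in enumerate("xy")})
        rows.append(row)
    truth = pd.DataFrame(rows)
    if len(truth):
        dt = truth["eod_time"].to_numpy()
        fid = truth["fish_id"].to_numpy()
        doublet = np.zeros(len(truth), dtype=bool)
        for i in range(len(truth) - 1):
            if dt[i + 1] - dt[i] < 400e-6 and fid[i + 1] != fid[i]:
                doublet[i] = doublet[i + 1] = True
        truth["doublet"] = doublet

    # TTL: ~1 ms high pulse per camera exposure
    ttl = np.zeros(n_samples)
    pulse_len = max(int(round(1e-3 * fs)), 1)
    for ft in tracks.frame_times:
        s = int(round(ft * fs))
        if s + pulse_len <= n_samples:
            ttl[s:s + pulse_len] = 5.0
    rec = MultichannelRecording(samples, fs)
    return rec, ttl, tracks, truth


def single_fish_scenario(scenario: SyntheticScenario, fish_index: int,
                         seed_offset: int = 0) -> SyntheticScenario:
    """Restrict a scenario to one fish (training segments have one fish)."""
    return replace(scenario, fish=[scenario.fish[fish_index]],
                   seed=scenario.seed + seed_offset)


def make_dyad_scene(size_ratio: float, approach_path,
                    base_length_cm: float = 13.0,
                    eod_times=None, n_rings: int = 15, ring_nodes: int = 9,
                    current_uA: float = 1000.0,
                    water_sigma_uScm: float = 120.0) -> list:
    """Per-timestep two-fish scenes along an approach trajectory.

    ``approach_path`` is a sequence of ``(t, pose1, pose2)`` with
    :class:`SkeletonPose` entries; fish 1 has length ``base_length_cm`` and
    fish 2 ``size_ratio`` times that.  The discharger alternates with each
    fish's EOD times (default: the path times, fish alternating).  Returns a
    list of ``(t, scene, emitter_id)``; a step whose meshes intersect is
    skipped with a log entry.
    """
    if not 0.0 < size_ratio <= 1.0:
        raise ValueError("size_ratio must lie in (0, 1]")
    lengths = {1: base_length_cm, 2: base_length_cm * size_ratio}
    profile = default_profile(n_rings)
    scenes = []
    for step, (t, pose1, pose2) in enumerate(approach_path):
        emitter = 1 + step % 2
        bodies = []
        for fid, pose in ((1, pose1), (2, pose2)):
            curve = fit_midline(pose)
            mesh = build_mesh(curve, lengths[fid], profile,
                              ring_nodes=ring_nodes)
            bodies.append(SceneBody(fid, mesh))
        if _meshes_intersect(bodies[0].mesh, bodies[1].mesh):
            import logging
            logging.getLogger(__name__).warning(
                "step %d skipped: meshes intersect", step)
            continue
        sources = eod_sources(bodies[emitter - 1].mesh, current_uA,
                              ring_nodes=ring_nodes)
        scenes.append((t, ConductivityScene(
            bodies, water_sigma_uScm, sources, emitter), emitter))
    return scenes


def _winding_number(mesh, points) -> np.ndarray:
    """Generalized winding number (~1 inside a closed outward mesh)."""
    tri = mesh.vertices[mesh.triangles]  # (F, 3, 3)
    total = np.zeros(len(points))
    for p_idx, p in enumerate(points):
        a = tri[:, 0] - p
        b = tri[:, 1] - p
        c = tri[:, 2] - p
        la = np.linalg.norm(a, axis=1)
        lb = np.linalg.norm(b, axis=1)
        lc = np.linalg.norm(c, axis=1)
        num = np.einsum("ij,ij->i", a, np.cross(b, c))
        den = (la * lb * lc + np.einsum("ij,ij->i", a, b) * lc
               + np.einsum("ij,ij->i", b, c) * la
               + np.einsum("ij,ij->i", a, c) * lb)
        total[p_idx] = np.sum(2.0 * np.arctan2(num, den)) / (4.0 * np.pi)
    return total


def _meshes_intersect(m0, m1) -> bool:
    # quick bounding-box reject, then winding-number point containment
    lo = np.maximum(m0.vertices.min(axis=0), m1.vertices.min(axis=0))
    hi = np.minimum(m0.vertices.max(axis=0), m1.vertices.max(axis=0))
    if np.any(lo > hi):
        return False
    in_box0 = np.all((m1.vertices >= lo - 1e-9)
                     & (m1.vertices <= hi + 1e-9), axis=1)
    in_box1 = np.all((m0.vertices >= lo - 1e-9)
                     & (m0.vertices <= hi + 1e-9), axis=1)
    if in_box0.any() and np.any(
            _winding_number(m0, m1.vertices[in_box0]) > 0.5):
        return True
    return bool(in_box1.any() and np.any(
        _winding_number(m1, m0.vertices[in_box1]) > 0.5))
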