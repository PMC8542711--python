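"""Closed 3-D fish surfaces from 2-D skeletons.

A third-order polynomial is fitted to the six skeleton nodes in a
fish-aligned frame; elliptical cross-sections (49 rings of 17 nodes by
default) are distributed along the curve by arc length and rotated to the
local tangent (the first derivative of the polynomial), tapering to apex
points at nose and tail.  The default resolution yields 49*17 + 2 = 835
vertices and 1,666 triangles, a closed orientable surface with
V - E + F = 2.  The two ellipse semi-axes per ring come from a canonical
body-profile table and scale with fish length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

__all__ = [
    "MidlineCurve",
    "FishMesh3D",
    "fit_midline",
    "default_profile",
    "build_mesh",
    "scale_mesh",
    "straight_pose",
    "sphere_mesh",
]

DEFAULT_N_RINGS = 49
DEFAULT_RING_NODES = 17


@dataclass
class MidlineCurve:
    """Cubic midline fit in a fish-aligned frame.

    The frame's x-axis is the head->tail principal direction of the visible
    skeleton nodes; ``coefficients`` are highest-power-first (numpy
    convention) for y_f = poly(x_f).
    """

    coefficients: np.ndarray   # (4,) cubic, highest power first
    rotation: np.ndarray       # (2, 2) tank -> fish frame
    translation: np.ndarray    # (2,) subtracted before rotation
    x_range: tuple             # (x_min, x_max) in the fish frame
    residuals: np.ndarray      # per-node fit residual, cm

    def evaluate(self, x_f) -> np.ndarray:
        """Curve points in tank coordinates for fish-frame abscissae."""
        x_f = np.atleast_1d(np.asarray(x_f, dtype=float))
        y_f = np.polyval(self.coefficients, x_f)
        pts_f = np.column_stack([x_f, y_f])
        return pts_f @ self.rotation + self.translation

    def tangent(self, x_f) -> np.ndarray:
        """Unit tangents (tank coordinates) from the first derivative."""
        x_f = np.atleast_1d(np.asarray(x_f, dtype=float))
        dy = np.polyval(np.polyder(self.coefficients), x_f)
        t_f = np.column_stack([np.ones_like(x_f), dy])
        t = t_f @ self.rotation
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    @property
    def arc_length(self) -> float:
        x = np.linspace(*self.x_range, 512)
        p = self.evaluate(x)
        return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))


def fit_midline(pose) -> MidlineCurve:
    """Least-squares cubic through the visible skeleton nodes.

    Needs at least 4 visible nodes (a cubic has 4 coefficients).  The fit is
    done in the fish frame so the curve stays single-valued for realistic
    body bends.
    """
    nodes = pose.nodes[pose.visibility]
    if nodes.shape[0] < 4:
        raise ValueError(
            f"midline fit needs >= 4 visible nodes, got {nodes.shape[0]}")
    head_to_tail = nodes[-1] - nodes[0]
    norm = np.linalg.norm(head_to_tail)
    if norm == 0:
        raise ValueError("degenerate skeleton: head and tail coincide")
    ex = head_to_tail / norm
    ey = np.array([-ex[1], ex[0]])
    rotation = np.column_stack([ex, ey])  # fish -> tank; orthonormal
    translation = nodes[0].astype(float)
    local = (nodes - translation) @ rotation  # tank -> fish (R^T = R^-1 used as right-mult)
    coeffs = np.polyfit(local[:, 0], local[:, 1], 3)
    resid = np.abs(np.polyval(coeffs, local[:, 0]) - local[:, 1])
    return MidlineCurve(
        coefficients=coeffs,
        rotation=rotation.T,
        translation=translation,
        x_range=(float(local[:, 0].min()), float(local[:, 0].max())),
        residuals=resid,
    )


@dataclass
class FishMesh3D:
    """Closed triangulated fish surface."""

    vertices: np.ndarray   # (V, 3) cm
    triangles: np.ndarray  # (F, 3) vertex indices, outward orientation
    length_cm: float

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def edge_counts(self) -> dict:
        """Occurrences of each undirected edge (2 everywhere iff closed)."""
        counts = {}
        for tri in self.triangles:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key = (min(a, b), max(a, b))
                counts[key] = counts.get(key, 0) + 1
        return counts

    def is_closed(self) -> bool:
        return all(c == 2 for c in self.edge_counts().values())

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edge_counts()) + self.n_triangles

    def signed_volume(self) -> float:
        v = self.vertices[self.triangles]
        return float(np.einsum("ij,ij->", np.cross(v[:, 0], v[:, 1]),
                               v[:, 2]) / 6.0)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)

    def export(self, path) -> None:
        """Write OBJ or PLY depending on the file suffix."""
        self.as_trimesh().export(path)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)

    def vertex_areas(self) -> np.ndarray:
        """Lumped area per vertex (one third of each incident triangle)."""
        areas = self.triangle_areas()
        out = np.zeros(self.n_vertices)
        for t, a in zip(self.triangles, areas):
            out[t] += a / 3.0
        return out


def default_profile(n_rings: int = DEFAULT_N_RINGS) -> pd.DataFrame:
    """Canonical body-profile table: relative ellipse semi-axes per ring.

    A mormyrid-like spindle: laterally compressed (height > width), deepest
    about 35% behind the snout, tapering smoothly toward both apexes.
    Columns are ``ring_index``, ``semi_width_rel``, ``semi_height_rel``
    (fractions of body length).
    """
    s = (np.arange(n_rings) + 1.0) / (n_rings + 1.0)
    shape = s**0.7 * (1.0 - s) ** 0.9
    shape = shape / shape.max()
    return pd.DataFrame({
        "ring_index": np.arange(n_rings),
        "semi_width_rel": 0.05 * shape,
        "semi_height_rel": 0.10 * shape,
    })


def load_profile(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"ring_index", "semi_width_rel", "semi_height_rel"}
    if not required <= set(df.columns):
        raise ValueError(f"profile table needs columns {sorted(required)}")
    return df


def build_mesh(curve: MidlineCurve, length_cm: float,
               profile: pd.DataFrame | None = None,
               ring_nodes: int = DEFAULT_RING_NODES,
               z_center: float = 6.0,
               bend_limit: float = 0.5,
               ring_positions: np.ndarray | None = None) -> FishMesh3D:
    """Stitch elliptical cross-sections along the midline into a closed mesh.

    Rings are spaced uniformly in arc length; each ring lies in the plane
    normal to the local tangent, spanned by the horizontal normal (width
    semi-axis) and the vertical (height semi-axis).  Adjacent rings are
    stitched with 2 * ring_nodes triangles and the nose/tail are closed by
    apex fans, so V = R*K + 2 and F = 2*V - 4.  The mesh is vertically
    centred at ``z_center`` (cm above the tank floor, half the water depth
    by default).
    """
    if length_cm <= 0:
        raise ValueError("length_cm must be positive")
    if profile is None:
        profile = default_profile()
    n_rings = len(profile)
    # arc-length parameterisation of the fitted curve
    x_dense = np.linspace(*curve.x_range, 1024)
    pts = curve.evaluate(x_dense)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s_cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = s_cum[-1]
    if total == 0:
        raise ValueError("midline has zero length")
    # rescale the fitted curve (about its midpoint) to the requested length
    scale = length_cm / total
    if ring_positions is None:
        ring_positions = (np.arange(n_rings) + 1.0) / (n_rings + 1.0)
    else:
        ring_positions = np.asarray(ring_positions, dtype=float)
        if ring_positions.shape != (n_rings,):
            raise ValueError("one ring position per profile row required")
    s_rel = np.concatenate([[0.0], ring_positions, [1.0]])
    x_at = np.interp(s_rel * total, s_cum, x_dense)
    mid = curve.evaluate(np.interp(0.5 * total, s_cum, x_dense))[0]
    centers2d = mid + (curve.evaluate(x_at) - mid) * scale
    tangents = curve.tangent(x_at)
    turn = np.abs(np.diff(np.arctan2(tangents[:, 1], tangents[:, 0])))
    turn = np.minimum(turn, 2 * np.pi - turn)
    if np.any(turn > bend_limit):
        import warnings
        warnings.warn("midline bends sharply; mesh may self-intersect",
                      RuntimeWarning, stacklevel=2)

    semi_w = profile["semi_width_rel"].to_numpy() * length_cm
    semi_h = profile["semi_height_rel"].to_numpy() * length_cm
    alphas = 2.0 * np.pi * np.arange(ring_nodes) / ring_nodes

    vertices = [np.array([centers2d[0, 0], centers2d[0, 1], z_center])]
    for k in range(n_rings):
        c = centers2d[k + 1]
        t = tangents[k + 1]
        u = np.array([-t[1], t[0], 0.0])       # horizontal ring axis
        vz = np.array([0.0, 0.0, 1.0])
        ring = (np.array([c[0], c[1], z_center])
                + np.outer(np.cos(alphas), semi_w[k] * u)
                + np.outer(np.sin(alphas), semi_h[k] * vz))
        vertices.extend(ring)
    vertices.append(np.array([centers2d[-1, 0], centers2d[-1, 1], z_center]))
    vertices = np.asarray(vertices)

    def ring_vertex(r, j):
        return 1 + r * ring_nodes + (j % ring_nodes)

    tris = []
    for j in range(ring_nodes):                      # nose fan
        tris.append((0, ring_vertex(0, j + 1), ring_vertex(0, j)))
    for r in range(n_rings - 1):                     # side strips
        for j in range(ring_nodes):
            a, b = ring_vertex(r, j), ring_vertex(r, j + 1)
            c, d = ring_vertex(r + 1, j), ring_vertex(r + 1, j + 1)
            tris.append((a, b, d))
            tris.append((a, d, c))
    tail_apex = len(vertices) - 1
    for j in range(ring_nodes):                      # tail fan
        tris.append((tail_apex, ring_vertex(n_rings - 1, j),
                     ring_vertex(n_rings - 1, j + 1)))
    mesh = FishMesh3D(vertices, np.asarray(tris), length_cm)
    if mesh.signed_volume() < 0:
        mesh.triangles = mesh.triangles[:, ::-1]
    return mesh


def scale_mesh(mesh: FishMesh3D, new_length_cm: float) -> FishMesh3D:
    """Uniformly scale about the centroid; vertex/triangle counts unchanged."""
    if new_length_cm <= 0:
        raise ValueError("new_length_cm must be positive")
    factor = new_length_cm / mesh.length_cm
    centroid = mesh.vertices.mean(axis=0)
    return FishMesh3D(centroid + factor * (mesh.vertices - centroid),
                      mesh.triangles.copy(), new_length_cm)


def straight_pose(length_cm: float = 12.0, center=(33.0, 36.0),
                  theta: float = 0.0):
    """A straight six-node skeleton, snout-first along ``theta``."""
    from .pose import SkeletonPose
    rel = np.array([0.5, 0.3, 0.1, -0.1, -0.3, -0.5])
    d = np.array([np.cos(theta), np.sin(theta)])
    nodes = np.asarray(center, dtype=float) + np.outer(rel * length_cm, d)
    return SkeletonPose(nodes)


def sphere_mesh(radius: float, center=(0.0, 0.0, 0.0),
                n_rings: int = DEFAULT_N_RINGS,
                ring_nodes: int = DEFAULT_RING_NODES) -> FishMesh3D:
    """A sphere built with the same ring/apex sampling as the fish meshes.

    Used as the analytic benchmark body for the boundary-element solver.
    """
    pose = straight_pose(2.0 * radius, center=(0.0, 0.0))
    curve = fit_midline(pose)
    # uniform polar angle for even sampling near the poles
    phi = np.pi * (np.arange(n_rings) + 1.0) / (n_rings + 1.0)
    s = (1.0 - np.cos(phi)) / 2.0
    r = np.sqrt(np.clip(1.0 - (2.0 * s - 1.0) ** 2, 0.0, 1.0)) / 2.0
    profile = pd.DataFrame({
        "ring_index": np.arange(n_rings),
        "semi_width_rel": r,
        "semi_height_rel": r,
    })
    mesh = build_mesh(curve, 2.0 * radius, profile, ring_nodes, z_center=0.0,
                      ring_positions=s)
    mesh.vertices = mesh.vertices + (np.asarray(center, dtype=float)
                                     - mesh.vertices.mean(axis=0))
    return mesh
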