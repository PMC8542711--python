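"""Boundary-element electrostatics for fish bodies with thin resistive skin.

The media are ohmic (J = sigma E), charge does not accumulate, and the
discharge is treated electrostatically, so the potential obeys a Poisson
equation driven by the source poles of the electric organ.  Each fish is a
homogeneous conductive volume bounded by a closed triangulated surface and
covered by a thin resistive skin: the normal current density J_n is
continuous across the skin while the potential jumps by rho_skin * J_n.

Collocating the boundary-integral form of the interior and exterior problems
at the N mesh nodes (linear interpolation over triangles, analytic Duffy
quadrature for the singular self terms) gives a dense 2N x 2N system whose
unknowns are the per-node transepithelial current density and surface
potential.  The electric image (EI) is the spatial pattern of transcutaneous
current density over a fish's skin: "active" is the perturbation of the
fish's own field by the other body (scene minus basal field), "passive" the
field a silent fish receives from the discharging one.

Internal units: cm, S/cm, uA; hence potentials in uV and current densities
in uA/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import FishMesh3D

__all__ = [
    "SceneBody",
    "ConductivityScene",
    "BoundarySolution",
    "ElectricImage",
    "assemble_and_solve",
    "basal_image",
    "active_image",
    "passive_image",
    "first_detection",
    "eod_sources",
    "BemError",
]


class BemError(RuntimeError):
    """Raised for invalid scenes or failed solves."""


# 7-point symmetric triangle rule (degree 5)
_QW = np.array([0.225,
                0.13239415278850618, 0.13239415278850618, 0.13239415278850618,
                0.12593918054482715, 0.12593918054482715, 0.12593918054482715])
_a1, _b1 = 0.059715871789769820, 0.470142064105115090
_a2, _b2 = 0.797426985353087320, 0.101286507323456340
_QB = np.array([
    [1 / 3, 1 / 3, 1 / 3],
    [_a1, _b1, _b1], [_b1, _a1, _b1], [_b1, _b1, _a1],
    [_a2, _b2, _b2], [_b2, _a2, _b2], [_b2, _b2, _a2],
])

# tensor Gauss-Legendre on [0,1]^2 for the Duffy-transformed self term
_GX, _GW = np.polynomial.legendre.leggauss(6)
_GX = 0.5 * (_GX + 1.0)
_GW = 0.5 * _GW


@dataclass
class SceneBody:
    """One conductive body (fish) in the scene."""

    body_id: object
    mesh: FishMesh3D
    sigma_body: float = 5e-3        # S/cm (0.5 S/m)
    skin_rho: float | np.ndarray = 30_000.0  # Ohm*cm^2, scalar or per node

    def skin_per_node(self) -> np.ndarray:
        rho = np.asarray(self.skin_rho, dtype=float)
        if rho.ndim == 0:
            rho = np.full(self.mesh.n_vertices, float(rho))
        if rho.shape != (self.mesh.n_vertices,):
            raise BemError("skin_rho must be scalar or per-node")
        return rho


@dataclass
class ConductivityScene:
    """Bodies, water conductivity and current sources for one solve.

    ``water_sigma_uScm`` is the measured water conductivity in uS/cm
    (default 120).  ``sources`` is a list of ((x, y, z) cm, current uA)
    poles inside the discharging body; the currents must sum to zero
    (charge conservation for an electrostatic discharge).  ``external_field``
    optionally applies a uniform field (uV/cm vector) for benchmark scenes.
    """

    bodies: list
    water_sigma_uScm: float = 120.0
    sources: list = field(default_factory=list)
    discharging_id: object = None
    external_field: np.ndarray | None = None

    def __post_init__(self):
        if self.water_sigma_uScm <= 0:
            raise BemError("water conductivity must be positive")
        ids = [b.body_id for b in self.bodies]
        if len(set(ids)) != len(ids):
            raise BemError("duplicate body ids")
        if self.sources:
            if self.discharging_id is None:
                raise BemError("sources require a discharging body id")
            if self.discharging_id not in ids:
                raise BemError("discharging body not in scene")
            total = sum(i for _, i in self.sources)
            mag = sum(abs(i) for _, i in self.sources)
            if mag > 0 and abs(total) > 1e-9 * mag:
                raise BemError("source currents must sum to zero")
        for b in self.bodies:
            if b.sigma_body < 0:
                raise BemError("body conductivity must be >= 0")

    @property
    def water_sigma(self) -> float:
        """S/cm."""
        return self.water_sigma_uScm * 1e-6

    def body(self, body_id) -> SceneBody:
        for b in self.bodies:
            if b.body_id == body_id:
                return b
        raise KeyError(body_id)


@dataclass
class BoundarySolution:
    """Per-node transepithelial current density and surface potential."""

    node_slices: dict                  # body_id -> slice into node arrays
    current_density: np.ndarray        # uA/cm^2, outward positive
    phi: np.ndarray                    # outer-surface potential, uV
    solve_residual: float
    vertex_areas: np.ndarray           # cm^2 (lumped)

    def body_values(self, body_id) -> np.ndarray:
        return self.current_density[self.node_slices[body_id]]

    def body_phi(self, body_id) -> np.ndarray:
        return self.phi[self.node_slices[body_id]]

    def total_current(self, body_id) -> float:
        """Net transcutaneous current (uA) over one body's surface."""
        s = self.node_slices[body_id]
        return float(np.sum(self.current_density[s] * self.vertex_areas[s]))


def _triangle_geometry(mesh: FishMesh3D):
    v = mesh.vertices[mesh.triangles]
    cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
    norms = np.linalg.norm(cross, axis=1)
    return v, cross / norms[:, None], 0.5 * norms


def _duffy_single_layer(x, p0, p1, p2, local_index):
    """Singular single-layer integrals for a triangle with x at vertex p0.

    Returns the three basis-weighted integrals (for vertices p0, p1, p2).
    ``local_index`` rotates the result so it matches the original vertex
    order.
    """
    e1, e2 = p1 - p0, p2 - p0
    area2 = np.linalg.norm(np.cross(e1, e2))
    u = _GX[:, None]
    v = _GX[None, :]
    w = _GW[:, None] * _GW[None, :]
    # y = p0 + u((1-v) e1 + v e2); |y - x| = u * |(1-v) e1 + v e2|
    direction = (1 - v)[..., None] * e1 + v[..., None] * e2
    dnorm = np.linalg.norm(direction, axis=-1)
    core = area2 * w / (4.0 * np.pi * dnorm)  # u jacobian cancels 1/u
    lam0 = (1 - u) * np.ones_like(v)
    lam1 = u * (1 - v)
    lam2 = u * v
    vals = np.array([(core * lam0).sum(), (core * lam1).sum(),
                     (core * lam2).sum()])
    out = np.empty(3)
    out[local_index] = vals[0]
    out[(local_index + 1) % 3] = vals[1]
    out[(local_index + 2) % 3] = vals[2]
    return out


def _subdivide(tri):
    p0, p1, p2 = tri
    m01, m12, m20 = (p0 + p1) / 2, (p1 + p2) / 2, (p2 + p0) / 2
    return [(p0, m01, m20), (m01, p1, m12), (m20, m12, p2), (m01, m12, m20)]


def _refined_quadrature(tri, depth=2):
    """Quadrature points/weights/barycentrics on a 4^depth subdivision."""
    tris = [(np.asarray(tri[0]), np.asarray(tri[1]), np.asarray(tri[2]))]
    barys = [np.eye(3)]
    for _ in range(depth):
        new_t, new_b = [], []
        for t, b in zip(tris, barys):
            subs = _subdivide(t)
            # barycentric corners of each sub-triangle w.r.t. the parent
            bc = [(b[0], (b[0] + b[1]) / 2, (b[2] + b[0]) / 2),
                  ((b[0] + b[1]) / 2, b[1], (b[1] + b[2]) / 2),
                  ((b[2] + b[0]) / 2, (b[1] + b[2]) / 2, b[2]),
                  ((b[0] + b[1]) / 2, (b[1] + b[2]) / 2, (b[2] + b[0]) / 2)]
            new_t.extend(subs)
            new_b.extend(np.array(x) for x in bc)
        tris, barys = new_t, new_b
    pts, wts, lams = [], [], []
    for t, b in zip(tris, barys):
        corners = np.array(t)
        area = 0.5 * np.linalg.norm(np.cross(corners[1] - corners[0],
                                             corners[2] - corners[0]))
        pts.append(_QB @ corners)
        wts.append(_QW * area)
        lams.append(_QB @ b)
    return np.vstack(pts), np.concatenate(wts), np.vstack(lams)


def _assemble_layers(nodes, tri_lists, near_factor=1.2):
    """Dense single- and double-layer matrices collocated at all nodes.

    ``tri_lists`` is a list of (triangles(3 indices into nodes), vertices,
    normals, areas) per body.  Self terms use the Duffy transform (single
    layer) and vanish exactly for the flat double layer; near terms are
    re-integrated on a refined subdivision.
    """
    n = len(nodes)
    S = np.zeros((n, n))
    D = np.zeros((n, n))
    for triangles, tri_v, tri_n, tri_a in tri_lists:
        diam = np.sqrt(tri_a.max()) * 2.0
        for t_idx in range(len(triangles)):
            verts = triangles[t_idx]
            corners = tri_v[t_idx]
            normal = tri_n[t_idx]
            area = tri_a[t_idx]
            qpts = _QB @ corners                     # (7, 3)
            r = nodes[:, None, :] - qpts[None, :, :]  # (n, 7, 3)
            dist = np.linalg.norm(r, axis=2)
            with np.errstate(divide="ignore", invalid="ignore"):
                g = 1.0 / (4.0 * np.pi * dist)
                h = (r @ normal) / (4.0 * np.pi * dist**3)
            wg = (g * _QW) * area                     # (n, 7)
            wh = (h * _QW) * area
            S[:, verts] += wg @ _QB
            D[:, verts] += wh @ _QB
            # refine nodes that are close to (but not on) the triangle
            centroid = corners.mean(axis=0)
            d_c = np.linalg.norm(nodes - centroid, axis=1)
            near = np.flatnonzero(d_c < near_factor * diam)
            near = [i for i in near if i not in verts]
            if near:
                pts, wts, lams = _refined_quadrature(corners, depth=2)
                rr = nodes[near][:, None, :] - pts[None, :, :]
                dd = np.linalg.norm(rr, axis=2)
                gg = wts / (4.0 * np.pi * dd)
                hh = (rr @ normal) * wts / (4.0 * np.pi * dd**3)
                S[np.ix_(near, verts)] += gg @ lams - (wg[near] @ _QB)
                D[np.ix_(near, verts)] += hh @ lams - (wh[near] @ _QB)
            # singular self terms
            for local, node_index in enumerate(verts):
                S[node_index, verts] -= wg[node_index] @ _QB
                D[node_index, verts] -= wh[node_index] @ _QB
                S[node_index, verts] += _duffy_single_layer(
                    nodes[node_index], corners[local],
                    corners[(local + 1) % 3], corners[(local + 2) % 3], local)
                # flat-triangle double layer through the node is exactly 0
    return S, D


def assemble_and_solve(scene: ConductivityScene) -> BoundarySolution:
    """Build and solve the collocation system for one scene.

    Unknowns are the outer-surface potential and the outward transepithelial
    current density at every node.  Interior equations are scaled by the
    body conductivity so perfectly insulating bodies stay well conditioned.
    """
    if not scene.bodies:
        raise BemError("scene has no bodies")
    meshes = [b.mesh for b in scene.bodies]
    for m in meshes:
        if not m.is_closed():
            raise BemError("all meshes must be closed surfaces")
    counts = [m.n_vertices for m in meshes]
    offsets = np.concatenate([[0], np.cumsum(counts)])
    n = int(offsets[-1])
    nodes = np.vstack([m.vertices for m in meshes])
    slices = {b.body_id: slice(int(offsets[i]), int(offsets[i + 1]))
              for i, b in enumerate(scene.bodies)}

    tri_lists = []
    for i, m in enumerate(meshes):
        tri_v, tri_n, tri_a = _triangle_geometry(m)
        tri_lists.append((m.triangles + offsets[i], tri_v, tri_n, tri_a))

    S, D = _assemble_layers(nodes, tri_lists)

    sigma_w = scene.water_sigma
    A = np.zeros((2 * n, 2 * n))
    rhs = np.zeros(2 * n)

    # exterior collocation rows (total field, all surfaces)
    c_ext = 1.0 + D.sum(axis=1)
    A[:n, :n] = -D
    A[:n, :n][np.arange(n), np.arange(n)] += c_ext
    A[:n, n:] = S / sigma_w
    if scene.external_field is not None:
        e0 = np.asarray(scene.external_field, dtype=float)
        rhs[:n] = -nodes @ e0

    # interior collocation rows per body, scaled by sigma_body
    for i, b in enumerate(scene.bodies):
        sl = slices[b.body_id]
        rho = b.skin_per_node()
        Dk = D[sl, sl]
        Sk = S[sl, sl]
        c_int = -Dk.sum(axis=1)
        M = Dk.copy()
        M[np.arange(counts[i]), np.arange(counts[i])] += c_int
        rows = slice(n + sl.start, n + sl.stop)
        A[rows, sl] = b.sigma_body * M
        A[rows, n + sl.start: n + sl.stop] = b.sigma_body * (M * rho[None, :]) - Sk
        if scene.sources and scene.discharging_id == b.body_id:
            for pos, current in scene.sources:
                r = np.linalg.norm(nodes[sl] - np.asarray(pos, dtype=float),
                                   axis=1)
                if np.any(r < 1e-9):
                    raise BemError("source pole touches the surface")
                rhs[rows] += current / (4.0 * np.pi * r)

    try:
        x = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(A)
        raise BemError(f"singular system (condition ~ {cond:.2e})") from exc
    residual = float(np.linalg.norm(A @ x - rhs)
                     / max(np.linalg.norm(rhs), 1e-300))

    areas = np.concatenate([m.vertex_areas() for m in meshes])
    return BoundarySolution(
        node_slices=slices,
        current_density=x[n:],
        phi=x[:n],
        solve_residual=residual,
        vertex_areas=areas,
    )


@dataclass
class ElectricImage:
    """Per-node transcutaneous current-density image at one fish's skin."""

    values: np.ndarray       # uA/cm^2
    modality: str            # "active" | "passive" | "active-basal"
    emitter_id: object
    perceiver_id: object

    def __post_init__(self):
        if self.modality == "active" and self.emitter_id != self.perceiver_id:
            raise BemError("active image requires emitter == perceiver")
        if self.modality == "passive" and self.emitter_id == self.perceiver_id:
            raise BemError("passive image requires emitter != perceiver")

    @property
    def summary(self) -> dict:
        return {"max": float(np.max(np.abs(self.values))),
                "rms": float(np.sqrt(np.mean(self.values**2)))}


def _emitter_scene(scene: ConductivityScene) -> ConductivityScene:
    emitter = scene.body(scene.discharging_id)
    return ConductivityScene([emitter], scene.water_sigma_uScm,
                             scene.sources, scene.discharging_id,
                             scene.external_field)


def basal_image(scene: ConductivityScene,
                solution: BoundarySolution | None = None) -> ElectricImage:
    """Self image of the emitter alone in water (the basal field)."""
    basal = _emitter_scene(scene)
    if solution is None:
        solution = assemble_and_solve(basal)
    eid = scene.discharging_id
    return ElectricImage(solution.body_values(eid), "active-basal", eid, eid)


def active_image(scene: ConductivityScene,
                 scene_solution: BoundarySolution | None = None,
                 basal_solution: BoundarySolution | None = None
                 ) -> ElectricImage:
    """Scene-minus-basal image at the discharging fish's own skin."""
    if len(scene.bodies) < 2:
        raise BemError("active image needs the full scene (both fish)")
    eid = scene.discharging_id
    if scene_solution is None:
        scene_solution = assemble_and_solve(scene)
    if basal_solution is None:
        basal_solution = assemble_and_solve(_emitter_scene(scene))
    full = scene_solution.body_values(eid)
    base = basal_solution.body_values(eid)
    if full.shape != base.shape:
        raise BemError("scene/basal mesh mismatch for the emitter")
    return ElectricImage(full - base, "active", eid, eid)


def passive_image(scene: ConductivityScene, receiver_id,
                  scene_solution: BoundarySolution | None = None
                  ) -> ElectricImage:
    """Stimulus image at the silent fish's skin."""
    if receiver_id == scene.discharging_id:
        raise BemError("receiver must not be the discharging fish")
    if scene_solution is None:
        scene_solution = assemble_and_solve(scene)
    return ElectricImage(scene_solution.body_values(receiver_id), "passive",
                         scene.discharging_id, receiver_id)


def first_detection(series_a, series_b, factor: float = 2.0,
                    floor: float = 0.1, ids=("A", "B")):
    """First moment one fish's EI amplitude doubly exceeds the other's.

    ``series_a``/``series_b`` are time-ordered (t, amplitude) pairs of the EI
    amplitude *received by* fish A and B.  On the union of both time axes
    (the other fish's amplitude held at its most recent value) the detection
    criterion is: amplitude > ``factor`` x other AND amplitude > ``floor``
    (the model's internal noise floor).  Returns ``(fish_id, t)`` or ``None``.
    """
    a = np.atleast_2d(np.asarray(series_a, dtype=float))
    b = np.atleast_2d(np.asarray(series_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both series must be non-empty")
    events = sorted(
        [(t, v, 0) for t, v in a] + [(t, v, 1) for t, v in b])
    last = [None, None]
    for t, v, who in events:
        last[who] = v
        if last[0] is None or last[1] is None:
            continue
        for me in (0, 1):
            other = 1 - me
            if last[me] > factor * last[other] and last[me] > floor:
                return ids[me], t
    return None


def eod_sources(mesh: FishMesh3D, current_uA: float = 1000.0,
                fractions=(0.78, 0.92), ring_nodes: int = 17) -> list:
    """Dipole source poles inside the caudal peduncle of a fish mesh.

    The electric organ of mormyrids sits in the tail; the two poles (+I at
    the rostral fraction, -I at the caudal one) are placed on the body
    midline at the given arc fractions.
    """
    n_rings = (mesh.n_vertices - 2) // ring_nodes
    centers = mesh.vertices[1:-1].reshape(n_rings, ring_nodes, 3).mean(axis=1)
    poles = []
    for frac, sign in zip(fractions, (1.0, -1.0)):
        idx = min(int(round(frac * (n_rings - 1))), n_rings - 1)
        poles.append((centers[idx], sign * current_uA))
    return poles
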