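"""Triangulated-surface data structures and geometric primitives.

The drop-model solver works on explicit triangle meshes: a closed surface for
the nucleus and a boundary-fixed cap for the cell cortex.  This module holds
the mesh container (:class:`TriSurface`), the geometric quantities the energy
functional needs (surface area, enclosed volume, centroidal-Voronoi-
tessellation quality energy, with analytic gradients), Delaunay-style edge
flipping used to keep the tessellation centroidal during minimization, and
DISTMESH-style initial mesh generation for spheres, ellipsoids and capped
footprints.

Units are µm throughout (µm² for areas, µm³ for volumes, µm⁴ for the CVT
energy).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, Delaunay

from .errors import ContractViolationError, InvalidParameterError

__all__ = [
    "TriSurface",
    "MeshEnergyReport",
    "make_initial_mesh",
    "surface_area",
    "enclosed_volume",
    "cvt_energy",
    "flip_edges",
    "energy_report",
    "vertex_dual_cells",
    "vertex_mean_curvature",
    "save_mesh",
    "load_mesh",
]


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------


@dataclass
class TriSurface:
    """A triangulated surface.

    Parameters
    ----------
    vertices : (N, 3) float array, µm
    faces : (F, 3) int array
        Vertex index triples with consistent (outward) orientation.
    fixed_mask : (N,) bool array, optional
        True for pinned vertices (the adhesion-perimeter boundary
        condition).  Defaults to all-free.
    """

    vertices: np.ndarray
    faces: np.ndarray
    fixed_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InvalidParameterError("vertices must be (N, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise InvalidParameterError("faces must be (F, 3)")
        if self.fixed_mask is None:
            self.fixed_mask = np.zeros(len(self.vertices), dtype=bool)
        else:
            self.fixed_mask = np.asarray(self.fixed_mask, dtype=bool)
            if self.fixed_mask.shape != (len(self.vertices),):
                raise InvalidParameterError("fixed_mask must be (N,)")

    # -- topology -----------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def directed_edges(self) -> np.ndarray:
        """(3F, 2) directed edge list, face-major."""
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def undirected_edges(self) -> np.ndarray:
        """(E, 2) unique sorted edge list."""
        de = np.sort(self.directed_edges(), axis=1)
        return np.unique(de, axis=0)

    def boundary_edges(self) -> np.ndarray:
        """Edges that belong to exactly one face."""
        de = np.sort(self.directed_edges(), axis=1)
        edges, counts = np.unique(de, axis=0, return_counts=True)
        return edges[counts == 1]

    def boundary_vertices(self) -> np.ndarray:
        be = self.boundary_edges()
        return np.unique(be)

    def is_closed(self) -> bool:
        return len(self.boundary_edges()) == 0

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.undirected_edges()) + self.n_faces

    def mean_edge_length(self) -> float:
        e = self.undirected_edges()
        d = self.vertices[e[:, 0]] - self.vertices[e[:, 1]]
        return float(np.linalg.norm(d, axis=1).mean())

    def copy(self) -> "TriSurface":
        return TriSurface(
            self.vertices.copy(), self.faces.copy(), self.fixed_mask.copy()
        )

    def validate(self) -> None:
        """Check the structural invariants; raise on violation."""
        f = self.faces
        if f.min(initial=0) < 0 or f.max(initial=-1) >= self.n_vertices:
            raise ContractViolationError("face index out of range")
        if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
            raise ContractViolationError("face with repeated vertex")
        de = self.directed_edges()
        key = de[:, 0] * self.n_vertices + de[:, 1]
        if len(np.unique(key)) != len(key):
            raise ContractViolationError(
                "directed edge repeated: inconsistent orientation or "
                "non-manifold mesh"
            )
        sde = np.sort(de, axis=1)
        _, counts = np.unique(sde, axis=0, return_counts=True)
        if counts.max(initial=0) > 2:
            raise ContractViolationError("edge shared by more than two faces")
        if np.any(triangle_areas(self) <= 0):
            raise ContractViolationError("degenerate (zero-area) triangle")


@dataclass
class MeshEnergyReport:
    """Bundle of the geometric quantities entering the energy functional."""

    surface_area: float  # µm²
    enclosed_volume: Optional[float]  # µm³; None for open surfaces
    cvt_energy: float  # µm⁴
    per_face_quality: np.ndarray = field(repr=False)  # aspect ratios, ≥ 1


# ---------------------------------------------------------------------------
# elementary quantities
# ---------------------------------------------------------------------------


def _face_corners(s: TriSurface):
    v, f = s.vertices, s.faces
    return v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]


def face_normals_raw(s: TriSurface) -> np.ndarray:
    """Unnormalized face normals (b-a) x (c-a); |n| = 2 * area."""
    a, b, c = _face_corners(s)
    return np.cross(b - a, c - a)


def triangle_areas(s: TriSurface) -> np.ndarray:
    return 0.5 * np.linalg.norm(face_normals_raw(s), axis=1)


def surface_area(s: TriSurface) -> float:
    """Total surface area (µm²): the sum of triangle areas."""
    return float(triangle_areas(s).sum())


def enclosed_volume(s: TriSurface) -> float:
    """Signed enclosed volume (µm³) by the divergence theorem.

    Positive for consistent outward orientation.  Raises
    :class:`ContractViolationError` on open surfaces.
    """
    if not s.is_closed():
        raise ContractViolationError("enclosed_volume requires a closed surface")
    a, b, c = _face_corners(s)
    return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)


def surface_area_grad(vertices: np.ndarray, faces: np.ndarray):
    """Total area and its gradient w.r.t. vertex positions."""
    a, b, c = vertices[faces[:, 0]], vertices[faces[:, 1]], vertices[faces[:, 2]]
    n = np.cross(b - a, c - a)
    nn = np.linalg.norm(n, axis=1)
    area = 0.5 * nn.sum()
    nhat = n / np.where(nn > 0, nn, 1.0)[:, None]
    g = np.zeros_like(vertices)
    # dA/da = ((b - c) x n_hat) / 2, cyclically
    np.add.at(g, faces[:, 0], 0.5 * np.cross(b - c, nhat))
    np.add.at(g, faces[:, 1], 0.5 * np.cross(c - a, nhat))
    np.add.at(g, faces[:, 2], 0.5 * np.cross(a - b, nhat))
    return float(area), g


def volume_zflux_grad(vertices: np.ndarray, faces: np.ndarray):
    """Volume below the surface by the flux of F = z e_z, with gradient.

    Exact for closed surfaces; for a cap whose boundary lies in the z = 0
    substrate plane it equals the volume enclosed between cap and plane.
    """
    a, b, c = vertices[faces[:, 0]], vertices[faces[:, 1]], vertices[faces[:, 2]]
    n = np.cross(b - a, c - a)  # |n| = 2A
    zsum = a[:, 2] + b[:, 2] + c[:, 2]
    vol = float((n[:, 2] * zsum).sum() / 6.0)
    g = np.zeros_like(vertices)
    ez = np.zeros(3)
    ez[2] = 1.0
    # d(n_z)/da = ((b-c)_y, -(b-c)_x, 0), cyclically
    for k, (p, q) in enumerate(((b, c), (c, a), (a, b))):
        d = p - q
        dn_z = np.stack([d[:, 1], -d[:, 0], np.zeros(len(d))], axis=1)
        contrib = (n[:, 2][:, None] * ez[None, :] + zsum[:, None] * dn_z) / 6.0
        np.add.at(g, faces[:, k], contrib)
    return vol, g


def enclosed_volume_any(s: TriSurface) -> float:
    """Enclosed volume for closed surfaces or substrate-bounded caps."""
    if s.is_closed():
        return enclosed_volume(s)
    v, _ = volume_zflux_grad(s.vertices, s.faces)
    return v


# ---------------------------------------------------------------------------
# CVT mesh-quality energy
# ---------------------------------------------------------------------------


def _tri_second_moment(q0, q1, q2, p, want_grad):
    """∫_T ||x - p||² dA over triangle (q0,q1,q2), exact (midpoint rule is
    exact for quadratics).  All arguments (..., 3) arrays."""
    m1 = 0.5 * (q0 + q1)
    m2 = 0.5 * (q1 + q2)
    m3 = 0.5 * (q2 + q0)
    n = np.cross(q1 - q0, q2 - q0)
    nn = np.linalg.norm(n, axis=-1)
    area = 0.5 * nn
    d1, d2, d3 = m1 - p, m2 - p, m3 - p
    S = (d1 * d1).sum(-1) + (d2 * d2).sum(-1) + (d3 * d3).sum(-1)
    I = area * S / 3.0
    if not want_grad:
        return I, None
    nhat = n / np.where(nn > 0, nn, 1.0)[..., None]
    gA0 = 0.5 * np.cross(q1 - q2, nhat)
    gA1 = 0.5 * np.cross(q2 - q0, nhat)
    gA2 = 0.5 * np.cross(q0 - q1, nhat)
    S3 = (S / 3.0)[..., None]
    A3 = (area / 3.0)[..., None]
    g0 = S3 * gA0 + A3 * (d1 + d3)
    g1 = S3 * gA1 + A3 * (d1 + d2)
    g2 = S3 * gA2 + A3 * (d2 + d3)
    gp = -2.0 * A3 * (d1 + d2 + d3)
    return I, (g0, g1, g2, gp)


def cvt_energy_grad(vertices: np.ndarray, faces: np.ndarray, want_grad=True):
    """CVT quality energy  E = Σ_i ∫_{v_i} ||x - x_i||² dA  on barycentric
    dual cells, with exact analytic gradient.

    The dual cell of vertex i inside an incident triangle is the quad
    (x_i, edge midpoint, barycenter, edge midpoint) — the region where the
    barycentric coordinate of i is largest.
    """
    a, b, c = vertices[faces[:, 0]], vertices[faces[:, 1]], vertices[faces[:, 2]]
    mab, mbc, mca = 0.5 * (a + b), 0.5 * (b + c), 0.5 * (c + a)
    g = (a + b + c) / 3.0
    total = 0.0
    grad = np.zeros_like(vertices) if want_grad else None

    def acc(I, grads, qspec, p_col):
        nonlocal total
        total += float(I.sum())
        if not want_grad:
            return
        g0, g1, g2, gp = grads
        cols = {0: faces[:, 0], 1: faces[:, 1], 2: faces[:, 2]}
        for gq, spec in zip((g0, g1, g2), qspec):
            for col, w in spec:
                np.add.at(grad, cols[col], w * gq)
        np.add.at(grad, cols[p_col], gp)

    third = 1.0 / 3.0
    G = [(0, third), (1, third), (2, third)]
    # corner a: (a, mab, g) and (a, g, mca)
    I, gr = _tri_second_moment(a, mab, g, a, want_grad)
    acc(I, gr, ([(0, 1.0)], [(0, 0.5), (1, 0.5)], G), 0)
    I, gr = _tri_second_moment(a, g, mca, a, want_grad)
    acc(I, gr, ([(0, 1.0)], G, [(2, 0.5), (0, 0.5)]), 0)
    # corner b: (b, mbc, g) and (b, g, mab)
    I, gr = _tri_second_moment(b, mbc, g, b, want_grad)
    acc(I, gr, ([(1, 1.0)], [(1, 0.5), (2, 0.5)], G), 1)
    I, gr = _tri_second_moment(b, g, mab, b, want_grad)
    acc(I, gr, ([(1, 1.0)], G, [(0, 0.5), (1, 0.5)]), 1)
    # corner c: (c, mca, g) and (c, g, mbc)
    I, gr = _tri_second_moment(c, mca, g, c, want_grad)
    acc(I, gr, ([(2, 1.0)], [(2, 0.5), (0, 0.5)], G), 2)
    I, gr = _tri_second_moment(c, g, mbc, c, want_grad)
    acc(I, gr, ([(2, 1.0)], G, [(1, 0.5), (2, 0.5)]), 2)
    return total, grad


def cvt_energy(s: TriSurface) -> float:
    """Centroidal-Voronoi-tessellation quality energy (µm⁴)."""
    e, _ = cvt_energy_grad(s.vertices, s.faces, want_grad=False)
    return e


def vertex_dual_cells(s: TriSurface):
    """Barycentric dual-cell areas (N,) and centroids (N, 3)."""
    v, f = s.vertices, s.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    mab, mbc, mca = 0.5 * (a + b), 0.5 * (b + c), 0.5 * (c + a)
    g = (a + b + c) / 3.0
    areas = np.zeros(s.n_vertices)
    first = np.zeros((s.n_vertices, 3))

    def add(q0, q1, q2, col):
        n = np.cross(q1 - q0, q2 - q0)
        A = 0.5 * np.linalg.norm(n, axis=-1)
        m = (q0 + q1 + q2) / 3.0  # centroid of a triangle
        np.add.at(areas, f[:, col], A)
        np.add.at(first, f[:, col], A[:, None] * m)

    add(a, mab, g, 0)
    add(a, g, mca, 0)
    add(b, mbc, g, 1)
    add(b, g, mab, 1)
    add(c, mca, g, 2)
    add(c, g, mbc, 2)
    cen = first / np.where(areas > 0, areas, 1.0)[:, None]
    return areas, cen


def energy_report(s: TriSurface) -> MeshEnergyReport:
    areas = triangle_areas(s)
    a, b, c = _face_corners(s)
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(c - a, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    sp = 0.5 * (la + lb + lc)
    # aspect = circumradius / (2 * inradius); 1 for equilateral
    inr = areas / np.where(sp > 0, sp, 1.0)
    circ = la * lb * lc / np.where(areas > 0, 4.0 * areas, 1.0)
    quality = circ / np.where(inr > 0, 2.0 * inr, np.inf)
    vol = enclosed_volume(s) if s.is_closed() else None
    return MeshEnergyReport(float(areas.sum()), vol, cvt_energy(s), quality)


def vertex_mean_curvature(s: TriSurface) -> np.ndarray:
    """Signed discrete mean curvature per vertex (1/µm), cotangent formula.

    Positive where the surface is convex with respect to the outward normal.
    Barycentric (1/3) vertex areas are used.
    """
    v, f = s.vertices, s.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    n = np.cross(b - a, c - a)
    areas = 0.5 * np.linalg.norm(n, axis=1)

    def cot(u, w):
        cr = np.linalg.norm(np.cross(u, w), axis=1)
        return np.einsum("ij,ij->i", u, w) / np.where(cr > 0, cr, np.inf)

    cot_a = cot(b - a, c - a)  # opposite edge (b, c)
    cot_b = cot(c - b, a - b)  # opposite edge (c, a)
    cot_c = cot(a - c, b - c)  # opposite edge (a, b)

    lap = np.zeros_like(v)
    for (i, j), w in (((1, 2), cot_a), ((2, 0), cot_b), ((0, 1), cot_c)):
        d = v[f[:, j]] - v[f[:, i]]
        np.add.at(lap, f[:, i], 0.5 * w[:, None] * d)
        np.add.at(lap, f[:, j], -0.5 * w[:, None] * d)

    va = np.zeros(len(v))
    for k in range(3):
        np.add.at(va, f[:, k], areas / 3.0)
    vn = np.zeros_like(v)
    for k in range(3):
        np.add.at(vn, f[:, k], n)
    nn = np.linalg.norm(vn, axis=1)
    vn = vn / np.where(nn > 0, nn, 1.0)[:, None]
    hvec = lap / np.where(va > 0, va, np.inf)[:, None]
    # mean-curvature normal points inward for convex outward-oriented surfaces
    return -0.5 * np.einsum("ij,ij->i", hvec, vn)


# ---------------------------------------------------------------------------
# edge flipping
# ---------------------------------------------------------------------------


def _opposite_angle(v, apex, e0, e1):
    u = v[e0] - v[apex]
    w = v[e1] - v[apex]
    cu = np.linalg.norm(u, axis=-1)
    cw = np.linalg.norm(w, axis=-1)
    cosang = np.einsum("...i,...i->...", u, w) / np.where(cu * cw > 0, cu * cw, np.inf)
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def flip_edges(s: TriSurface, angle_tol: float = 1e-8, max_passes: int = 100) -> TriSurface:
    """Enforce the local Delaunay criterion by flipping interior edges whose
    two opposite angles sum to more than π (beyond ``angle_tol``).

    Vertex positions are untouched; flips that would duplicate an existing
    edge or create a degenerate triangle are skipped.  Ties (sum exactly π
    within tolerance) are not flipped, for determinism.
    """
    v = s.vertices
    faces = s.faces.copy()
    for _ in range(max_passes):
        nV = len(v)
        de = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
        face_of = np.tile(np.arange(len(faces)), 3)
        corner = np.concatenate(
            [faces[:, 2], faces[:, 0], faces[:, 1]]
        )  # vertex opposite each directed edge
        key = np.minimum(de[:, 0], de[:, 1]) * nV + np.maximum(de[:, 0], de[:, 1])
        order = np.argsort(key, kind="stable")
        key_s = key[order]
        interior = np.flatnonzero(key_s[:-1] == key_s[1:])
        i0, i1 = order[interior], order[interior + 1]
        if len(i0) == 0:
            break
        a, bb = de[i0, 0], de[i0, 1]
        cc, dd = corner[i0], corner[i1]
        ang = _opposite_angle(v, cc, a, bb) + _opposite_angle(v, dd, a, bb)
        cand = np.flatnonzero(ang > np.pi + angle_tol)
        if len(cand) == 0:
            break
        # existing undirected edges, to veto duplicate-creating flips
        existing = set(map(tuple, np.sort(de, axis=1).tolist()))
        used = np.zeros(len(faces), dtype=bool)
        cand = cand[np.argsort(-(ang[cand]))]
        flipped = 0
        for k in cand:
            f1, f2 = face_of[i0[k]], face_of[i1[k]]
            if used[f1] or used[f2]:
                continue
            va, vb, vc, vd = a[k], bb[k], cc[k], dd[k]
            new_edge = (min(vc, vd), max(vc, vd))
            if new_edge in existing:
                continue
            t1 = np.array([va, vd, vc])
            t2 = np.array([vd, vb, vc])
            ar1 = 0.5 * np.linalg.norm(np.cross(v[t1[1]] - v[t1[0]], v[t1[2]] - v[t1[0]]))
            ar2 = 0.5 * np.linalg.norm(np.cross(v[t2[1]] - v[t2[0]], v[t2[2]] - v[t2[0]]))
            if ar1 < 1e-12 or ar2 < 1e-12:
                continue
            faces[f1] = t1
            faces[f2] = t2
            used[f1] = used[f2] = True
            existing.add(new_edge)
            flipped += 1
        if flipped == 0:
            break
    return TriSurface(v.copy(), faces, s.fixed_mask.copy())


# ---------------------------------------------------------------------------
# DISTMESH-style initial meshing
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = 2.0 * np.pi * i / phi + rng.uniform(0, 2 * np.pi)
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _project_ellipsoid(p: np.ndarray, axes: np.ndarray) -> np.ndarray:
    u = p / axes
    nrm = np.linalg.norm(u, axis=-1, keepdims=True)
    nrm = np.where(nrm > 0, nrm, 1.0)
    return (u / nrm) * axes


def _relax_on_ellipsoid(pts, axes, h, n_iter=80):
    """DISTMESH-style spring equilibration with projection to the surface.

    The triangulation is recomputed from the convex hull every iteration
    (the surface is convex); edges act as purely repulsive springs at rest
    length 1.2 h."""
    for _ in range(n_iter):
        hull = ConvexHull(pts)
        faces = hull.simplices
        edges = np.unique(
            np.sort(
                np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]),
                axis=1,
            ),
            axis=0,
        )
        d = pts[edges[:, 1]] - pts[edges[:, 0]]
        L = np.linalg.norm(d, axis=1, keepdims=True)
        L0 = 1.2 * h
        Fmag = np.maximum(L0 - L, 0.0)
        Fvec = Fmag * d / np.where(L > 0, L, 1.0)
        force = np.zeros_like(pts)
        np.add.at(force, edges[:, 0], -Fvec)
        np.add.at(force, edges[:, 1], Fvec)
        pts = _project_ellipsoid(pts + 0.2 * force, axes)
    return pts


def _ellipsoid_mesh(axes, target_edge_length, seed):
    axes = np.asarray(axes, dtype=float)
    if np.any(axes <= 0):
        raise InvalidParameterError("ellipsoid semiaxes must be positive")
    # surface area estimate (Thomsen's approximation) to size the point set
    p = 1.6075
    ap, bp, cp = axes**p
    area = 4.0 * np.pi * ((ap * bp + ap * cp + bp * cp) / 3.0) ** (1.0 / p)
    n_faces = max(int(round(area / (np.sqrt(3) / 4.0 * target_edge_length**2))), 50)
    n_pts = n_faces // 2 + 2
    pts = _fibonacci_sphere(n_pts, seed) * axes
    pts = _project_ellipsoid(pts, axes)
    pts = _relax_on_ellipsoid(pts, axes, target_edge_length)
    hull = ConvexHull(pts)
    faces = hull.simplices.copy()
    # orient all faces outward
    cen = pts.mean(axis=0)
    a, b, c = pts[faces[:, 0]], pts[faces[:, 1]], pts[faces[:, 2]]
    n = np.cross(b - a, c - a)
    flip = np.einsum("ij,ij->i", n, (a + b + c) / 3.0 - cen) < 0
    faces[flip] = faces[flip][:, ::-1]
    return TriSurface(pts, faces)


def _polygon_cap_mesh(footprint, height, target_edge_length, seed):
    from shapely.geometry import Point, Polygon

    poly = Polygon(footprint)
    if not poly.is_valid or poly.area <= 0:
        raise InvalidParameterError("footprint polygon is degenerate")
    h = target_edge_length
    # boundary points at spacing ~h
    ring = poly.exterior
    n_b = max(int(np.ceil(ring.length / h)), 8)
    tvals = np.linspace(0, ring.length, n_b, endpoint=False)
    bpts = np.array([ring.interpolate(t).coords[0] for t in tvals])
    # interior points on a staggered (hex) grid
    minx, miny, maxx, maxy = poly.bounds
    xs = np.arange(minx, maxx + h, h)
    ys = np.arange(miny, maxy + h * np.sqrt(3) / 2, h * np.sqrt(3) / 2)
    gx, gy = np.meshgrid(xs, ys)
    gx[1::2] += h / 2.0
    cand = np.stack([gx.ravel(), gy.ravel()], axis=1)
    inner = poly.buffer(-0.6 * h)
    if not inner.is_empty:
        keep = np.array([inner.contains(Point(p)) for p in cand])
        ipts = cand[keep]
    else:
        ipts = np.empty((0, 2))
    pts2 = np.vstack([bpts, ipts])
    n_bnd = len(bpts)
    # spring relaxation with fixed boundary
    for _ in range(60):
        tri = Delaunay(pts2)
        simps = tri.simplices
        cen = pts2[simps].mean(axis=1)
        keep = np.array([poly.contains(Point(p)) for p in cen])
        simps = simps[keep]
        edges = np.unique(
            np.sort(
                np.concatenate([simps[:, [0, 1]], simps[:, [1, 2]], simps[:, [2, 0]]]),
                axis=1,
            ),
            axis=0,
        )
        d = pts2[edges[:, 1]] - pts2[edges[:, 0]]
        L = np.linalg.norm(d, axis=1, keepdims=True)
        Fmag = np.maximum(1.2 * h - L, 0.0)
        Fvec = Fmag * d / np.where(L > 0, L, 1.0)
        force = np.zeros_like(pts2)
        np.add.at(force, edges[:, 0], -Fvec)
        np.add.at(force, edges[:, 1], Fvec)
        force[:n_bnd] = 0.0
        pts2 = pts2 + 0.2 * force
    tri = Delaunay(pts2)
    simps = tri.simplices
    cen = pts2[simps].mean(axis=1)
    keep = np.array([poly.contains(Point(p)) for p in cen])
    simps = simps[keep].copy()
    # CCW in xy -> upward normal (outward for the volume below the cap)
    a, b, c = pts2[simps[:, 0]], pts2[simps[:, 1]], pts2[simps[:, 2]]
    cr = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (
        c[:, 0] - a[:, 0]
    )
    simps[cr < 0] = simps[cr < 0][:, ::-1]
    # lift by normalized distance to the boundary (parabolic cap profile)
    dist = np.array([ring.distance(Point(p)) for p in pts2])
    dmax = dist.max()
    if height > 0 and dmax > 0:
        t = dist / dmax
        z = height * t * (2.0 - t)
    else:
        z = np.zeros(len(pts2))
    verts = np.column_stack([pts2, z])
    fixed = np.zeros(len(verts), dtype=bool)
    fixed[:n_bnd] = True
    surf = TriSurface(verts, simps, fixed)
    return flip_edges(surf)


def make_initial_mesh(shape_spec: dict, target_edge_length: float, seed: int = 0) -> TriSurface:
    """Generate a near-equilateral initial mesh (DISTMESH-style).

    ``shape_spec`` is a dict with a ``kind`` key:

    - ``{"kind": "sphere", "radius": r}``
    - ``{"kind": "ellipsoid", "semiaxes": (a, b, c)}``
    - ``{"kind": "capped_footprint", "footprint": (M, 2) polygon or
      {"radius": r}, "height": h}`` — a cap over the adhesion footprint;
      boundary vertices are pinned (``fixed_mask``) at z = 0.

    The point layout is seeded and deterministic for a given ``seed``.
    """
    if target_edge_length <= 0:
        raise InvalidParameterError("target_edge_length must be positive")
    kind = shape_spec.get("kind")
    if kind == "sphere":
        r = float(shape_spec.get("radius", 0.0))
        if r <= 0:
            raise InvalidParameterError("sphere radius must be positive")
        return _ellipsoid_mesh((r, r, r), target_edge_length, seed)
    if kind == "ellipsoid":
        return _ellipsoid_mesh(shape_spec["semiaxes"], target_edge_length, seed)
    if kind == "capped_footprint":
        fp = shape_spec.get("footprint")
        if isinstance(fp, dict):
            r = float(fp.get("radius", 0.0))
            if r <= 0:
                raise InvalidParameterError("footprint radius must be positive")
            th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
            fp = np.column_stack([r * np.cos(th), r * np.sin(th)])
        fp = np.asarray(fp, dtype=float)
        height = float(shape_spec.get("height", 0.0))
        return _polygon_cap_mesh(fp, height, target_edge_length, seed)
    raise InvalidParameterError(f"unknown shape kind: {kind!r}")


# ---------------------------------------------------------------------------
# I/O (ASCII OFF / PLY via trimesh)
# ---------------------------------------------------------------------------


def save_mesh(s: TriSurface, path: str) -> None:
    """Write to ASCII OFF or PLY (by extension).  Vertices in µm.

    The ``fixed_mask`` is not stored; for boundary-fixed caps it is
    recovered on load from the boundary edges."""
    import trimesh

    m = trimesh.Trimesh(vertices=s.vertices, faces=s.faces, process=False)
    path = str(path)
    if path.endswith(".off"):
        data = m.export(file_type="off")
    elif path.endswith(".ply"):
        data = m.export(file_type="ply", encoding="ascii")
    else:
        raise InvalidParameterError("mesh path must end in .off or .ply")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def load_mesh(path: str, restore_fixed_boundary: bool = True) -> TriSurface:
    import trimesh

    m = trimesh.load(str(path), process=False, force="mesh")
    s = TriSurface(np.asarray(m.vertices, dtype=float), np.asarray(m.faces))
    if restore_fixed_boundary and not s.is_closed():
        fixed = np.zeros(s.n_vertices, dtype=bool)
        fixed[s.boundary_vertices()] = True
        s = replace(s, fixed_mask=fixed)
    return s
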