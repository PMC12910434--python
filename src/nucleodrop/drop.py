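"""Constrained surface-energy minimization: the nuclear drop model.

The nucleus is treated as a drop bounded by an inextensible lamina: its
volume and surface area are fixed while the cell cortex — a minimal-area cap
pinned at the adhesion perimeter — confines it from above and the substrate
plane z = 0 from below.  Equilibrium shapes minimize

    E_tot = E_cell + E_nuc
          + γ (A_nuc/A_nuc0 - 1)²
          + β_nuc (V_nuc/V_nuc0 - 1)²
          + β_cell (V_cell/V_cell0 - 1)²

where E_cell is the (normalized) cortex surface area plus a small
centroidal-Voronoi mesh-quality regularizer and E_nuc is the CVT regularizer
alone (the lamina area is constrained, not minimized).  The stiffnesses γ,
β_nuc, β_cell are raised stage by stage until the three relative residuals
fall below the convergence tolerance (10⁻³ by default).

Contact (nucleus–cortex, substrate, rigid micropost) is handled by
closest-point projection applied between quasi-Newton descent sweeps; edge
flips keep the tessellations locally Delaunay as vertices move.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .errors import (
    ContractViolationError,
    InfeasibleConfigurationError,
    InvalidParameterError,
)
from .mesh import (
    TriSurface,
    cvt_energy_grad,
    face_normals_raw,
    flip_edges,
    surface_area_grad,
    volume_zflux_grad,
)

__all__ = [
    "DropConfig",
    "Obstacle",
    "SolveResult",
    "sphere_area_for_volume",
    "excess_area_percent",
    "wall_shear_stress",
    "total_energy",
    "solve_equilibrium",
    "enforce_no_overlap",
    "indent_with_post",
]


def sphere_area_for_volume(volume: float) -> float:
    """Surface area of the sphere with the given volume (µm² from µm³)."""
    if volume <= 0:
        raise InvalidParameterError("volume must be positive")
    r = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    return 4.0 * np.pi * r * r


def excess_area_percent(A: float, V: float) -> float:
    """Percent surface area in excess of the equal-volume sphere.

    100 (A / A_sphere(V) - 1); negative values indicate sub-spherical input
    (impossible for a real closed surface) and are returned as-is so callers
    can flag them.
    """
    if A <= 0 or V <= 0:
        raise InvalidParameterError("A and V must be positive")
    return 100.0 * (A / sphere_area_for_volume(V) - 1.0)


def wall_shear_stress(Q: float, eta: float, w: float, h: float) -> float:
    """Wall shear stress τ = 6 Q η / (w h²) in a shallow rectangular channel.

    Parameters
    ----------
    Q : flow rate, µL/min
    eta : dynamic viscosity, mPa·s
    w, h : channel width and height, µm

    Returns
    -------
    τ in dyne/cm².
    """
    if Q < 0 or eta <= 0 or w <= 0 or h <= 0:
        raise InvalidParameterError("channel dimensions and viscosity must be positive")
    Q_si = Q * 1e-9 / 60.0  # m³/s
    eta_si = eta * 1e-3  # Pa·s
    w_si, h_si = w * 1e-6, h * 1e-6  # m
    tau_pa = 6.0 * Q_si * eta_si / (w_si * h_si * h_si)
    return tau_pa * 10.0  # 1 Pa = 10 dyne/cm²


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _default_schedule() -> np.ndarray:
    return np.logspace(2, 8, 7)


@dataclass
class Obstacle:
    """A rigid vertical micropost (cylinder standing on the substrate).

    ``approach_path`` is the sequence of (x, y) center positions the post is
    stepped through, quasi-statically; each step must be no longer than one
    mean nuclear edge length so contact stays near-equilibrium.
    """

    center_xy: Sequence[float]
    radius: float
    height: float
    approach_path: Optional[np.ndarray] = None
    kind: str = "cylinder"

    def __post_init__(self) -> None:
        if self.kind != "cylinder":
            raise InvalidParameterError("only cylindrical obstacles are supported")
        if self.radius <= 0 or self.height <= 0:
            raise InvalidParameterError("obstacle radius and height must be positive")
        self.center_xy = np.asarray(self.center_xy, dtype=float)
        if self.approach_path is not None:
            self.approach_path = np.asarray(self.approach_path, dtype=float)


@dataclass
class DropConfig:
    """Targets, penalty schedule and environment for the drop solver.

    Volumes in µm³, areas in µm².  ``V_cell0`` may be None for a free
    (cell-less) nucleus.  ``substrate`` switches the z ≥ 0 half-space
    constraint (the coverslip).  The three stiffness schedules must be
    positive, strictly increasing, and of equal length.
    """

    V_nuc0: float
    A_nuc0: float
    V_cell0: Optional[float] = None
    gamma_schedule: np.ndarray = field(default_factory=_default_schedule)
    beta_nuc_schedule: np.ndarray = field(default_factory=_default_schedule)
    beta_cell_schedule: np.ndarray = field(default_factory=_default_schedule)
    residual_tol: float = 1e-3
    footprint: Optional[np.ndarray] = None  # (M, 2) closed polygon, µm
    substrate: bool = True
    cvt_weight: float = 0.02
    obstacles: List[Obstacle] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gamma_schedule = np.asarray(self.gamma_schedule, dtype=float)
        self.beta_nuc_schedule = np.asarray(self.beta_nuc_schedule, dtype=float)
        self.beta_cell_schedule = np.asarray(self.beta_cell_schedule, dtype=float)
        if self.V_nuc0 <= 0:
            raise InvalidParameterError("V_nuc0 must be positive")
        if self.V_cell0 is not None and self.V_cell0 <= self.V_nuc0:
            raise InvalidParameterError("V_cell0 must exceed V_nuc0")
        if self.A_nuc0 < sphere_area_for_volume(self.V_nuc0) * (1.0 - 1e-9):
            raise InvalidParameterError(
                "A_nuc0 below the isoperimetric minimum for V_nuc0"
            )
        if self.residual_tol <= 0:
            raise InvalidParameterError("residual_tol must be positive")
        for sched in (
            self.gamma_schedule,
            self.beta_nuc_schedule,
            self.beta_cell_schedule,
        ):
            if len(sched) == 0 or np.any(sched <= 0) or np.any(np.diff(sched) <= 0):
                raise InvalidParameterError(
                    "stiffness schedules must be positive and strictly increasing"
                )
        n = len(self.gamma_schedule)
        if len(self.beta_nuc_schedule) != n or len(self.beta_cell_schedule) != n:
            raise InvalidParameterError("stiffness schedules must share one length")
        if self.footprint is not None:
            self.footprint = np.asarray(self.footprint, dtype=float)

    @classmethod
    def from_excess_area(cls, V_nuc0: float, excess_pct: float, **kwargs) -> "DropConfig":
        """Parameterize the lamina area as percent excess over the
        equal-volume sphere (the drop model's primary shape parameter)."""
        if excess_pct < 0:
            raise InvalidParameterError("excess_pct must be >= 0")
        A = sphere_area_for_volume(V_nuc0) * (1.0 + excess_pct / 100.0)
        return cls(V_nuc0=V_nuc0, A_nuc0=A, **kwargs)

    @property
    def n_stages(self) -> int:
        return len(self.gamma_schedule)


@dataclass
class SolveResult:
    """Converged (or stalled) equilibrium state with diagnostics."""

    cell: Optional[TriSurface]
    nucleus: TriSurface
    residuals: dict  # V_nuc, A_nuc, V_cell relative residuals
    total_energy: float
    converged: bool
    outer_iterations: int
    energy_history: list = field(default_factory=list, repr=False)
    seed: int = 0


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------


def _energy_terms(cell, nucleus, cfg, gamma, beta_nuc, beta_cell, want_grad=True):
    """E_tot plus gradients w.r.t. cell and nucleus vertices."""
    A0 = cfg.A_nuc0
    An, gAn = surface_area_grad(nucleus.vertices, nucleus.faces)
    Vn, gVn = volume_zflux_grad(nucleus.vertices, nucleus.faces)
    Cn, gCn = cvt_energy_grad(nucleus.vertices, nucleus.faces, want_grad)

    w_nuc = cfg.cvt_weight * nucleus.n_faces / (A0 * A0)
    E = w_nuc * Cn
    E += gamma * (An / A0 - 1.0) ** 2
    E += beta_nuc * (Vn / cfg.V_nuc0 - 1.0) ** 2
    g_nuc = None
    if want_grad:
        g_nuc = w_nuc * gCn
        g_nuc += (2.0 * gamma * (An / A0 - 1.0) / A0) * gAn
        g_nuc += (2.0 * beta_nuc * (Vn / cfg.V_nuc0 - 1.0) / cfg.V_nuc0) * gVn

    g_cell = None
    Ac = Vc = None
    if cell is not None:
        Ac, gAc = surface_area_grad(cell.vertices, cell.faces)
        Vc, gVc = volume_zflux_grad(cell.vertices, cell.faces)
        Cc, gCc = cvt_energy_grad(cell.vertices, cell.faces, want_grad)
        w_cell = cfg.cvt_weight * cell.n_faces / (A0 * A0)
        E += Ac / A0 + w_cell * Cc
        E += beta_cell * (Vc / cfg.V_cell0 - 1.0) ** 2
        if want_grad:
            g_cell = gAc / A0 + w_cell * gCc
            g_cell += (2.0 * beta_cell * (Vc / cfg.V_cell0 - 1.0) / cfg.V_cell0) * gVc
    return float(E), g_cell, g_nuc, dict(A_nuc=An, V_nuc=Vn, A_cell=Ac, V_cell=Vc)


def total_energy(
    cell: Optional[TriSurface],
    nucleus: TriSurface,
    cfg: DropConfig,
    stiffness_index: int,
) -> float:
    """Evaluate E_tot at the given stage of the stiffness schedule."""
    if not 0 <= stiffness_index < cfg.n_stages:
        raise InvalidParameterError("stiffness_index out of schedule range")
    E, _, _, _ = _energy_terms(
        cell,
        nucleus,
        cfg,
        cfg.gamma_schedule[stiffness_index],
        cfg.beta_nuc_schedule[stiffness_index],
        cfg.beta_cell_schedule[stiffness_index],
        want_grad=False,
    )
    return E


def residuals_of(cell, nucleus, cfg) -> dict:
    An, _ = surface_area_grad(nucleus.vertices, nucleus.faces)
    Vn, _ = volume_zflux_grad(nucleus.vertices, nucleus.faces)
    res = {
        "V_nuc": abs(Vn / cfg.V_nuc0 - 1.0),
        "A_nuc": abs(An / cfg.A_nuc0 - 1.0),
        "V_cell": 0.0,
    }
    if cell is not None and cfg.V_cell0 is not None:
        Vc, _ = volume_zflux_grad(cell.vertices, cell.faces)
        res["V_cell"] = abs(Vc / cfg.V_cell0 - 1.0)
    return res


# ---------------------------------------------------------------------------
# closest-point machinery (contact)
# ---------------------------------------------------------------------------


def _closest_point_triangles(p, a, b, c):
    """Vectorized closest point on triangle (a, b, c) to point p (Ericson)."""
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    out = np.empty_like(p)
    done = np.zeros(p.shape[:-1], dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        out[m] = value[m]
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)
    assign((d3 >= 0) & (d4 <= d3), b)
    assign((d6 >= 0) & (d5 <= d6), c)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
        assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[..., None] * ab)
        v_ac = d2 / (d2 - d6)
        assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + v_ac[..., None] * ac)
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        assign(
            (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0),
            b + w_bc[..., None] * (c - b),
        )
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
        assign(np.ones_like(done), a + v[..., None] * ab + w[..., None] * ac)
    return out


class MeshProximity:
    """Closest-point queries against a triangle mesh via a centroid KD-tree."""

    def __init__(self, surf: TriSurface, k: int = 12):
        self.surf = surf
        v, f = surf.vertices, surf.faces
        self.tris = (v[f[:, 0]], v[f[:, 1]], v[f[:, 2]])
        self.centroids = (self.tris[0] + self.tris[1] + self.tris[2]) / 3.0
        n = face_normals_raw(surf)
        nn = np.linalg.norm(n, axis=1, keepdims=True)
        self.normals = n / np.where(nn > 0, nn, 1.0)
        self.tree = cKDTree(self.centroids)
        self.k = min(k, len(f))

    def query(self, points: np.ndarray):
        """Return (closest points, outward normals, signed distances).

        The sign uses the normal of the nearest face: positive outside.
        """
        points = np.atleast_2d(points)
        _, idx = self.tree.query(points, k=self.k)
        if self.k == 1:
            idx = idx[:, None]
        a = self.tris[0][idx]
        b = self.tris[1][idx]
        c = self.tris[2][idx]
        p = points[:, None, :]
        q = _closest_point_triangles(np.broadcast_to(p, a.shape).copy(), a, b, c)
        d2 = ((q - p) ** 2).sum(-1)
        best = np.argmin(d2, axis=1)
        rows = np.arange(len(points))
        qbest = q[rows, best]
        fbest = idx[rows, best]
        nrm = self.normals[fbest]
        signed = np.einsum("ij,ij->i", points - qbest, nrm)
        return qbest, nrm, signed


_CONTACT_INSET = 1e-6  # µm


def enforce_no_overlap(cell: Optional[TriSurface], nucleus: TriSurface):
    """Resolve cell/nucleus interpenetration by closest-point projection.

    Nuclear vertices found outside the cell surface are moved to just inside
    it; cell vertices found inside the nucleus are moved to just outside.
    Pinned (fixed_mask) vertices are never moved.  Returns new surfaces.
    """
    if cell is None:
        return cell, nucleus
    cell = cell.copy()
    nucleus = nucleus.copy()
    prox_cell = MeshProximity(cell)
    q, n, signed = prox_cell.query(nucleus.vertices)
    outside = (signed > 0) & ~nucleus.fixed_mask
    if outside.any():
        nucleus.vertices[outside] = q[outside] - _CONTACT_INSET * n[outside]
    prox_nuc = MeshProximity(nucleus)
    q, n, signed = prox_nuc.query(cell.vertices)
    inside = (signed < 0) & ~cell.fixed_mask
    if inside.any():
        cell.vertices[inside] = q[inside] + _CONTACT_INSET * n[inside]
    return cell, nucleus


def _project_out_of_cylinder(surf: TriSurface, obs: Obstacle, center_xy=None):
    """Reflect vertices found inside the post to the nearest point on its
    surface (radial wall or top cap, whichever is closer)."""
    c = np.asarray(center_xy if center_xy is not None else obs.center_xy, float)
    v = surf.vertices
    dx = v[:, 0] - c[0]
    dy = v[:, 1] - c[1]
    rad = np.hypot(dx, dy)
    inside = (rad < obs.radius) & (v[:, 2] < obs.height) & (v[:, 2] >= 0.0)
    inside &= ~surf.fixed_mask
    if not inside.any():
        return surf, 0
    v = v.copy()
    wall = (obs.radius - rad) <= (obs.height - v[:, 2])
    to_wall = inside & wall
    to_top = inside & ~wall
    safe = np.where(rad > 1e-12, rad, 1.0)
    ux = np.where(rad > 1e-12, dx / safe, 1.0)
    uy = np.where(rad > 1e-12, dy / safe, 0.0)
    rnew = obs.radius + _CONTACT_INSET
    v[to_wall, 0] = c[0] + rnew * ux[to_wall]
    v[to_wall, 1] = c[1] + rnew * uy[to_wall]
    v[to_top, 2] = obs.height + _CONTACT_INSET
    out = surf.copy()
    out.vertices = v
    return out, int(inside.sum())


# ---------------------------------------------------------------------------
# descent
# ---------------------------------------------------------------------------


def _descend(cell, nucleus, cfg, stage, maxiter, obstacle_state=None):
    """One L-BFGS-B sweep over the free vertices of both surfaces at a fixed
    stiffness stage.  The substrate constraint z >= 0 enters as a box bound;
    monotone decrease within the sweep is guaranteed by the line search."""
    gamma = cfg.gamma_schedule[stage]
    bnuc = cfg.beta_nuc_schedule[stage]
    bcell = cfg.beta_cell_schedule[stage]

    free_n = ~nucleus.fixed_mask
    n_free_n = int(free_n.sum())
    if cell is not None:
        free_c = ~cell.fixed_mask
        n_free_c = int(free_c.sum())
    else:
        free_c, n_free_c = None, 0

    x0 = np.empty(3 * (n_free_n + n_free_c))
    x0[: 3 * n_free_n] = nucleus.vertices[free_n].ravel()
    if cell is not None:
        x0[3 * n_free_n :] = cell.vertices[free_c].ravel()

    nv = nucleus.vertices.copy()
    cv = cell.vertices.copy() if cell is not None else None
    nuc_work = TriSurface(nv, nucleus.faces, nucleus.fixed_mask)
    cell_work = TriSurface(cv, cell.faces, cell.fixed_mask) if cell is not None else None

    def fun(x):
        nv[free_n] = x[: 3 * n_free_n].reshape(-1, 3)
        if cell is not None:
            cv[free_c] = x[3 * n_free_n :].reshape(-1, 3)
        E, g_cell, g_nuc, _ = _energy_terms(cell_work, nuc_work, cfg, gamma, bnuc, bcell)
        g = np.empty_like(x)
        g[: 3 * n_free_n] = g_nuc[free_n].ravel()
        if cell is not None:
            g[3 * n_free_n :] = g_cell[free_c].ravel()
        return E, g

    bounds = None
    if cfg.substrate:
        lb = np.full_like(x0, -np.inf)
        lb[2::3] = 0.0
        bounds = np.stack([lb, np.full_like(x0, np.inf)], axis=1)

    E0, _ = fun(x0)
    res = minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": maxiter, "maxcor": 12, "ftol": 1e-14, "gtol": 1e-12},
    )
    # leave the work surfaces at the optimizer's final iterate
    nv[free_n] = res.x[: 3 * n_free_n].reshape(-1, 3)
    if cell is not None:
        cv[free_c] = res.x[3 * n_free_n :].reshape(-1, 3)
    return cell_work, nuc_work, float(E0), float(res.fun)


def _repair_degenerate(surf: TriSurface, rel_tol: float = 1e-7) -> TriSurface:
    """Nudge vertices of (near-)zero-area triangles toward their neighbor
    centroid.  Contact projections can occasionally map the three corners of
    a triangle onto a line or point; a small umbrella step restores
    positivity without visibly moving the surface."""
    v, f = surf.vertices, surf.faces
    scale = surf.mean_edge_length() ** 2
    for _ in range(4):
        a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
        areas = 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)
        bad = areas < rel_tol * scale
        if not bad.any():
            return surf
        verts_bad = np.unique(f[bad])
        verts_bad = verts_bad[~surf.fixed_mask[verts_bad]]
        # umbrella (neighbor-mean) pull, 10% strength
        nbr_sum = np.zeros_like(v)
        nbr_cnt = np.zeros(len(v))
        e = surf.undirected_edges()
        np.add.at(nbr_sum, e[:, 0], v[e[:, 1]])
        np.add.at(nbr_sum, e[:, 1], v[e[:, 0]])
        np.add.at(nbr_cnt, e[:, 0], 1.0)
        np.add.at(nbr_cnt, e[:, 1], 1.0)
        v = v.copy()
        mean = nbr_sum[verts_bad] / np.maximum(nbr_cnt[verts_bad], 1.0)[:, None]
        v[verts_bad] += 0.1 * (mean - v[verts_bad])
        surf = TriSurface(v, f, surf.fixed_mask)
    return surf


def _apply_constraints(cell, nucleus, cfg, obstacle=None, obstacle_center=None):
    """Post-sweep projections; returns surfaces and max vertex displacement."""
    before_n = nucleus.vertices.copy()
    before_c = cell.vertices.copy() if cell is not None else None
    if cfg.substrate:
        nucleus = nucleus.copy()
        nucleus.vertices[:, 2] = np.maximum(nucleus.vertices[:, 2], 0.0)
        if cell is not None:
            cell = cell.copy()
            free = ~cell.fixed_mask
            cell.vertices[free, 2] = np.maximum(cell.vertices[free, 2], 0.0)
    if obstacle is not None:
        nucleus, _ = _project_out_of_cylinder(nucleus, obstacle, obstacle_center)
        if cell is not None:
            cell, _ = _project_out_of_cylinder(cell, obstacle, obstacle_center)
    for obs in cfg.obstacles:
        nucleus, _ = _project_out_of_cylinder(nucleus, obs)
        if cell is not None:
            cell, _ = _project_out_of_cylinder(cell, obs)
    if cell is not None:
        cell, nucleus = enforce_no_overlap(cell, nucleus)
    disp = np.linalg.norm(nucleus.vertices - before_n, axis=1).max()
    if cell is not None:
        disp = max(disp, np.linalg.norm(cell.vertices - before_c, axis=1).max())
    return cell, nucleus, float(disp)


def solve_equilibrium(
    cfg: DropConfig,
    init_cell: Optional[TriSurface],
    init_nucleus: TriSurface,
    seed: int = 0,
    *,
    stage_sweeps: int = 8,
    inner_maxiter: int = 120,
    first_stage: int = 0,
    obstacle=None,
    obstacle_center=None,
    proj_tol: float = 2e-4,
) -> SolveResult:
    """Relax cell and nucleus to the constrained-equilibrium shape.

    The outer loop walks the stiffness schedule; each stage alternates
    quasi-Newton descent sweeps (monotone in E_tot) with edge flips and
    contact projections until projections become quiescent.  ``converged``
    is True iff all three relative residuals are below ``cfg.residual_tol``.
    A stalled solve returns ``converged=False`` with diagnostics rather than
    raising.
    """
    init_nucleus.validate()
    if not init_nucleus.is_closed():
        raise ContractViolationError("nucleus surface must be closed")
    if init_cell is not None:
        init_cell.validate()
        if cfg.V_cell0 is None:
            raise InvalidParameterError("V_cell0 required when a cell is present")
    cell = init_cell.copy() if init_cell is not None else None
    nucleus = init_nucleus.copy()
    energy_history = []
    outer = 0
    for stage in range(first_stage, cfg.n_stages):
        prev_E = None
        for sweep in range(stage_sweeps):
            outer += 1
            cell, nucleus, E_start, E_end = _descend(
                cell, nucleus, cfg, stage, inner_maxiter
            )
            nucleus = flip_edges(nucleus)
            if cell is not None:
                cell = flip_edges(cell)
            cell, nucleus, disp = _apply_constraints(
                cell, nucleus, cfg, obstacle, obstacle_center
            )
            nucleus = _repair_degenerate(nucleus)
            if cell is not None:
                cell = _repair_degenerate(cell)
            energy_history.append(
                {"stage": stage, "sweep": sweep, "E_start": E_start, "E_end": E_end}
            )
            # a stage is done once projections are quiescent and descent has
            # stopped making progress
            settled = disp < proj_tol
            stalled = prev_E is not None and abs(prev_E - E_end) < 1e-9 * max(
                1.0, abs(E_end)
            )
            if settled and stalled:
                break
            prev_E = E_end
    res = residuals_of(cell, nucleus, cfg)
    converged = all(v < cfg.residual_tol for v in res.values())
    E_final = total_energy(cell, nucleus, cfg, cfg.n_stages - 1)
    return SolveResult(
        cell=cell,
        nucleus=nucleus,
        residuals=res,
        total_energy=E_final,
        converged=converged,
        outer_iterations=outer,
        energy_history=energy_history,
        seed=seed,
    )


def indent_with_post(
    result: SolveResult,
    obstacle: Obstacle,
    cfg: DropConfig,
    *,
    step_sweeps: int = 4,
    inner_maxiter: int = 100,
    final_sweeps: int = 8,
    reanneal: bool = True,
) -> SolveResult:
    """Quasi-static micropost indentation (and withdrawal, if the path
    returns).

    The post center is stepped along ``obstacle.approach_path``; at each
    position vertices caught inside the cylinder are reflected to its
    surface and the equilibrium continued at the stiffest schedule stage.
    After the last path position the state is re-equilibrated through the
    second half of the stiffness schedule (``reanneal``) — stepping is done
    at full stiffness for constraint fidelity, but the quasi-static premise
    is full equilibration, and softening lets mesh-scale contact scars relax.
    The returned state has no vertex inside the post and reports the final
    residuals.
    """
    if obstacle.approach_path is None or len(obstacle.approach_path) == 0:
        raise InvalidParameterError("obstacle.approach_path is required")
    if cfg.V_cell0 is not None:
        cyl_volume = np.pi * obstacle.radius**2 * obstacle.height
        if cyl_volume >= cfg.V_cell0 - cfg.V_nuc0:
            raise InfeasibleConfigurationError(
                "post displaces more volume than the cytoplasm can absorb"
            )
    mean_edge = result.nucleus.mean_edge_length()
    steps = np.asarray(obstacle.approach_path, dtype=float)
    if len(steps) > 1:
        seg = np.linalg.norm(np.diff(steps, axis=0), axis=1)
        if seg.max() > mean_edge * (1.0 + 1e-9):
            raise InvalidParameterError(
                "approach path step exceeds one mean nuclear edge length"
            )
    state = result
    last = cfg.n_stages - 1
    residual_trace = []
    for i, center in enumerate(steps):
        sweeps = final_sweeps if i == len(steps) - 1 else step_sweeps
        state = solve_equilibrium(
            cfg,
            state.cell,
            state.nucleus,
            seed=result.seed,
            stage_sweeps=sweeps,
            inner_maxiter=inner_maxiter,
            first_stage=last,
            obstacle=obstacle,
            obstacle_center=center,
        )
        residual_trace.append(dict(state.residuals))
    if reanneal:
        state = solve_equilibrium(
            cfg,
            state.cell,
            state.nucleus,
            seed=result.seed,
            stage_sweeps=2 * step_sweeps,
            inner_maxiter=2 * inner_maxiter,
            first_stage=cfg.n_stages // 2,
            obstacle=obstacle,
            obstacle_center=steps[-1],
        )
        residual_trace.append(dict(state.residuals))
    state.energy_history.append({"residual_trace": residual_trace})
    return state
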