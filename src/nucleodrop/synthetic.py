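"""Synthetic ground-truth generators.

Everything the measurement pipeline consumes can be produced here with known
truth: wrinkled or taut nuclear surfaces at prescribed volume and excess
area, voxelized confocal-like renders (anisotropic voxels, Gaussian PSF,
Poisson-Gaussian noise), monolayer fields with a controllable fraction of
tall cells, YAP scenes with known nuclear/cytoplasmic contrast, focal-
adhesion spot fields, and detachment time series.

All generators are deterministic given their seed and return the ground
truth alongside the artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from scipy.special import sph_harm_y

from .drop import excess_area_percent
from .errors import InfeasibleConfigurationError, InvalidParameterError
from .images import DEFAULT_DZ, ImageStack
from .mesh import TriSurface, enclosed_volume, make_initial_mesh, surface_area

__all__ = [
    "NucleusSpec",
    "RenderSpec",
    "make_nucleus_surface",
    "render_stack",
    "make_monolayer",
    "make_yap_scene",
    "make_fa_field",
    "make_detachment_series",
]


# ---------------------------------------------------------------------------
# wrinkled nuclear surfaces
# ---------------------------------------------------------------------------


@dataclass
class NucleusSpec:
    """Target geometry of a synthetic nucleus.

    Wrinkles are band-limited radial spherical-harmonic perturbations of a
    sphere (degrees ``wrinkle_orders``); the amplitude is tuned by bisection
    so the measured excess area matches ``excess_area_pct``.
    """

    volume: float = 800.0  # µm³
    excess_area_pct: float = 37.0
    wrinkle_orders: Sequence[int] = (4, 5, 6, 7, 8)
    seed: int = 0
    mesh_edge: float = 0.2  # relative to unit sphere radius

    def __post_init__(self) -> None:
        if self.volume <= 0 or self.excess_area_pct < 0:
            raise InvalidParameterError("volume > 0 and excess >= 0 required")


@dataclass
class RenderSpec:
    """Confocal-like rendering parameters (µm, photon counts)."""

    voxel_size: Tuple[float, float, float] = (0.1, 0.1, DEFAULT_DZ)
    psf_sigma: float = 0.2  # µm, isotropic Gaussian
    signal_level: float = 100.0  # mean photons at full signal (SNR ~ sqrt)
    read_noise_sd: float = 2.0  # Gaussian read noise, a.u.
    background_level: float = 10.0
    shell_thickness: float = 0.25  # µm, lamina shell width
    margin: float = 1.5  # µm of empty border around the object
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise InvalidParameterError("voxel sizes must be positive")


def _real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * y.real
    if m < 0:
        return np.sqrt(2.0) * y.imag
    return y.real


def _draw_wrinkle_coeffs(spec: NucleusSpec, rng) -> dict:
    return {
        l: np.array([rng.normal() for _ in range(2 * l + 1)])
        for l in spec.wrinkle_orders
    }


def _eval_wrinkle_field(coeffs: dict, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    total = np.zeros_like(theta)
    for l, cs in coeffs.items():
        for j, m in enumerate(range(-l, l + 1)):
            total += cs[j] * _real_sph_harm(l, m, theta, phi)
    return total


def star_radius(truth: dict, directions: np.ndarray) -> np.ndarray:
    """Surface radius of a generated (star-shaped) nucleus along unit
    ``directions`` from its center — the exact interior test used when
    rasterizing solid renders."""
    d = np.asarray(directions, dtype=float)
    theta = np.arccos(np.clip(d[:, 2], -1, 1))
    phi = np.arctan2(d[:, 1], d[:, 0])
    f = _eval_wrinkle_field(truth["coeffs"], theta, phi) / truth["field_rms"]
    return truth["scale"] * (1.0 + truth["amplitude_rel"] * f)


def make_nucleus_surface(spec: NucleusSpec):
    """Build a wrinkled closed surface with prescribed volume and excess
    area.

    Returns ``(surface, truth)`` where truth holds the exact mesh-measured
    volume and area plus the radial-field parameters (the surface is
    star-shaped, which the renderer exploits).
    """
    base = make_initial_mesh({"kind": "sphere", "radius": 1.0}, spec.mesh_edge, seed=spec.seed)
    v = base.vertices
    r0 = np.linalg.norm(v, axis=1)
    theta = np.arccos(np.clip(v[:, 2] / r0, -1, 1))
    phi = np.arctan2(v[:, 1], v[:, 0])
    rng = np.random.default_rng(spec.seed)
    coeffs = _draw_wrinkle_coeffs(spec, rng)
    f = _eval_wrinkle_field(coeffs, theta, phi)
    field_rms = max(np.sqrt((f**2).mean()), 1e-300)
    f = f / field_rms

    def build(amp: float) -> TriSurface:
        vv = v / r0[:, None] * (1.0 + amp * f)[:, None]
        return TriSurface(vv, base.faces.copy())

    def excess_of(amp: float) -> float:
        s = build(amp)
        return excess_area_percent(surface_area(s), enclosed_volume(s))

    # the deepest trough must stay well away from the center
    amp_max = 0.9 / max(-f.min(), 1e-9)
    target = spec.excess_area_pct
    base_excess = excess_of(0.0)  # discretization offset of the sphere mesh
    if target <= base_excess + 1e-9:
        amp = 0.0
    else:
        if excess_of(amp_max) < target:
            raise InfeasibleConfigurationError(
                f"excess area {target}% unreachable with orders {spec.wrinkle_orders}"
            )
        lo, hi = 0.0, amp_max
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            e = excess_of(mid)
            if abs(e - target) < 0.01 * target:
                amp = mid
                break
            if e < target:
                lo = mid
            else:
                hi = mid
        else:
            amp = 0.5 * (lo + hi)

    surf = build(amp)
    scale = (spec.volume / enclosed_volume(surf)) ** (1.0 / 3.0)
    surf = TriSurface(surf.vertices * scale, surf.faces)
    truth = {
        "volume": enclosed_volume(surf),
        "area": surface_area(surf),
        "excess_area_pct": excess_area_percent(surface_area(surf), enclosed_volume(surf)),
        "amplitude": amp * scale,
        "amplitude_rel": amp,
        "scale": scale,
        "coeffs": coeffs,
        "field_rms": field_rms,
        "orders": tuple(spec.wrinkle_orders),
        "seed": spec.seed,
    }
    return surf, truth


# ---------------------------------------------------------------------------
# voxel rendering
# ---------------------------------------------------------------------------


def _sample_surface_points(surf: TriSurface, max_spacing: float) -> np.ndarray:
    """Points covering the surface at spacing <= max_spacing (vertices plus
    recursive face subdivision)."""
    v, f = surf.vertices, surf.faces
    pts = [v]
    tris = v[f]
    for _ in range(6):
        e = np.linalg.norm(np.diff(np.concatenate([tris, tris[:, :1]], axis=1), axis=1), axis=2)
        if e.max() <= max_spacing:
            break
        a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
        ab, bc, ca = 0.5 * (a + b), 0.5 * (b + c), 0.5 * (c + a)
        pts.append(np.concatenate([ab, bc, ca]))
        tris = np.concatenate(
            [
                np.stack([a, ab, ca], axis=1),
                np.stack([ab, b, bc], axis=1),
                np.stack([ca, bc, c], axis=1),
                np.stack([ab, bc, ca], axis=1),
            ]
        )
    return np.concatenate(pts)


def _rasterize_interior(surface: TriSurface, lo, shape, voxel) -> np.ndarray:
    """Exact solid rasterization of a closed mesh by column-parity ray
    casting: for every x-y voxel column, z-crossings with the triangles are
    paired into inside intervals.  Unbiased up to voxel quantization."""
    nz, ny, nx = shape
    dx, dy, dz = voxel
    # tiny irrational shift avoids edge-on-pixel ties in the parity count
    v = surface.vertices + np.array([dx, dy, 0.0]) * 1e-4 * np.sqrt(2)
    f = surface.faces
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    cols: List[np.ndarray] = []
    zs: List[np.ndarray] = []
    xc0, yc0 = lo[0] + 0.5 * dx, lo[1] + 0.5 * dy
    for t in range(len(f)):
        p0, p1, p2 = a[t], b[t], c[t]
        det = (p1[0] - p0[0]) * (p2[1] - p0[1]) - (p2[0] - p0[0]) * (p1[1] - p0[1])
        if abs(det) < 1e-14:
            continue  # vertical triangle: measure-zero crossing
        ix0 = max(int(np.ceil((min(p0[0], p1[0], p2[0]) - xc0) / dx)), 0)
        ix1 = min(int(np.floor((max(p0[0], p1[0], p2[0]) - xc0) / dx)), nx - 1)
        iy0 = max(int(np.ceil((min(p0[1], p1[1], p2[1]) - yc0) / dy)), 0)
        iy1 = min(int(np.floor((max(p0[1], p1[1], p2[1]) - yc0) / dy)), ny - 1)
        if ix1 < ix0 or iy1 < iy0:
            continue
        gx = xc0 + np.arange(ix0, ix1 + 1) * dx
        gy = yc0 + np.arange(iy0, iy1 + 1) * dy
        GX, GY = np.meshgrid(gx, gy, indexing="xy")
        l1 = ((GX - p0[0]) * (p2[1] - p0[1]) - (p2[0] - p0[0]) * (GY - p0[1])) / det
        l2 = ((p1[0] - p0[0]) * (GY - p0[1]) - (GX - p0[0]) * (p1[1] - p0[1])) / det
        inside = (l1 >= 0) & (l2 >= 0) & (l1 + l2 <= 1)
        if not inside.any():
            continue
        zc = p0[2] + l1 * (p1[2] - p0[2]) + l2 * (p2[2] - p0[2])
        II, JJ = np.meshgrid(np.arange(ix0, ix1 + 1), np.arange(iy0, iy1 + 1), indexing="xy")
        cols.append((JJ[inside] * nx + II[inside]).ravel())
        zs.append(zc[inside].ravel())
    out = np.zeros((nz, ny, nx), dtype=bool)
    if not cols:
        return out
    col = np.concatenate(cols)
    zz = np.concatenate(zs)
    order = np.lexsort((zz, col))
    col, zz = col[order], zz[order]
    starts = np.flatnonzero(np.concatenate([[True], col[1:] != col[:-1]]))
    ends = np.concatenate([starts[1:], [len(col)]])
    zc0 = lo[2] + 0.5 * dz
    flat = out.reshape(nz, ny * nx)
    for s, e in zip(starts, ends):
        crossings = zz[s:e]
        n_pairs = len(crossings) // 2
        for k in range(n_pairs):
            z1, z2 = crossings[2 * k], crossings[2 * k + 1]
            i0 = max(int(np.ceil((z1 - zc0) / dz)), 0)
            i1 = min(int(np.floor((z2 - zc0) / dz)), nz - 1)
            if i1 >= i0:
                flat[i0 : i1 + 1, col[s]] = True
    return out


def render_stack(surface: TriSurface, render: RenderSpec, signal: str = "shell"):
    """Voxelize a closed surface into a confocal-like stack.

    ``shell`` paints a thin band around the surface (lamin-like) via a
    splatted-sample distance transform; ``solid`` fills the interior
    (DNA-like) by exact parity rasterization of the mesh.  Returns
    ``(stack, truth)`` with the noiseless masks in truth.
    """
    if signal not in ("shell", "solid"):
        raise InvalidParameterError("signal must be 'shell' or 'solid'")
    dx, dy, dz = render.voxel_size
    v = surface.vertices
    lo = v.min(axis=0) - render.margin
    hi = v.max(axis=0) + render.margin
    nx = int(np.ceil((hi[0] - lo[0]) / dx))
    ny = int(np.ceil((hi[1] - lo[1]) / dy))
    nz = int(np.ceil((hi[2] - lo[2]) / dz))
    if nx * ny * nz > 4e8:
        raise InvalidParameterError("surface exceeds the renderable field")
    # splat surface samples into the grid, then one anisotropic distance
    # transform gives voxel-to-surface distance for the whole field
    samp = _sample_surface_points(surface, max_spacing=0.8 * min(dx, dy, dz))
    iz = np.clip(((samp[:, 2] - lo[2]) / dz).astype(int), 0, nz - 1)
    iy = np.clip(((samp[:, 1] - lo[1]) / dy).astype(int), 0, ny - 1)
    ix = np.clip(((samp[:, 0] - lo[0]) / dx).astype(int), 0, nx - 1)
    occ = np.zeros((nz, ny, nx), dtype=bool)
    occ[iz, iy, ix] = True
    dist = ndi.distance_transform_edt(~occ, sampling=(dz, dy, dx))
    half = max(render.shell_thickness / 2.0, 0.8 * max(dx, dy, dz))
    shell = dist <= half
    solid = _rasterize_interior(surface, lo, (nz, ny, nx), (dx, dy, dz))
    mask = shell if signal == "shell" else solid

    img = render.signal_level * mask.astype(float)
    if render.psf_sigma > 0:
        img = ndi.gaussian_filter(
            img, sigma=(render.psf_sigma / dz, render.psf_sigma / dy, render.psf_sigma / dx)
        )
    img = img + render.background_level
    if not render.noiseless:
        rng = np.random.default_rng(render.seed)
        img = rng.poisson(np.maximum(img, 0)).astype(float)
        img = img + rng.normal(0.0, render.read_noise_sd, size=img.shape)
    stack = ImageStack(img, render.voxel_size, "lamin" if signal == "shell" else "dna")
    truth = {
        "solid_mask": solid,
        "shell_mask": shell,
        "origin": lo,
        "volume": enclosed_volume(surface),
        "area": surface_area(surface),
    }
    return stack, truth


# ---------------------------------------------------------------------------
# monolayers
# ---------------------------------------------------------------------------


def make_monolayer(
    field: Tuple[float, float] = (60.0, 60.0),
    base_height: float = 3.0,
    tall_cell_fraction: float = 0.0,
    tall_height: float = 8.0,
    *,
    cell_diameter: float = 20.0,
    pixel_size: float = 0.4,
    dz: float = 2.0 * DEFAULT_DZ,
    noiseless: bool = False,
    seed: int = 0,
):
    """A confluent monolayer rendered to a two-channel 3D stack.

    Cell footprints come from a seeded Voronoi tessellation of the field;
    a ``tall_cell_fraction`` of cells carries a dome rising to
    ``tall_height``.  Returns ``(stack, truth)``; truth holds the per-pixel
    height grid and the cell label image.
    """
    if not (0.0 <= tall_cell_fraction <= 1.0):
        raise InvalidParameterError("tall_cell_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    W, H = field
    nx, ny = int(W / pixel_size), int(H / pixel_size)
    n_cells = max(int(round(W * H / (np.pi * (cell_diameter / 2) ** 2))), 2)
    seeds = rng.uniform([0, 0], [W, H], size=(n_cells, 2))
    xs = (np.arange(nx) + 0.5) * pixel_size
    ys = (np.arange(ny) + 0.5) * pixel_size
    PX, PY = np.meshgrid(xs, ys, indexing="xy")
    pix = np.stack([PX.ravel(), PY.ravel()], axis=1)
    tree = cKDTree(seeds)
    d, owner = tree.query(pix, k=1)
    owner = owner.reshape(ny, nx)
    d = d.reshape(ny, nx)

    n_tall = int(round(tall_cell_fraction * n_cells))
    tall_ids = rng.choice(n_cells, size=n_tall, replace=False) if n_tall else np.array([], int)
    heights = np.full((ny, nx), base_height)
    for cid in tall_ids:
        m = owner == cid
        if not m.any():
            continue
        r_dome = max(np.sqrt(m.sum() * pixel_size**2 / np.pi), pixel_size)
        prof = np.clip(1.0 - (d / r_dome) ** 2, 0.0, None)
        heights = np.where(m, base_height + (tall_height - base_height) * prof, heights)

    nz = int(np.ceil((heights.max() + 1.0) / dz))
    zc = (np.arange(nz) + 0.5) * dz
    occ = zc[:, None, None] < heights[None, :, :]
    actin = 100.0 * occ.astype(float)
    vecad = 60.0 * occ.astype(float)
    stack4 = np.stack([actin, vecad])
    stack4 = ndi.gaussian_filter(stack4, sigma=(0, 0.5, 1.0, 1.0))
    stack4 += 5.0
    if not noiseless:
        stack4 = rng.poisson(np.maximum(stack4, 0)).astype(float)
        stack4 += rng.normal(0, 1.0, size=stack4.shape)
    stack = ImageStack(stack4, (pixel_size, pixel_size, dz), "multi")
    truth = {
        "height_grid": heights,
        "labels": owner + 1,
        "tall_ids": tall_ids + 1,
        "seeds": seeds,
        "n_cells": n_cells,
    }
    return stack, truth


# ---------------------------------------------------------------------------
# YAP scenes
# ---------------------------------------------------------------------------


def make_yap_scene(
    n_cells: int,
    nc_ratios: Sequence[float],
    noise: float = 0.0,
    *,
    cell_diameter: float = 30.0,
    nucleus_radius: float = 6.0,
    pixel_size: float = 0.4,
    background: float = 20.0,
    cytoplasm_level: float = 100.0,
    seed: int = 0,
):
    """Cells on a grid with prescribed nuclear/cytoplasmic YAP contrast.

    Nuclear intensity is set to background + ratio x (cytoplasm - background)
    so the measured background-subtracted N/C equals the request exactly in
    the noiseless limit.  Returns ``(yap image, masks dict, truth)``.
    """
    nc_ratios = np.asarray(nc_ratios, dtype=float)
    if np.any(nc_ratios <= 0):
        raise InvalidParameterError("nc_ratios must be positive")
    if len(nc_ratios) != n_cells:
        raise InvalidParameterError("one ratio per cell required")
    rng = np.random.default_rng(seed)
    ncol = int(np.ceil(np.sqrt(n_cells)))
    nrow = int(np.ceil(n_cells / ncol))
    W, H = ncol * cell_diameter, nrow * cell_diameter
    nx, ny = int(W / pixel_size), int(H / pixel_size)
    img = np.full((ny, nx), background, dtype=float)
    nuc_labels = np.zeros((ny, nx), dtype=np.int32)
    cell_labels = np.zeros((ny, nx), dtype=np.int32)
    xs = (np.arange(nx) + 0.5) * pixel_size
    ys = (np.arange(ny) + 0.5) * pixel_size
    PX, PY = np.meshgrid(xs, ys, indexing="xy")
    margin = 0.08 * cell_diameter
    for i in range(n_cells):
        r, c = divmod(i, ncol)
        cx = (c + 0.5) * cell_diameter
        cy = (r + 0.5) * cell_diameter
        half = cell_diameter / 2.0 - margin
        cell = (np.abs(PX - cx) < half) & (np.abs(PY - cy) < half)
        nuc = (PX - cx) ** 2 + (PY - cy) ** 2 < nucleus_radius**2
        nuc &= cell
        cell_labels[cell] = i + 1
        nuc_labels[nuc] = i + 1
        nuc_level = background + nc_ratios[i] * (cytoplasm_level - background)
        img[cell] = cytoplasm_level
        img[nuc] = nuc_level
    if noise > 0:
        img = img * (1.0 + rng.normal(0.0, noise, size=img.shape))
    bg_region = cell_labels == 0
    masks = {"nuclei": nuc_labels, "cells": cell_labels, "background": bg_region}
    truth = {"nc_ratios": nc_ratios.copy(), "background": background}
    return ImageStack(img, (pixel_size, pixel_size, DEFAULT_DZ), "yap"), masks, truth


# ---------------------------------------------------------------------------
# focal-adhesion spot fields
# ---------------------------------------------------------------------------


def make_fa_field(
    n_spots: int = 20,
    spot_area: float = 2.0,
    *,
    field: Tuple[float, float] = (40.0, 25.0),
    pixel_size: float = 0.1,
    aspect: float = 2.5,
    intensity: float = 100.0,
    background: float = 5.0,
    seed: int = 0,
):
    """Non-overlapping elliptical vinculin-like spots of known area.

    Returns ``(image, truth)``; truth holds spot centers and the count.
    """
    rng = np.random.default_rng(seed)
    W, H = field
    nx, ny = int(W / pixel_size), int(H / pixel_size)
    img = np.full((ny, nx), background, dtype=float)
    b_ax = np.sqrt(spot_area / (np.pi * aspect))
    a_ax = aspect * b_ax
    xs = (np.arange(nx) + 0.5) * pixel_size
    ys = (np.arange(ny) + 0.5) * pixel_size
    PX, PY = np.meshgrid(xs, ys, indexing="xy")
    centers = []
    guard = a_ax + 1.0
    attempts = 0
    while len(centers) < n_spots and attempts < 10000:
        attempts += 1
        p = rng.uniform([guard, guard], [W - guard, H - guard])
        if all(np.hypot(*(p - q)) > 2.5 * a_ax for q in centers):
            centers.append(p)
    if len(centers) < n_spots:
        raise InfeasibleConfigurationError("field too small for requested spots")
    for cx, cy in centers:
        ang = rng.uniform(0, np.pi)
        ca, sa = np.cos(ang), np.sin(ang)
        u = (PX - cx) * ca + (PY - cy) * sa
        w = -(PX - cx) * sa + (PY - cy) * ca
        img[(u / a_ax) ** 2 + (w / b_ax) ** 2 <= 1.0] = intensity
    stack = ImageStack(img, (pixel_size, pixel_size, DEFAULT_DZ), "vinculin")
    return stack, {"count": len(centers), "centers": np.array(centers), "spot_area": spot_area}


# ---------------------------------------------------------------------------
# detachment time series
# ---------------------------------------------------------------------------


def make_detachment_series(
    n_frames: int = 12,
    detach_frame: Optional[int] = 8,
    *,
    field: Tuple[float, float] = (60.0, 60.0),
    pixel_size: float = 0.5,
    n_cells: int = 9,
    seed: int = 0,
):
    """Label-mask time series in which one cell shrinks monotonically and
    vanishes at ``detach_frame`` (None: nothing detaches); neighbors take
    over the vacated area.

    Returns ``(list of label frames, truth)``; truth flags the detaching
    label.
    """
    if detach_frame is not None and not (0 < detach_frame < n_frames):
        raise InvalidParameterError("need 0 < detach_frame < n_frames")
    rng = np.random.default_rng(seed)
    W, H = field
    nx, ny = int(W / pixel_size), int(H / pixel_size)
    side = int(np.ceil(np.sqrt(n_cells)))
    gx, gy = np.meshgrid(
        (np.arange(side) + 0.5) * W / side, (np.arange(side) + 0.5) * H / side
    )
    seeds = np.stack([gx.ravel(), gy.ravel()], axis=1)[:n_cells]
    seeds += rng.uniform(-0.1, 0.1, seeds.shape) * min(W, H) / side
    xs = (np.arange(nx) + 0.5) * pixel_size
    ys = (np.arange(ny) + 0.5) * pixel_size
    PX, PY = np.meshgrid(xs, ys, indexing="xy")
    pix = np.stack([PX.ravel(), PY.ravel()], axis=1)
    owner = cKDTree(seeds).query(pix, k=1)[1].reshape(ny, nx) + 1

    if detach_frame is None:
        frames = [owner.copy() for _ in range(n_frames)]
        return frames, {"detach_label": None, "detach_frame": None}
    # pick the most central cell as the one that detaches
    center = np.array([W / 2, H / 2])
    detach_label = int(np.argmin(np.linalg.norm(seeds - center, axis=1))) + 1
    base_mask = owner == detach_label
    # how many erosion iterations kill the cell
    m = base_mask.copy()
    n_iter = 0
    while m.any():
        m = ndi.binary_erosion(m)
        n_iter += 1
    frames = []
    others = cKDTree(np.delete(seeds, detach_label - 1, axis=0))
    other_ids = np.delete(np.arange(1, len(seeds) + 1), detach_label - 1)
    for t in range(n_frames):
        if t >= detach_frame:
            shrunk = np.zeros_like(base_mask)
        else:
            k = int(round(n_iter * t / detach_frame))
            shrunk = (
                ndi.binary_erosion(base_mask, iterations=k) if k > 0 else base_mask
            )
        frame = owner.copy()
        vacated = base_mask & ~shrunk
        if vacated.any():
            idx = others.query(pix[vacated.ravel()], k=1)[1]
            frame[vacated] = other_ids[idx]
        frame[shrunk] = detach_label
        frames.append(frame)
    truth = {"detach_label": detach_label, "detach_frame": detach_frame}
    return frames, truth
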