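"""Morphometric image analysis for endothelial monolayers.

Implements the quantification pipeline used to characterize nuclear
wrinkling and monolayer topography from confocal z-stacks:

- bulk nuclear segmentation (Otsu on the lamin max-projection) with edge and
  overlap exclusion;
- sub-pixel lamina tracing (intensity maximum along contour normals);
- elliptical Fourier analysis of nuclear contours (15 harmonics) and the
  EFC ratio — (major+minor semiaxes of harmonic 1) over the summed semiaxes
  of harmonics 2..15; higher values mean smoother contours;
- nuclear height (onset/offset of per-plane mean lamin intensity above
  background), surface area and volume from the voxelized nuclear region;
- monolayer height maps and roughness (SD of apical height);
- YAP nuclear/cytoplasmic ratio, focal-adhesion density with size and
  circularity gates, pMLC intensity per area, cell area/aspect ratio and
  detachment traces.

Coordinates are 0-based pixel indices, x = column, y = row; physical units
(µm) are attached via the stack's voxel sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure as skmeasure
from skimage.filters import threshold_otsu
from skimage.measure import block_reduce, regionprops
from skimage.segmentation import clear_border

from .errors import InvalidInputError, InvalidParameterError
from .images import ImageStack

logger = logging.getLogger(__name__)

N_HARMONICS = 15
EFC_RATIO_CAP = 1e3


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Contour:
    """Ordered closed planar point list in µm (closure implicit)."""

    points: np.ndarray  # (N, 2), µm
    plane_z: float = 0.0  # µm
    source: str = "bulk"  # bulk | subpixel

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InvalidInputError("contour points must be (N, 2)")
        if len(self.points) < 16:
            raise InvalidInputError("contour needs at least 16 points")
        if np.allclose(self.points[0], self.points[-1]):
            self.points = self.points[:-1]

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def mean_radius(self) -> float:
        return float(np.linalg.norm(self.points - self.centroid, axis=1).mean())


@dataclass
class EFCResult:
    """Per-harmonic semiaxes of the elliptical Fourier decomposition."""

    harmonic_semiaxes: np.ndarray  # (n, 2): (major, minor) per harmonic, µm
    coefficients: np.ndarray = field(repr=False)  # (n, 4): a, b, c, d
    locus: Tuple[float, float] = (0.0, 0.0)  # A0, C0

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonic_semiaxes)

    @property
    def efc_ratio(self) -> float:
        return efc_ratio(self)


@dataclass
class HeightMap:
    """Apical-minus-basal height grid (µm) with coverage and roughness."""

    grid: np.ndarray
    mask_covered: np.ndarray
    roughness_sd: float  # µm


@dataclass
class MorphometricsRecord:
    """Per-nucleus / per-cell measurement bundle (NaN where a readout was
    not part of the run)."""

    nucleus_id: int
    height: float = float("nan")  # µm
    surface_area: float = float("nan")  # µm²
    volume: float = float("nan")  # µm³
    efc_mean: float = float("nan")
    spread_area: float = float("nan")  # µm²
    aspect_ratio: float = float("nan")
    yap_nc: float = float("nan")
    fa_density: float = float("nan")  # count/µm²
    pmlc_per_area: float = float("nan")  # a.u./µm²


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_nuclei_bulk(lamin_stack: ImageStack, min_area_um2: float = 10.0) -> np.ndarray:
    """Bulk nuclear masks: Otsu on the lamin max-projection, connected
    components; specks below ``min_area_um2`` (noise, debris) are dropped,
    then labels touching the image edge or another label (after one-pixel
    dilation) are removed.

    Returns a 2D int label image (0 = background).
    """
    proj = lamin_stack.max_projection().astype(float)
    if proj.max() <= proj.min():
        logger.warning("uniform image: no nuclei segmented")
        return np.zeros(proj.shape, dtype=np.int32)
    thr = threshold_otsu(proj)
    fg = proj > thr
    if not fg.any():
        logger.warning("empty foreground after Otsu")
        return np.zeros(proj.shape, dtype=np.int32)
    fg = ndi.binary_fill_holes(fg)
    labels, n = ndi.label(fg)
    # speck gate: anything far below nuclear size is noise, not a nucleus
    if n:
        sizes = ndi.sum_labels(fg, labels, index=np.arange(1, n + 1))
        min_px = min_area_um2 / lamin_stack.pixel_area
        small = np.flatnonzero(sizes < min_px) + 1
        if len(small):
            labels[np.isin(labels, small)] = 0
    # edge exclusion
    labels = clear_border(labels)
    # overlap exclusion: labels whose one-pixel dilations touch.  Evaluated
    # at every pixel, so pairs up to a two-pixel gap are caught; nuclei that
    # merged into a single component are beyond this rule (they enter as one
    # object).
    sentinel = np.iinfo(np.int32).max
    dil_max = ndi.maximum_filter(labels, size=3)
    dil_min = ndi.minimum_filter(np.where(labels > 0, labels, sentinel), size=3)
    clash = (dil_max > 0) & (dil_min < sentinel) & (dil_min != dil_max)
    bad = set(np.unique(dil_max[clash]).tolist()) | set(np.unique(dil_min[clash]).tolist())
    for lab in bad - {0, sentinel}:
        labels[labels == lab] = 0
        logger.info("excluded nucleus %d: overlaps a neighbor", lab)
    # relabel compactly
    out = np.zeros_like(labels, dtype=np.int32)
    for i, lab in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == lab] = i
    return out


def contour_from_mask(
    mask: np.ndarray, pixel_size: Tuple[float, float] = (1.0, 1.0), plane_z: float = 0.0
) -> Contour:
    """Longest iso-0.5 contour of a binary mask, in µm (marching squares)."""
    cs = skmeasure.find_contours(mask.astype(float), 0.5)
    if not cs:
        raise InvalidInputError("mask has no contour")
    c = max(cs, key=len)  # (row, col)
    pts = np.column_stack([c[:, 1] * pixel_size[0], c[:, 0] * pixel_size[1]])
    return Contour(pts, plane_z=plane_z, source="bulk")


# ---------------------------------------------------------------------------
# sub-pixel lamina tracing
# ---------------------------------------------------------------------------


def trace_lamina_subpixel(
    plane: ImageStack, bulk_contour: Contour, probe_len: float = 1.5
) -> Contour:
    """Refine a bulk contour to the lamina ridge at sub-pixel resolution.

    For every contour point the intensity is sampled along the local outward
    normal over ±``probe_len`` µm; the refined point sits at the parabolic
    interpolation of the sampled maximum.  Flat profiles or probes leaving
    the image keep the bulk position.
    """
    if plane.data.ndim != 2:
        raise InvalidParameterError("trace_lamina_subpixel expects a 2D plane")
    img = plane.data.astype(float)
    dx, dy = plane.dx, plane.dy
    pts = bulk_contour.points
    n_pts = len(pts)
    tangents = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    normals = np.column_stack([tangents[:, 1], -tangents[:, 0]])
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = normals / np.where(norms > 0, norms, 1.0)
    # orient outward (away from the centroid)
    outward = pts - bulk_contour.centroid
    flip = np.einsum("ij,ij->i", normals, outward) < 0
    normals[flip] *= -1.0

    step = 0.25 * min(dx, dy)
    offsets = np.arange(-probe_len, probe_len + step / 2, step)
    # sample positions in pixel coordinates (row=y/dy, col=x/dx)
    sample_xy = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    cols = sample_xy[..., 0] / dx
    rows = sample_xy[..., 1] / dy
    inb = (
        (rows >= 0)
        & (rows <= img.shape[0] - 1)
        & (cols >= 0)
        & (cols <= img.shape[1] - 1)
    )
    vals = ndi.map_coordinates(
        img, [rows.ravel(), cols.ravel()], order=3, mode="nearest"
    ).reshape(rows.shape)
    vals = np.where(inb, vals, -np.inf)

    refined = pts.copy()
    kmax = np.argmax(vals, axis=1)
    for i in range(n_pts):
        k = kmax[i]
        if not np.isfinite(vals[i, k]):
            continue  # probe fully outside: keep bulk position
        vmax, vmin = vals[i][np.isfinite(vals[i])].max(), vals[i][np.isfinite(vals[i])].min()
        if vmax - vmin < 1e-12:
            continue  # flat profile: keep bulk position
        if k == 0 or k == len(offsets) - 1:
            s = offsets[k]
        else:
            y0, y1, y2 = vals[i, k - 1], vals[i, k], vals[i, k + 1]
            if not (np.isfinite(y0) and np.isfinite(y2)):
                s = offsets[k]
            else:
                denom = y0 - 2 * y1 + y2
                delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-300 else 0.0
                delta = np.clip(delta, -1.0, 1.0)
                s = offsets[k] + delta * step
        refined[i] = pts[i] + s * normals[i]
    return Contour(refined, plane_z=bulk_contour.plane_z, source="subpixel")


# ---------------------------------------------------------------------------
# elliptical Fourier analysis
# ---------------------------------------------------------------------------


def elliptical_fourier(contour: Contour, n_harmonics: int = N_HARMONICS) -> EFCResult:
    """Elliptical Fourier decomposition of a closed contour.

    Coefficients follow the standard chain-code-free formulation for a
    polygonal closed curve parameterized by arc length; per-harmonic semiaxes
    are the singular values of the 2x2 coefficient matrix [[a, b], [c, d]].
    """
    pts = contour.points
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1e-300):
        raise InvalidInputError("degenerate (collinear) contour")
    d = np.vstack([pts, pts[:1]])
    dxy = np.diff(d, axis=0)
    # uniform-index parameterization: each point advances the curve
    # parameter by one step.  Traced contours have near-equal point spacing,
    # where this coincides with the classical chord-length convention, and a
    # parametric ellipse decomposes exactly into its first harmonic.
    dt = np.ones(len(dxy))
    keep = np.linalg.norm(dxy, axis=1) >= 0
    dxy, dt = dxy[keep], dt[keep]
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2.0 * np.pi * t / T
    n = np.arange(1, n_harmonics + 1)[:, None]
    cosd = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])  # (n, P)
    sind = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    const = T / (2.0 * (n[:, 0] ** 2) * np.pi**2)
    vx = dxy[:, 0] / dt
    vy = dxy[:, 1] / dt
    a = const * (cosd @ vx)
    b = const * (sind @ vx)
    c = const * (cosd @ vy)
    dd = const * (sind @ vy)
    coeffs = np.stack([a, b, c, dd], axis=1)
    mats = coeffs.reshape(-1, 2, 2)
    semi = np.linalg.svd(mats, compute_uv=False)  # sorted descending
    # locus (DC term)
    xi = np.cumsum(dxy[:, 0]) - dxy[:, 0] / dt * t[1:]
    A0 = (1.0 / T) * np.sum(dxy[:, 0] / (2 * dt) * np.diff(t**2) + xi * dt) + pts[0, 0]
    yi = np.cumsum(dxy[:, 1]) - dxy[:, 1] / dt * t[1:]
    C0 = (1.0 / T) * np.sum(dxy[:, 1] / (2 * dt) * np.diff(t**2) + yi * dt) + pts[0, 1]
    return EFCResult(harmonic_semiaxes=semi, coefficients=coeffs, locus=(A0, C0))


def efd_reconstruct(res: EFCResult, n_points: int = 256) -> np.ndarray:
    """Evaluate the truncated Fourier series (all stored harmonics)."""
    t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    n = np.arange(1, res.n_harmonics + 1)[:, None]
    cos, sin = np.cos(n * t), np.sin(n * t)
    a, b, c, d = res.coefficients.T
    x = res.locus[0] + a @ cos + b @ sin
    y = res.locus[1] + c @ cos + d @ sin
    return np.column_stack([x, y])


def efc_ratio(res: EFCResult) -> float:
    """(major1 + minor1) / sum of semiaxes of harmonics 2..n, capped at 10³
    for near-perfect ellipses (the ratio is unbounded when all higher
    harmonics vanish)."""
    num = float(res.harmonic_semiaxes[0].sum())
    den = float(res.harmonic_semiaxes[1:].sum())
    if den < num / EFC_RATIO_CAP:
        return EFC_RATIO_CAP
    return num / den


# ---------------------------------------------------------------------------
# nuclear 3D geometry
# ---------------------------------------------------------------------------


def _border_background(img: np.ndarray, border_frac: float = 0.05):
    """Mean and SD of the border frame (assumed cell-free)."""
    b = max(int(round(border_frac * min(img.shape[-2:]))), 1)
    frame = np.concatenate(
        [
            img[..., :b, :].ravel(),
            img[..., -b:, :].ravel(),
            img[..., :, :b].ravel(),
            img[..., :, -b:].ravel(),
        ]
    )
    return float(frame.mean()), float(frame.std())


def nuclear_height(
    lamin_stack: ImageStack,
    mask2d: np.ndarray,
    bg_region: Optional[np.ndarray] = None,
) -> float:
    """Nuclear height (µm) from the z-extent of above-background lamin
    signal.

    The mean in-mask lamin intensity is computed per z-plane and compared
    with the per-plane mean over a cell-free background region (``bg_region``
    or the image border).  Onset and offset are the first and last planes
    whose background-subtracted plane mean exceeds 3 SD of the background
    plane means (floored at 5% of the peak excess, so the blur tail is cut
    consistently in the noiseless limit).  Height is (offset - onset) * dz.
    """
    if lamin_stack.data.ndim != 3:
        raise InvalidParameterError("nuclear_height expects a 3D stack")
    data = lamin_stack.data.astype(float)
    if bg_region is not None:
        bg_prof = data[:, bg_region.astype(bool)].mean(axis=1)
    else:
        b = max(int(round(0.05 * min(data.shape[1:]))), 1)
        frame = np.zeros(data.shape[1:], dtype=bool)
        frame[:b, :] = frame[-b:, :] = frame[:, :b] = frame[:, -b:] = True
        bg_prof = data[:, frame].mean(axis=1)
    prof = data[:, mask2d.astype(bool)].mean(axis=1)
    excess = prof - bg_prof
    peak = excess.max()
    if peak <= 0:
        logger.warning("no plane above background: height 0")
        return 0.0
    thr = max(3.0 * float(bg_prof.std()), 0.05 * peak)
    above = np.flatnonzero(excess > thr)
    if len(above) == 0:
        logger.warning("no plane above background: height 0")
        return 0.0
    return float((above[-1] - above[0]) * lamin_stack.dz)


def nuclear_binary_region(
    lamin_stack: ImageStack, mask2d: Optional[np.ndarray] = None
) -> np.ndarray:
    """3D binary nuclear region: Otsu threshold, 3D hole filling, largest
    connected component (restricted to ``mask2d`` in x-y if given)."""
    data = lamin_stack.data.astype(float)
    if data.max() <= data.min():
        return np.zeros(data.shape, dtype=bool)
    fg = data > threshold_otsu(data)
    if mask2d is not None:
        big = ndi.binary_dilation(mask2d.astype(bool), iterations=3)
        fg &= big[None, :, :]
    fg = ndi.binary_fill_holes(fg)
    if not fg.any():
        return fg
    labels, n = ndi.label(fg)
    if n > 1:
        sizes = ndi.sum_labels(fg, labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    return fg


def nuclear_surface_volume(
    lamin_stack: ImageStack, mask2d: Optional[np.ndarray] = None
) -> Tuple[float, float]:
    """(surface area µm², volume µm³) of the voxelized nuclear region.

    Volume is voxel count x voxel volume; area comes from a marching-cubes
    isosurface of the (lightly smoothed) binary region with anisotropic
    spacing.
    """
    region = nuclear_binary_region(lamin_stack, mask2d)
    if not region.any():
        return 0.0, 0.0
    volume = float(region.sum()) * lamin_stack.voxel_volume
    smooth = ndi.gaussian_filter(region.astype(float), sigma=1.0)
    pad = np.pad(smooth, 1)
    verts, faces, _, _ = skmeasure.marching_cubes(
        pad, level=0.5, spacing=(lamin_stack.dz, lamin_stack.dy, lamin_stack.dx)
    )
    area = float(skmeasure.mesh_surface_area(verts, faces))
    return area, volume


def nucleus_efc_3plane(
    lamin_stack: ImageStack,
    labels: np.ndarray,
    nucleus_label: int,
    probe_len: float = 1.5,
) -> float:
    """Mean EFC ratio over the planes at 25%, 50% and 75% of nuclear height,
    each contour refined by sub-pixel lamina tracing.

    Nuclei spanning fewer than 3 planes fall back to the single best plane
    (logged)."""
    if lamin_stack.data.ndim != 3:
        raise InvalidParameterError("nucleus_efc_3plane expects a 3D stack")
    mask = labels == nucleus_label
    if not mask.any():
        raise InvalidInputError(f"label {nucleus_label} not present")
    data = lamin_stack.data.astype(float)
    bg_mean, bg_sd = _border_background(data)
    prof = data[:, mask].mean(axis=1)
    above = np.flatnonzero(prof > bg_mean + 3.0 * bg_sd)
    if len(above) == 0:
        above = np.array([int(np.argmax(prof))])
    z0, z1 = above[0], above[-1]
    if z1 - z0 + 1 < 3:
        logger.info("nucleus %d spans <3 planes: single-plane EFC", nucleus_label)
        zplanes = [int(np.argmax(prof))]
    else:
        zplanes = [int(round(z0 + f * (z1 - z0))) for f in (0.25, 0.5, 0.75)]
    ratios = []
    for z in zplanes:
        plane = ImageStack(data[z], lamin_stack.voxel_size, lamin_stack.channel)
        bulk = contour_from_mask(mask, (lamin_stack.dx, lamin_stack.dy), z * lamin_stack.dz)
        traced = trace_lamina_subpixel(plane, bulk, probe_len=probe_len)
        ratios.append(efc_ratio(elliptical_fourier(traced)))
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# monolayer topography
# ---------------------------------------------------------------------------


def monolayer_height_map(
    stack: ImageStack, crop_margin: float = 2.0, downsample: int = 4
) -> HeightMap:
    """Apical-basal thickness map of a monolayer from a (multi)channel stack.

    Channels are summed, the combined stack is globally thresholded (Otsu),
    and each x-y column's covered z-extent gives the local height.  A border
    of ``crop_margin`` µm is removed, uncovered columns are filled with the
    mean of covered neighbors, and the grid is block-averaged by
    ``downsample`` before the roughness SD is taken.
    """
    data = stack.data.astype(float)
    if data.ndim == 4:
        data = data.sum(axis=0)
    if data.ndim != 3:
        raise InvalidParameterError("monolayer_height_map expects a 3D or 4D stack")
    if data.max() <= data.min():
        raise InvalidInputError("empty field: no cells to segment")
    binary = data > threshold_otsu(data)
    covered = binary.any(axis=0)
    zidx = np.arange(binary.shape[0])[:, None, None]
    top = np.where(binary, zidx, -1).max(axis=0)
    bottom = np.where(binary, zidx, binary.shape[0]).min(axis=0)
    height = np.where(covered, (top - bottom + 1) * stack.dz, 0.0)

    mx = int(round(crop_margin / stack.dx))
    my = int(round(crop_margin / stack.dy))
    if 2 * my >= height.shape[0] or 2 * mx >= height.shape[1]:
        raise InvalidParameterError("crop margin covers the whole field")
    if mx or my:
        height = height[my : height.shape[0] - my or None, mx : height.shape[1] - mx or None]
        covered = covered[my : covered.shape[0] - my or None, mx : covered.shape[1] - mx or None]
    if not covered.any():
        raise InvalidInputError("no cell coverage after cropping")

    # neighborhood-mean interpolation of uncovered columns
    filled = height.copy()
    known = covered.copy()
    kernel = np.ones((3, 3))
    for _ in range(max(filled.shape)):
        if known.all():
            break
        ssum = ndi.convolve(np.where(known, filled, 0.0), kernel, mode="constant")
        scnt = ndi.convolve(known.astype(float), kernel, mode="constant")
        newly = (~known) & (scnt > 0)
        filled[newly] = ssum[newly] / scnt[newly]
        known |= newly

    # truncate to a multiple of the downsample factor (block_reduce pads
    # partial blocks with zeros, which would corrupt the edge means)
    ny2 = (filled.shape[0] // downsample) * downsample
    nx2 = (filled.shape[1] // downsample) * downsample
    filled = filled[:ny2, :nx2]
    covered = covered[:ny2, :nx2]
    grid = block_reduce(filled, (downsample, downsample), np.mean)
    cov_ds = block_reduce(covered.astype(float), (downsample, downsample), np.mean) > 0.5
    return HeightMap(grid=grid, mask_covered=cov_ds, roughness_sd=float(grid.std()))


# ---------------------------------------------------------------------------
# intensity readouts
# ---------------------------------------------------------------------------


def yap_nc_ratio(
    yap_img: ImageStack,
    nuc_mask: np.ndarray,
    cell_mask: np.ndarray,
    bg_region: np.ndarray,
) -> float:
    """Background-subtracted nuclear-to-cytoplasmic mean YAP intensity on
    the max-projection: (N - bg) / (C - bg).  Returns NaN (missing) when the
    cytoplasmic mean does not exceed background."""
    proj = yap_img.max_projection().astype(float)
    nuc_mask = nuc_mask.astype(bool)
    cell_mask = cell_mask.astype(bool)
    if not (nuc_mask & cell_mask).sum() == nuc_mask.sum():
        raise InvalidParameterError("nuclear mask must lie inside the cell mask")
    cyto = cell_mask & ~nuc_mask
    if not cyto.any() or not nuc_mask.any() or not bg_region.any():
        raise InvalidInputError("empty mask")
    bg = proj[bg_region.astype(bool)].mean()
    cyt = proj[cyto].mean() - bg
    nuc = proj[nuc_mask].mean() - bg
    if cyt <= 0:
        logger.warning("cytoplasmic mean at/below background: N/C undefined")
        return float("nan")
    return float(nuc / cyt)


def fa_detect(vinculin_img: ImageStack, roi: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Focal-adhesion candidates from the vinculin channel.

    Otsu threshold, connected components, then the standard particle gates:
    area 0.5-15 µm², circularity 4πA/P² in [0.1, 1.0] (clipped at 1 for
    small blobs), excluding objects touching the ROI edge.  Returns one row
    per retained particle.
    """
    proj = vinculin_img.max_projection().astype(float)
    if roi is None:
        roi = np.ones(proj.shape, dtype=bool)
    roi = roi.astype(bool)
    sub = proj.copy()
    sub[~roi] = 0
    if sub.max() <= 0 or proj[roi].max() == proj[roi].min():
        return pd.DataFrame(columns=["label", "area_um2", "circularity"])
    thr = threshold_otsu(proj[roi])
    fg = (proj > thr) & roi
    labels, _ = ndi.label(fg)
    # exclusion of ROI-edge objects: those touching pixels just outside roi
    # or the image border
    edge = roi & ~ndi.binary_erosion(roi, border_value=0)
    edge_labels = set(np.unique(labels[edge])) - {0}
    px_area = vinculin_img.pixel_area
    px_len = vinculin_img.dx
    rows = []
    for p in regionprops(labels):
        if p.label in edge_labels:
            continue
        area = p.area * px_area
        perim = p.perimeter * px_len
        circ = min(4.0 * np.pi * area / perim**2, 1.0) if perim > 0 else 1.0
        if 0.5 <= area <= 15.0 and 0.1 <= circ <= 1.0:
            rows.append({"label": p.label, "area_um2": area, "circularity": circ})
    return pd.DataFrame(rows, columns=["label", "area_um2", "circularity"])


def fa_density(vinculin_img: ImageStack, roi: Optional[np.ndarray] = None) -> float:
    """Focal adhesions per µm² of ROI."""
    proj_shape = vinculin_img.max_projection().shape
    if roi is None:
        roi = np.ones(proj_shape, dtype=bool)
    particles = fa_detect(vinculin_img, roi)
    roi_area = roi.astype(bool).sum() * vinculin_img.pixel_area
    return float(len(particles) / roi_area)


def pmlc_per_area(pmlc_stack: ImageStack, roi: np.ndarray) -> float:
    """Mean pMLC intensity (average z-projection) divided by ROI area
    (a.u./µm²)."""
    roi = roi.astype(bool)
    if not roi.any():
        raise InvalidInputError("empty ROI")
    data = pmlc_stack.data.astype(float)
    proj = data.mean(axis=0) if data.ndim == 3 else data
    roi_area = roi.sum() * pmlc_stack.pixel_area
    return float(proj[roi].mean() / roi_area)


def cell_area_aspect(
    cell_mask: np.ndarray, pixel_size: Tuple[float, float] = (1.0, 1.0)
) -> Tuple[float, float]:
    """(spread area µm², aspect ratio >= 1) of a single-cell mask via the
    best-fit (second-moment) ellipse."""
    mask = cell_mask.astype(bool)
    if not mask.any():
        raise InvalidInputError("empty cell mask")
    area = float(mask.sum()) * pixel_size[0] * pixel_size[1]
    props = regionprops(mask.astype(np.uint8))[0]
    minor = props.axis_minor_length
    major = props.axis_major_length
    aspect = float(major / minor) if minor > 0 else float("inf")
    return area, max(aspect, 1.0)


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------


def area_traces(
    label_series: Sequence[np.ndarray],
    pixel_area: float = 1.0,
    decline_window: int = 3,
) -> pd.DataFrame:
    """Per-object area over time with a detachment flag.

    An object is flagged detached when its area reaches zero (it disappears)
    after a monotone non-increasing decline over ``decline_window`` frames.
    Objects that reappear after a gap are flagged with a warning and treated
    as retained (trace split).
    """
    label_series = [np.asarray(m) for m in label_series]
    all_labels = sorted(
        set(int(l) for m in label_series for l in np.unique(m) if l > 0)
    )
    rows = []
    flags = {}
    for lab in all_labels:
        areas = np.array([float((m == lab).sum()) * pixel_area for m in label_series])
        present = np.flatnonzero(areas > 0)
        gap = len(present) > 0 and np.any(np.diff(present) > 1)
        if gap:
            logger.warning("object %d has identity gaps: trace split, retained", lab)
        detached = False
        if not gap and len(present) > 0 and present[-1] < len(areas) - 1:
            last = present[-1]
            w0 = max(0, last - decline_window + 1)
            seg = areas[w0 : last + 1]
            if len(seg) >= 2 and np.all(np.diff(seg) <= 0) and seg[0] > seg[-1]:
                detached = True
        flags[lab] = detached
        for frame, a in enumerate(areas):
            rows.append(
                {"frame": frame, "label": lab, "area": a, "detached": detached}
            )
    return pd.DataFrame(rows, columns=["frame", "label", "area", "detached"])


# ---------------------------------------------------------------------------
# per-nucleus pipeline
# ---------------------------------------------------------------------------


def measure_nuclei(lamin_stack: ImageStack) -> pd.DataFrame:
    """One record per retained nucleus: height, surface area, volume and
    3-plane mean EFC ratio.  Exclusions happen in segmentation and are
    logged there."""
    labels = segment_nuclei_bulk(lamin_stack)
    records = []
    for lab in np.unique(labels[labels > 0]):
        mask = labels == lab
        height = nuclear_height(lamin_stack, mask)
        area, volume = nuclear_surface_volume(lamin_stack, mask)
        efc = nucleus_efc_3plane(lamin_stack, labels, int(lab))
        records.append(
            MorphometricsRecord(
                nucleus_id=int(lab),
                height=height,
                surface_area=area,
                volume=volume,
                efc_mean=efc,
            )
        )
    from dataclasses import asdict

    cols = ["nucleus_id", "height", "surface_area", "volume", "efc_mean"]
    return pd.DataFrame([asdict(r) for r in records], columns=cols)
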