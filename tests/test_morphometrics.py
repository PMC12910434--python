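"""Image-analysis operations: segmentation, sub-pixel tracing, elliptical
Fourier analysis, 3D nuclear geometry, topography and intensity readouts."""

import numpy as np
import pytest

from conftest import star_contour_points
from nucleodrop.errors import InvalidInputError, InvalidParameterError
from nucleodrop.images import ImageStack
from nucleodrop.morphometrics import (
    EFC_RATIO_CAP,
    Contour,
    area_traces,
    cell_area_aspect,
    contour_from_mask,
    efc_ratio,
    efd_reconstruct,
    elliptical_fourier,
    fa_density,
    fa_detect,
    monolayer_height_map,
    nuclear_height,
    nuclear_surface_volume,
    pmlc_per_area,
    segment_nuclei_bulk,
    trace_lamina_subpixel,
    yap_nc_ratio,
)


def ellipse_points(a=10.0, b=5.0, n=20000):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([a * np.cos(t), b * np.sin(t)])


class TestEllipticalFourier:
    def test_exact_ellipse_single_harmonic(self):
        res = elliptical_fourier(Contour(ellipse_points()))
        assert res.harmonic_semiaxes[0] == pytest.approx([10.0, 5.0], abs=1e-6)
        assert res.harmonic_semiaxes[1:].max() < 1e-6
        assert efc_ratio(res) == EFC_RATIO_CAP

    def test_similarity_invariance(self):
        pts = ellipse_points()
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        res = elliptical_fourier(Contour(pts @ R.T * 3.0 + [4.0, -7.0]))
        assert res.harmonic_semiaxes[0] == pytest.approx([30.0, 15.0], abs=3e-6)
        assert efc_ratio(res) == EFC_RATIO_CAP

    def test_reversal_invariance(self):
        pts = star_contour_points()
        r1 = elliptical_fourier(Contour(pts)).harmonic_semiaxes
        r2 = elliptical_fourier(Contour(pts[::-1])).harmonic_semiaxes
        assert np.allclose(r1, r2, atol=1e-9)

    def test_against_dense_quadrature_oracle(self):
        """Independent oracle: resample the analytic star uniformly in arc
        length, take the FFT of x(u), y(u), build the per-harmonic 2x2
        matrices and their singular values."""
        R, eps, k = 10.0, 0.2, 5
        th = np.linspace(0, 2 * np.pi, 400001)
        r = R * (1 + eps * np.cos(k * th))
        x, y = r * np.cos(th), r * np.sin(th)
        s = np.concatenate([[0], np.cumsum(np.hypot(np.diff(x), np.diff(y)))])
        N = 2**16
        u = np.linspace(0, s[-1], N, endpoint=False)
        xi, yi = np.interp(u, s, x), np.interp(u, s, y)
        X = np.fft.rfft(xi) / N
        Y = np.fft.rfft(yi) / N
        oracle = np.array(
            [
                np.linalg.svd(
                    [[2 * X[n].real, -2 * X[n].imag], [2 * Y[n].real, -2 * Y[n].imag]],
                    compute_uv=False,
                )
                for n in range(1, 16)
            ]
        )
        mine = elliptical_fourier(Contour(star_contour_points(R, eps, k))).harmonic_semiaxes
        dominant = oracle[:, 0] > 1e-2
        rel = np.abs(mine[dominant] - oracle[dominant]).max() / oracle.max()
        assert rel < 0.005

    def test_ratio_decreases_with_wrinkle_amplitude(self):
        ratios = [
            efc_ratio(elliptical_fourier(Contour(star_contour_points(10, e, 5))))
            for e in (0.05, 0.1, 0.2)
        ]
        assert ratios[0] > ratios[1] > ratios[2]

    def test_band_limited_reconstruction(self):
        c = Contour(star_contour_points(10, 0.2, 5, n=800))
        rec = efd_reconstruct(elliptical_fourier(c), 800)
        from scipy.spatial import cKDTree

        err = cKDTree(c.points).query(rec)[0].mean()
        assert err / c.mean_radius() < 0.02

    def test_collinear_contour_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 40), np.linspace(0, 2, 40)])
        with pytest.raises(InvalidInputError):
            elliptical_fourier(Contour(pts))

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            Contour(np.random.default_rng(0).normal(size=(5, 2)))


def gaussian_ring_image(radius_px=30.0, sigma_px=2.0, size=101, offset=0.0):
    y, x = np.mgrid[:size, :size]
    rho = np.hypot(x - size // 2, y - size // 2)
    return np.exp(-((rho - (radius_px + offset)) ** 2) / (2 * sigma_px**2))


def circle_contour(radius_px, size=101, n=180):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    c = size // 2
    return Contour(np.column_stack([c + radius_px * np.cos(t), c + radius_px * np.sin(t)]))


class TestSubpixelTracing:
    @pytest.mark.parametrize("bulk_offset", [-0.4, 0.4])
    def test_recovers_ridge_radius(self, bulk_offset):
        img = ImageStack(gaussian_ring_image(), (1.0, 1.0, 0.13), "lamin")
        bulk = circle_contour(30.0 + bulk_offset)
        traced = trace_lamina_subpixel(img, bulk, probe_len=4.0)
        r = np.linalg.norm(traced.points - [50, 50], axis=1)
        assert np.abs(r - 30.0).max() < 0.1  # sub-pixel accuracy

    def test_flat_profile_keeps_bulk_point(self):
        img = ImageStack(np.ones((101, 101)), (1.0, 1.0, 0.13), "lamin")
        bulk = circle_contour(30.0)
        traced = trace_lamina_subpixel(img, bulk, probe_len=4.0)
        assert np.allclose(traced.points, bulk.points)

    def test_shifted_ridge_traced_one_pixel_out(self):
        img = ImageStack(gaussian_ring_image(offset=1.0), (1.0, 1.0, 0.13), "lamin")
        bulk = circle_contour(30.0)
        traced = trace_lamina_subpixel(img, bulk, probe_len=4.0)
        r = np.linalg.norm(traced.points - [50, 50], axis=1)
        assert np.abs(r - 31.0).max() < 0.1


def ring_mask(cy, cx, r, size):
    y, x = np.mgrid[: size[0], : size[1]]
    rho = np.hypot(x - cx, y - cy)
    return np.abs(rho - r) < 2.5


class TestBulkSegmentation:
    def test_three_rings_three_labels(self):
        img = np.zeros((160, 160))
        for cy, cx in ((40, 40), (40, 120), (120, 80)):
            img[ring_mask(cy, cx, 18, img.shape)] = 100.0
        labels = segment_nuclei_bulk(ImageStack(img, (0.2, 0.2, 0.13), "lamin"))
        assert labels.max() == 3

    def test_edge_touching_excluded(self):
        img = np.zeros((160, 160))
        img[ring_mask(80, 80, 18, img.shape)] = 100.0
        img[ring_mask(5, 40, 18, img.shape)] = 100.0  # clipped by the frame
        labels = segment_nuclei_bulk(ImageStack(img, (0.2, 0.2, 0.13), "lamin"))
        assert labels.max() == 1

    def test_touching_pair_excluded(self):
        """Two nuclei whose filled masks come within the one-pixel dilation
        of each other are both removed (near-contact exclusion; fully merged
        pairs appear as one object and are out of reach of this rule)."""
        img = np.zeros((160, 160))
        img[ring_mask(80, 59, 18, img.shape)] = 100.0
        img[ring_mask(80, 101, 18, img.shape)] = 100.0  # ~1-2 px gap
        labels = segment_nuclei_bulk(ImageStack(img, (0.2, 0.2, 0.13), "lamin"))
        assert labels.max() == 0

    def test_uniform_image_no_labels(self):
        labels = segment_nuclei_bulk(ImageStack(np.ones((64, 64)), (0.2, 0.2, 0.13), "lamin"))
        assert labels.max() == 0


class TestNuclearHeight:
    def _stack(self, z0=10, z1=40, nz=60, dz=0.13):
        data = np.zeros((nz, 40, 40))
        data[z0 : z1 + 1, 10:30, 10:30] = 100.0
        return ImageStack(data, (0.2, 0.2, dz), "lamin")

    def test_plane_span(self):
        st = self._stack()
        mask = np.zeros((40, 40), bool)
        mask[10:30, 10:30] = True
        assert nuclear_height(st, mask) == pytest.approx(30 * 0.13, abs=2 * 0.13)

    def test_all_background_is_zero(self):
        st = ImageStack(np.zeros((20, 40, 40)), (0.2, 0.2, 0.13), "lamin")
        mask = np.ones((40, 40), bool)
        assert nuclear_height(st, mask) == 0.0

    def test_height_scales_with_dz(self):
        mask = np.zeros((40, 40), bool)
        mask[10:30, 10:30] = True
        h1 = nuclear_height(self._stack(dz=0.13), mask)
        h2 = nuclear_height(self._stack(dz=0.26), mask)
        assert h2 == pytest.approx(2 * h1)


class TestSurfaceVolume:
    @staticmethod
    def _ball_stack(r=5.0, voxel=(0.1, 0.1, 0.13)):
        dx, dy, dz = voxel
        nx = int(2 * (r + 1) / dx)
        ny = int(2 * (r + 1) / dy)
        nz = int(2 * (r + 1) / dz)
        z, y, x = np.mgrid[:nz, :ny, :nx]
        rho = np.sqrt(
            ((x - nx / 2 + 0.5) * dx) ** 2
            + ((y - ny / 2 + 0.5) * dy) ** 2
            + ((z - nz / 2 + 0.5) * dz) ** 2
        )
        return ImageStack((rho < r) * 100.0, voxel, "lamin")

    def test_voxelized_ball(self):
        st = self._ball_stack()
        A, V = nuclear_surface_volume(st)
        assert V == pytest.approx(4 / 3 * np.pi * 125, rel=0.03)
        assert A == pytest.approx(4 * np.pi * 25, rel=0.05)

    def test_voxel_size_scaling(self):
        st = self._ball_stack()
        st2 = ImageStack(st.data, (0.2, 0.2, 0.26), "lamin")
        A1, V1 = nuclear_surface_volume(st)
        A2, V2 = nuclear_surface_volume(st2)
        assert V2 == pytest.approx(8 * V1, rel=1e-6)
        assert A2 == pytest.approx(4 * A1, rel=0.02)

    def test_empty_region(self):
        st = ImageStack(np.zeros((10, 20, 20)), (0.1, 0.1, 0.13), "lamin")
        assert nuclear_surface_volume(st) == (0.0, 0.0)


class TestHeightMap:
    @staticmethod
    def _monolayer_stack(heights, dz=0.26, pixel=0.4):
        nz = int(np.ceil(heights.max() / dz)) + 4
        zc = (np.arange(nz) + 0.5) * dz
        occ = zc[:, None, None] < heights[None]
        data = np.stack([100.0 * occ, 60.0 * occ]) + 1.0
        return ImageStack(data, (pixel, pixel, dz), "multi")

    def test_flat_monolayer(self):
        h = np.full((120, 120), 3.0)
        st = self._monolayer_stack(h)
        hm = monolayer_height_map(st, crop_margin=2.0, downsample=4)
        assert np.abs(hm.grid - 3.0).max() <= st.dz + 1e-9
        assert hm.roughness_sd < st.dz

    def test_dome_raises_roughness(self):
        h = np.full((120, 120), 3.0)
        y, x = np.mgrid[:120, :120]
        dome = np.clip(1 - ((x - 60) ** 2 + (y - 60) ** 2) / 25**2, 0, None)
        h2 = h + 5.0 * dome
        r_flat = monolayer_height_map(self._monolayer_stack(h), 2.0, 4).roughness_sd
        r_dome = monolayer_height_map(self._monolayer_stack(h2), 2.0, 4).roughness_sd
        assert r_dome > r_flat
        hm = monolayer_height_map(self._monolayer_stack(h2), 2.0, 4)
        assert hm.grid.max() > 6.0  # dome visible

    def test_crop_covering_field_rejected(self):
        st = self._monolayer_stack(np.full((60, 60), 3.0))
        with pytest.raises(InvalidParameterError):
            monolayer_height_map(st, crop_margin=50.0, downsample=2)


class TestYapRatio:
    def test_stated_formula(self):
        img = np.full((60, 60), 50.0)
        cell = np.zeros((60, 60), bool)
        cell[10:50, 10:50] = True
        nuc = np.zeros((60, 60), bool)
        nuc[25:35, 25:35] = True
        img[cell] = 100.0
        img[nuc] = 200.0
        bg = ~cell
        st = ImageStack(img, (0.4, 0.4, 0.13), "yap")
        assert yap_nc_ratio(st, nuc, cell, bg) == pytest.approx(3.0)

    def test_uniform_image_is_one(self):
        img = np.full((60, 60), 80.0)
        cell = np.zeros((60, 60), bool)
        cell[10:50, 10:50] = True
        nuc = np.zeros((60, 60), bool)
        nuc[25:35, 25:35] = True
        st = ImageStack(img, (0.4, 0.4, 0.13), "yap")
        # uniform: N - bg == C - bg for any bg < C
        img2 = img.copy()
        img2[~cell] = 40.0
        st2 = ImageStack(img2, (0.4, 0.4, 0.13), "yap")
        assert yap_nc_ratio(st2, nuc, cell, ~cell) == pytest.approx(1.0)

    def test_cytoplasm_at_background_is_missing(self):
        img = np.full((60, 60), 50.0)
        cell = np.zeros((60, 60), bool)
        cell[10:50, 10:50] = True
        nuc = np.zeros((60, 60), bool)
        nuc[25:35, 25:35] = True
        img[nuc] = 200.0
        st = ImageStack(img, (0.4, 0.4, 0.13), "yap")
        assert np.isnan(yap_nc_ratio(st, nuc, cell, ~cell))


class TestFocalAdhesions:
    def test_spot_field_count_and_density(self):
        from nucleodrop.synthetic import make_fa_field

        img, truth = make_fa_field(n_spots=20, spot_area=2.0, seed=3)
        parts = fa_detect(img)
        assert len(parts) == truth["count"] == 20
        roi_area = img.data.shape[0] * img.data.shape[1] * img.pixel_area
        assert fa_density(img) == pytest.approx(20 / roi_area)
        assert fa_density(img) == pytest.approx(0.02, rel=0.01)

    def test_small_spot_excluded(self):
        img_arr = np.full((200, 200), 5.0)
        y, x = np.mgrid[:200, :200]
        # area 0.2 um^2 at 0.1 um px -> radius 2.5 px
        img_arr[np.hypot(x - 100, y - 100) < 2.52] = 100.0
        img = ImageStack(img_arr, (0.1, 0.1, 0.13), "vinculin")
        assert len(fa_detect(img)) == 0

    def test_filament_excluded_by_circularity(self):
        img_arr = np.full((200, 200), 5.0)
        img_arr[100, 30:170] = 100.0  # 1-px-wide, 14 um long
        img = ImageStack(img_arr, (0.1, 0.1, 0.13), "vinculin")
        assert len(fa_detect(img)) == 0


class TestIntensityPerArea:
    def test_uniform_patch(self):
        data = np.full((5, 50, 50), 10.0)
        roi = np.zeros((50, 50), bool)
        roi[:20, :50] = True  # 1000 px * 0.1 um^2? -> use 0.32 um px: area 102.4
        st = ImageStack(data, (0.5, 0.5, 0.13), "pmlc")
        # mean 10 over roi area 20*50*0.25 um^2 = 250
        assert pmlc_per_area(st, roi) == pytest.approx(10.0 / 250.0)

    def test_doubling_roi_halves_value(self):
        data = np.full((5, 50, 50), 10.0)
        roi1 = np.zeros((50, 50), bool)
        roi1[:10] = True
        roi2 = np.zeros((50, 50), bool)
        roi2[:20] = True
        st = ImageStack(data, (0.5, 0.5, 0.13), "pmlc")
        assert pmlc_per_area(st, roi2) == pytest.approx(pmlc_per_area(st, roi1) / 2)

    def test_empty_roi_rejected(self):
        st = ImageStack(np.ones((5, 20, 20)), (0.5, 0.5, 0.13), "pmlc")
        with pytest.raises(InvalidInputError):
            pmlc_per_area(st, np.zeros((20, 20), bool))


class TestCellShape:
    def test_square(self):
        mask = np.zeros((30, 30), bool)
        mask[10:20, 10:20] = True
        area, aspect = cell_area_aspect(mask, (0.5, 0.5))
        assert area == pytest.approx(25.0)
        assert aspect == pytest.approx(1.0, abs=0.02)

    def test_rectangle_aspect(self):
        mask = np.zeros((60, 60), bool)
        mask[10:20, 10:50] = True  # 40 x 10 px
        _, aspect = cell_area_aspect(mask, (0.5, 0.5))
        assert aspect == pytest.approx(4.0, rel=0.05)

    def test_rotation_invariance(self):
        mask = np.zeros((60, 60), bool)
        mask[10:20, 10:50] = True
        a1 = cell_area_aspect(mask, (0.5, 0.5))
        a2 = cell_area_aspect(np.rot90(mask), (0.5, 0.5))
        assert a1[0] == pytest.approx(a2[0])
        assert a1[1] == pytest.approx(a2[1], rel=1e-6)


class TestAreaTraces:
    def test_detachment_flagged(self):
        from nucleodrop.synthetic import make_detachment_series

        frames, truth = make_detachment_series(n_frames=10, detach_frame=6, seed=2)
        df = area_traces(frames, pixel_area=0.25)
        flagged = set(df.loc[df.detached, "label"].unique())
        assert flagged == {truth["detach_label"]}

    def test_constant_object_retained(self):
        m = np.zeros((20, 20), int)
        m[5:15, 5:15] = 1
        df = area_traces([m] * 5)
        assert not df.detached.any()
        assert (df.area == 100).all()

    def test_neighbor_growth_retained(self):
        from nucleodrop.synthetic import make_detachment_series

        frames, truth = make_detachment_series(n_frames=10, detach_frame=6, seed=2)
        df = area_traces(frames, pixel_area=0.25)
        lab = truth["detach_label"]
        others = df[(df.label != lab)]
        # neighbors absorb the vacated area: their total area grows
        tot0 = others[others.frame == 0].area.sum()
        tot9 = others[others.frame == 9].area.sum()
        assert tot9 > tot0
        assert not others.detached.any()


class TestMeasureNuclei:
    def test_every_label_yields_one_record(self):
        from nucleodrop.morphometrics import measure_nuclei, segment_nuclei_bulk

        img = np.zeros((30, 160, 160))
        for cy, cx in ((40, 40), (40, 120), (120, 80)):
            m = ring_mask(cy, cx, 18, (160, 160))
            img[8:22, m] = 100.0
        st = ImageStack(img, (0.2, 0.2, 0.13), "lamin")
        labels = segment_nuclei_bulk(st)
        df = measure_nuclei(st)
        assert sorted(df.nucleus_id) == sorted(np.unique(labels[labels > 0]))
        assert df.nucleus_id.is_unique
        assert (df.volume > 0).all() and (df.height > 0).all()


class TestContourFromMask:
    def test_physical_units(self):
        mask = np.zeros((64, 64), bool)
        y, x = np.mgrid[:64, :64]
        mask[np.hypot(x - 32, y - 32) < 20] = True
        c = contour_from_mask(mask, (0.5, 0.5))
        r = np.linalg.norm(c.points - c.centroid, axis=1)
        assert r.mean() == pytest.approx(10.0, rel=0.03)
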