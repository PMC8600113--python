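"""Geometry module: contours, layered wall model, morphometrics."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from plaquestress.geometry import (Contour, CrossSection, GeometryError,
                                   PlaqueRegion, build_layered_geometry,
                                   complete_partial_iel, compute_plaque_burden,
                                   measure_cap_thickness, offset_contour,
                                   select_representative_frames)

from conftest import ray_cast_inside, shoelace


class TestContour:
    def test_normalizes_orientation_and_rejects_bad_input(self):
        cw = Contour.circle(1.0).points[::-1]
        c = Contour(cw)
        assert c.area > 0  # counterclockwise after normalization
        with pytest.raises(GeometryError):
            Contour(np.array([[0, 0], [1, 0], [1, 1], [0, 1]]))  # <8 vertices
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1], [0.5, -0.2],
                           [0.2, -0.3], [0.8, -0.4], [0.1, -0.5]])
        with pytest.raises(GeometryError):
            Contour(bowtie)

    def test_resample_preserves_shape(self):
        c = Contour.ellipse(2.0, 1.0, n=64).resample(256)
        r = np.hypot(c.points[:, 0] / 2.0, c.points[:, 1] / 1.0)
        assert np.allclose(r, 1.0, atol=5e-3)


class TestRepresentativeFrames:
    def test_argmin_and_midpoints(self):
        m = select_representative_frames([8.0, 5.0, 2.7, 4.9, 7.8], pr=0, dr=4)
        assert (m.mla, m.ps, m.ds) == (2, 1, 3)

    def test_missing_reference_uses_lesion_edge(self):
        areas = {i: 10.0 - i if i <= 6 else 4.0 + i for i in range(11)}
        m = select_representative_frames(areas, lesion_bounds=(0, 10))
        assert m.mla == 6
        assert m.ps == 3  # midpoint of proximal edge (0) and MLA

    def test_floor_tie_break(self):
        areas = {i: [9, 8, 7, 6, 5, 1, 5, 7][i] for i in range(8)}
        m = select_representative_frames(areas, pr=0, dr=7)
        assert m.ps == (0 + 5) // 2 == 2

    def test_shift_invariance(self):
        areas = [8.0, 5.0, 2.7, 4.9, 7.8]
        base = select_representative_frames(areas, pr=0, dr=4)
        shifted = select_representative_frames({i + 100: a for i, a in
                                                enumerate(areas)}, pr=100, dr=104)
        for name in ("ps", "mla", "ds"):
            assert getattr(shifted, name) == getattr(base, name) + 100

    def test_tie_picks_most_proximal(self):
        m = select_representative_frames([9, 8, 3, 5, 3, 8, 9], pr=0, dr=6)
        assert m.mla == 2

    def test_errors(self):
        with pytest.raises(GeometryError):
            select_representative_frames([1.0, 2.0], lesion_bounds=(0, 1))
        with pytest.raises(GeometryError):
            select_representative_frames([1, 2, 3], lesion_bounds=(5, 9))


class TestOffset:
    def test_circle_offset_area(self):
        out = offset_contour(Contour.circle(2.0), 0.2)
        assert out.area == pytest.approx(np.pi * 2.2 ** 2, rel=5e-3)

    def test_zero_offset_identity(self):
        c = Contour.circle(1.0)
        assert offset_contour(c, 0.0) is c

    def test_ellipse_against_bruteforce_normal_offset(self):
        a, b, t = 2.0, 1.5, 0.25
        out = offset_contour(Contour.ellipse(a, b, n=256), t)
        # dense brute-force offset: point + t * outward normal of the ellipse
        u = np.linspace(0, 2 * np.pi, 20000, endpoint=False)
        p = np.column_stack([a * np.cos(u), b * np.sin(u)])
        nrm = np.column_stack([b * np.cos(u), a * np.sin(u)])
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        dense = p + t * nrm
        d = cdist(out.points, dense).min(axis=1)
        assert d.max() < 0.01 * t + 1e-4

    def test_round_trip_restores_circle(self):
        c = Contour.circle(2.0, n=256)
        grown = offset_contour(c, 0.3)
        back = grown.polygon.buffer(-0.3, quad_segs=32)
        assert back.area == pytest.approx(c.area, rel=5e-3)

    def test_negative_offset_rejected(self):
        with pytest.raises(GeometryError):
            offset_contour(Contour.circle(1.0), -0.1)


class TestLayeredGeometry:
    def test_concentric_layer_areas(self, annulus_geom):
        assert annulus_geom.area("media") == pytest.approx(
            np.pi * (2.2 ** 2 - 2.0 ** 2), rel=5e-3)
        assert annulus_geom.area("adventitia") == pytest.approx(
            np.pi * (2.5 ** 2 - 2.2 ** 2), rel=5e-3)

    def test_lipid_partitions_intima(self):
        lumen, iel = Contour.circle(1.5, n=256), Contour.circle(2.0, n=256)
        pool = Contour.ellipse(0.35, 0.12, center=(0, 1.73), n=64)
        cs = CrossSection(0, 0.0, lumen, iel,
                          (PlaqueRegion("lipid", pool),), 0.2, 0.3)
        geom = build_layered_geometry(cs)
        intima = geom.area("intima_fibrous") + geom.area("intima_lipid")
        assert intima == pytest.approx(iel.area - lumen.area, rel=1e-3)
        assert geom.area("intima_lipid") == pytest.approx(pool.area, rel=1e-2)

    def test_protruding_region_is_clipped(self):
        lumen, iel = Contour.circle(1.5, n=256), Contour.circle(2.0, n=256)
        pool = Contour.circle(0.4, center=(0.0, 1.95), n=64)  # crosses the IEL
        cs = CrossSection(0, 0.0, lumen, iel,
                          (PlaqueRegion("lipid", pool),), 0.2, 0.3)
        with pytest.warns(UserWarning, match="clipped"):
            geom = build_layered_geometry(cs)
        # independent clipping oracle: dense grid + own ray casting
        g = np.linspace(-2.5, 2.5, 701)
        gx, gy = np.meshgrid(g, g)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        in_pool = ray_cast_inside(pts, pool.points)
        in_iel = ray_cast_inside(pts, iel.points)
        in_lum = ray_cast_inside(pts, lumen.points)
        cell = (g[1] - g[0]) ** 2
        expected = float(np.sum(in_pool & in_iel & ~in_lum)) * cell
        assert geom.area("intima_lipid") == pytest.approx(expected, rel=2e-2)

    def test_calcium_wins_overlap(self):
        lumen, iel = Contour.circle(1.5, n=256), Contour.circle(2.0, n=256)
        blob = Contour.ellipse(0.3, 0.12, center=(0, 1.73), n=64)
        cs = CrossSection(0, 0.0, lumen, iel,
                          (PlaqueRegion("lipid", blob),
                           PlaqueRegion("calcium", blob)), 0.2, 0.3)
        geom = build_layered_geometry(cs)
        assert geom.area("intima_lipid") == pytest.approx(0.0, abs=1e-9)
        assert geom.area("intima_calcium") == pytest.approx(blob.area, rel=1e-2)

    def test_tiling_partition_invariant(self, annulus_geom, annulus_cs):
        wall = annulus_geom.outer_boundary.area - annulus_cs.lumen.area
        assert annulus_geom.total_area() == pytest.approx(wall, rel=1e-3)


class TestPartialIEL:
    def test_circle_with_quarter_removed(self):
        t = np.linspace(0, 1.5 * np.pi, 120)
        arc = np.column_stack([2.0 * np.cos(t), 2.0 * np.sin(t)])
        fit = complete_partial_iel(arc)
        r = np.hypot(*fit.points.T)
        assert np.allclose(r, 2.0, rtol=0.01)

    def test_half_ellipse_recovery(self):
        t = np.linspace(0, np.pi, 100)
        arc = np.column_stack([2.0 * np.cos(t), 1.6 * np.sin(t)])
        fit = complete_partial_iel(arc)
        x, y = fit.points[:, 0], fit.points[:, 1]
        assert np.allclose((x / 2.0) ** 2 + (y / 1.6) ** 2, 1.0, atol=0.03)

    def test_noisy_arc_residual_and_oracle(self):
        rng = np.random.default_rng(7)
        sigma = 0.020  # 20 um
        t = np.linspace(-0.2, 1.3 * np.pi, 200)
        arc = np.column_stack([1.8 * np.cos(t), 1.5 * np.sin(t)])
        arc += rng.normal(0, sigma, arc.shape)
        fit = complete_partial_iel(arc, n_vertices=720)
        # residual RMS of arc points against the fitted contour
        d = cdist(arc, fit.points).min(axis=1)
        assert np.sqrt(np.mean(d ** 2)) <= 2 * sigma
        # independent geometric fit oracle (scipy least squares)
        from scipy.optimize import least_squares
        def resid(q):
            cx, cy, a, b, th = q
            ca, sa = np.cos(th), np.sin(th)
            xr = (arc[:, 0] - cx) * ca + (arc[:, 1] - cy) * sa
            yr = -(arc[:, 0] - cx) * sa + (arc[:, 1] - cy) * ca
            return np.hypot(xr / a, yr / b) - 1.0
        sol = least_squares(resid, x0=[0, 0, 1.8, 1.5, 0.0])
        axes_oracle = np.sort(np.abs(sol.x[2:4]))
        x, y = fit.points[:, 0] - sol.x[0], fit.points[:, 1] - sol.x[1]
        half_width = np.sort([np.max(np.hypot(x, y)), np.min(np.hypot(x, y))])
        assert np.allclose(np.sort(half_width), axes_oracle, rtol=0.05)

    def test_short_arc_refused(self):
        t = np.linspace(0, 0.8 * np.pi, 50)
        arc = np.column_stack([np.cos(t), np.sin(t)])
        with pytest.raises(GeometryError, match="adjacent"):
            complete_partial_iel(arc)


class TestMorphometrics:
    def test_plaque_burden_formula(self):
        # the scale of an MLA frame: lumen 2.7 mm^2 inside IEL 8.74 mm^2
        lumen = Contour.circle(np.sqrt(2.7 / np.pi), n=256)
        iel = Contour.circle(np.sqrt(8.74 / np.pi), n=256)
        assert compute_plaque_burden(lumen, iel) == pytest.approx(69.1, abs=0.1)

    def test_burden_degenerate_and_bounds(self):
        c = Contour.circle(1.0)
        assert compute_plaque_burden(c, c) == pytest.approx(0.0, abs=1e-9)
        rng = np.random.default_rng(0)
        for _ in range(20):
            r1 = rng.uniform(0.5, 1.4)
            r2 = r1 + rng.uniform(0.05, 1.0)
            lumen = Contour.circle(r1, n=64)
            iel = Contour.circle(r2, n=64)
            pb = compute_plaque_burden(lumen, iel)
            assert 0.0 <= pb < 100.0
            oracle = 100 * (shoelace(iel.points) - shoelace(lumen.points)) \
                / shoelace(iel.points)
            assert pb == pytest.approx(oracle, rel=1e-12)

    def test_non_nested_rejected(self):
        with pytest.raises(GeometryError):
            compute_plaque_burden(Contour.circle(1.0, center=(5, 0)),
                                  Contour.circle(1.2))

    def test_cap_thickness_concentric(self):
        lumen = Contour.circle(1.50, n=256)
        region = PlaqueRegion("lipid", Contour.circle(1.65, n=256))
        assert measure_cap_thickness(lumen, region) == pytest.approx(150.0, abs=2.0)

    def test_cap_thickness_touching_and_missing(self):
        lumen = Contour.circle(1.5, n=128)
        touching = PlaqueRegion("lipid", Contour.circle(0.4, center=(1.9, 0), n=64))
        assert measure_cap_thickness(lumen, touching) == pytest.approx(0.0, abs=1.0)
        assert measure_cap_thickness(lumen, None) is None

    def test_cap_thickness_eccentric_vs_bruteforce(self):
        lumen = Contour.ellipse(1.4, 1.1, n=512)
        pool = Contour.ellipse(0.5, 0.2, center=(1.35, 0.9), angle=0.6, n=256)
        got = measure_cap_thickness(lumen, PlaqueRegion("lipid", pool))
        a = lumen.resample(4000).points
        b = pool.resample(4000).points
        brute = cdist(a, b).min() * 1000.0
        assert got == pytest.approx(brute, abs=1.0)
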