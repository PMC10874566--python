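"""Zone delineation, vertex centroids and cross-animal overlays."""

import math

import numpy as np
import pytest
import shapely
from conftest import make_cellset

from claumap import synthgen as sg
from claumap.stack_io import SliceMeta
from claumap.zones import (
    ZoneConfig,
    ZonePolygon,
    delineate_devoid_zone,
    delineate_enriched_zone,
    overlay_cohort,
    vertex_centroid,
)


def _gaussian_cluster(rng, n=200, center=(300.0, 300.0), sd=40.0):
    return rng.normal(center, sd, size=(n, 2))


def _in_polygon_fraction(poly: ZonePolygon, xy) -> float:
    shp = poly.as_shapely().buffer(1e-9)
    return float(shapely.contains_xy(shp, xy[:, 0], xy[:, 1]).mean())


class TestEnrichedZone:
    def test_containment_rule_on_tight_cluster(self):
        rng = np.random.default_rng(0)
        xy = _gaussian_cluster(rng)
        poly = delineate_enriched_zone(make_cellset(xy))
        assert poly.kind == "enriched"
        assert poly.contained_fraction >= 0.90
        assert _in_polygon_fraction(poly, xy) >= 0.90
        assert len(poly.vertices) <= 200

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        xy = _gaussian_cluster(rng)
        cfg = ZoneConfig()
        shift = np.array([5 * cfg.grid_um, -3 * cfg.grid_um])  # grid-aligned shift
        p0 = delineate_enriched_zone(make_cellset(xy), cfg)
        p1 = delineate_enriched_zone(make_cellset(xy + shift), cfg)
        assert np.allclose(p1.vertices, p0.vertices + shift, atol=1e-9)
        assert np.allclose(p1.centroid, p0.centroid + shift)

    def test_dense_ellipse_with_background_recovers_area(self):
        """Polygon area within 25% of the true ellipse, geometry oracle."""
        rng = np.random.default_rng(2)
        a, b = 200.0, 100.0
        n = 600
        r = np.sqrt(rng.uniform(size=n))
        phi = rng.uniform(0, 2 * math.pi, n)
        ell = np.column_stack([512 + a * r * np.cos(phi), 512 + b * r * np.sin(phi)])
        bg = rng.uniform(0, 1024, size=(60, 2))  # 10% uniform clutter
        poly = delineate_enriched_zone(make_cellset(np.vstack([ell, bg])))
        true_area = math.pi * a * b
        assert abs(poly.as_shapely().area - true_area) / true_area <= 0.25
        assert _in_polygon_fraction(poly, np.vstack([ell, bg])) >= 0.90

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="10"):
            delineate_enriched_zone(make_cellset(np.zeros((9, 2))))


class TestDevoidZone:
    def test_ring_yields_devoid_interior(self):
        """Tle4 ring around an empty ellipse: polygon covers the interior.

        The devoid margin must exceed the kernel bandwidth for the low-
        density region to reach the true ellipse boundary."""
        geom = sg.ClaustrumGeometry(
            center_um=(128.0, 128.0), axes_um=(60.0, 30.0), orientation_deg=20.0,
            ring_width_um=30.0, devoid_margin_um=20.0,
        )
        rng = np.random.default_rng(3)
        truth = sg.sample_cells(
            geom, {"ring": {"tle4": 8000.0}, "background": {"tle4": 1200.0}},
            {}, rng, frame_um=256.0, channels=("tle4",),
        )
        cells = sg.ground_truth_cellsets(truth)["tle4"]
        cfg = ZoneConfig(kde_bandwidth_um=10.0, grid_um=4.0)
        small_geometry = geom
        poly = delineate_devoid_zone(cells, small_geometry.center_um, cfg)
        assert poly.kind == "devoid"
        # sample the true ellipse interior and require >= 95% coverage
        r = np.sqrt(rng.uniform(size=400))
        phi = rng.uniform(0, 2 * math.pi, 400)
        th = math.radians(small_geometry.orientation_deg)
        u = small_geometry.axes_um[0] * r * np.cos(phi)
        v = small_geometry.axes_um[1] * r * np.sin(phi)
        pts = np.column_stack(
            [small_geometry.center_um[0] + u * math.cos(th) - v * math.sin(th),
             small_geometry.center_um[1] + u * math.sin(th) + v * math.cos(th)]
        )
        shp = poly.as_shapely().buffer(1e-9)
        assert shapely.contains_xy(shp, pts[:, 0], pts[:, 1]).mean() >= 0.95

    def test_uniform_labelling_has_no_devoid_region(self):
        rng = np.random.default_rng(4)
        xy = rng.uniform(0, 400, size=(800, 2))
        with pytest.raises(ValueError, match="devoid"):
            delineate_devoid_zone(make_cellset(xy, "tle4"), (200.0, 200.0))

    def test_far_corner_labelling_leaves_anchor_devoid(self):
        rng = np.random.default_rng(5)
        xy = rng.normal((60.0, 60.0), 15.0, size=(40, 2))
        poly = delineate_devoid_zone(make_cellset(xy, "tle4"), (512.0, 512.0))
        assert poly.as_shapely().buffer(1e-9).contains(shapely.Point(512.0, 512.0))


class TestVertexCentroid:
    def test_unit_square(self):
        p = ZonePolygon(np.array([[0, 0], [1, 0], [1, 1], [0, 1]]), kind="enriched")
        assert np.allclose(vertex_centroid(p), [0.5, 0.5])

    def test_subdivided_edge_pulls_centroid(self):
        """Vertex mean differs from the area centroid: extra collinear
        vertices on one edge drag the centroid toward it."""
        bottom = [[x / 10, 0.0] for x in range(11)]  # (0,0) .. (1,0) in 10 steps
        verts = np.array(bottom + [[1.0, 1.0], [0.0, 1.0]])
        p = ZonePolygon(verts, kind="enriched")
        c = vertex_centroid(p)
        assert c[0] == pytest.approx(0.5)
        assert c[1] == pytest.approx(2.0 / 13.0)  # 13 vertices, two at y=1
        assert abs(c[1] - 0.5) > 0.3  # clearly not the area centroid

    def test_translation(self):
        verts = np.array([[0, 0], [2, 0], [1, 3]], dtype=float)
        p = ZonePolygon(verts, kind="enriched")
        q = p.translated(10.0, -4.0)
        assert np.allclose(vertex_centroid(q), vertex_centroid(p) + [10.0, -4.0])

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            ZonePolygon(np.array([[0, 0], [1, 1]]), kind="enriched")


class TestOverlay:
    def _pair(self, shift=(0.0, 0.0), subdivision="anterior"):
        meta = SliceMeta(mouse_id="m", subdivision=subdivision)
        sq = np.array([[0, 0], [100, 0], [100, 100], [0, 100]], dtype=float)
        ref = ZonePolygon(sq + shift, kind="enriched", channel="retro", meta=meta)
        par = ZonePolygon(sq * 1.2 + shift, kind="enriched", channel="nr2f2", meta=meta)
        return ref, par

    def test_single_mouse_reference_at_origin(self):
        ov = overlay_cohort([self._pair(shift=(37.0, -12.0))], "anterior")
        ref = ov.polygons[0][0]
        assert np.allclose(ref.centroid, [0.0, 0.0], atol=1e-9)
        assert set(np.unique(ov.occupancy_reference)) <= {0, 1}

    def test_six_identical_mice_stack_to_six(self):
        ov = overlay_cohort([self._pair() for _ in range(6)], "anterior")
        assert ov.occupancy_reference.max() == 6
        inside = ov.occupancy_reference[ov.occupancy_reference > 0]
        assert (inside == 6).all()  # identical polygons agree everywhere

    def test_overlay_invariant_to_single_mouse_translation(self):
        ov1 = overlay_cohort([self._pair(), self._pair(shift=(250.0, 90.0))], "anterior")
        ov2 = overlay_cohort([self._pair(), self._pair()], "anterior")
        assert np.array_equal(ov1.occupancy_reference, ov2.occupancy_reference)

    def test_subdivision_mismatch_rejected(self):
        with pytest.raises(ValueError, match="subdivision"):
            overlay_cohort([self._pair(subdivision="middle")], "anterior")

    def test_cohort_reference_jaccard_after_alignment(self, small_config):
        """Aligned retro polygons of a jittered cohort overlap substantially."""
        pairs = []
        for mi in range(6):
            rng = np.random.default_rng(100 + mi)
            geom = sg.jittered_geometry(small_config.zone_geometry, rng)
            truth = sg.sample_cells(
                geom, {"enriched": {"retro": 6000.0}}, {}, rng,
                frame_um=256.0, channels=("retro",),
            )
            cells = sg.ground_truth_cellsets(truth)["retro"]
            cfg = ZoneConfig(kde_bandwidth_um=12.0, grid_um=4.0)
            poly = delineate_enriched_zone(cells, cfg)
            pairs.append((poly, poly))
        ov = overlay_cohort(pairs, "anterior", grid_um=4.0)
        # rasterized pairwise Jaccard oracle on the occupancy grid
        gx, gy = np.meshgrid(ov.grid_x_um, ov.grid_y_um)
        masks = [
            shapely.contains_xy(r.as_shapely(), gx.ravel(), gy.ravel())
            for r, _ in ov.polygons
        ]
        jac = []
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                inter = (masks[i] & masks[j]).sum()
                union = (masks[i] | masks[j]).sum()
                jac.append(inter / union)
        assert np.mean(jac) >= 0.5
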