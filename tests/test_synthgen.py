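"""Ground-truth generator: point sampling, memberships, rendering, cohorts."""

import math

import numpy as np
import pandas as pd
import pytest

from claumap import synthgen as sg
from claumap.stack_io import max_project


def _sample(geom, densities, fractions, seed=0, frame_um=256.0, channels=("retro", "nurr1", "tle4")):
    rng = np.random.default_rng(seed)
    return sg.sample_cells(geom, densities, fractions, rng, frame_um=frame_um, channels=channels)


class TestSampleCells:
    def test_zero_densities_give_zero_cells(self, small_geometry):
        truth = _sample(small_geometry, {z: {} for z in ("enriched", "ring", "background")}, {})
        assert len(truth.cells) == 0

    def test_unit_fraction_forces_full_comembership(self, small_geometry):
        truth = _sample(
            small_geometry,
            {"enriched": {"retro": 3000.0}},
            {("retro", "nurr1"): 1.0},
            seed=3,
        )
        retro = truth.members("retro")
        assert len(retro) > 0
        assert retro["member_nurr1"].all()

    def test_binomial_fraction_recovery(self, small_geometry):
        """Realized |A∩B|/|A| converges to f within 3 binomial SE (n >= 10000)."""
        f = 0.87
        n_ab = n_a = 0
        seed = 0
        while n_a < 10000:
            truth = _sample(
                small_geometry, {"enriched": {"retro": 5000.0}}, {("retro", "nurr1"): f}, seed=seed
            )
            retro = truth.members("retro")
            n_a += len(retro)
            n_ab += int(retro["member_nurr1"].sum())
            seed += 1
        se = math.sqrt(f * (1 - f) / n_a)
        assert abs(n_ab / n_a - f) <= 3 * se

    def test_zone_labels_match_point_in_region_oracle(self, small_geometry):
        truth = _sample(
            small_geometry,
            {
                "enriched": {"retro": 3000.0},
                "ring": {"tle4": 3000.0},
                "background": {"nurr1": 500.0},
            },
            {},
            seed=5,
        )
        g = small_geometry
        th = math.radians(g.orientation_deg)

        def norm_r(x, y, grow):
            dx, dy = x - g.center_um[0], y - g.center_um[1]
            u = dx * math.cos(th) + dy * math.sin(th)
            v = -dx * math.sin(th) + dy * math.cos(th)
            return math.hypot(u / (g.axes_um[0] + grow), v / (g.axes_um[1] + grow))

        for _, c in truth.cells.iterrows():
            if c["zone"] == "enriched":
                assert norm_r(c["x_um"], c["y_um"], 0.0) <= 1.0 + 1e-9
            elif c["zone"] == "ring":
                assert norm_r(c["x_um"], c["y_um"], g.devoid_margin_um) > 1.0 - 1e-9
                assert norm_r(c["x_um"], c["y_um"], g.devoid_margin_um + g.ring_width_um) <= 1.0 + 1e-9

    def test_all_cells_inside_frame(self, small_geometry):
        truth = _sample(
            small_geometry,
            {"background": {"tle4": 2000.0}, "ring": {"tle4": 2000.0}},
            {},
            seed=2,
        )
        assert (truth.cells["x_um"].between(0, 256)).all()
        assert (truth.cells["y_um"].between(0, 256)).all()

    def test_oversized_ellipse_raises_with_dimension(self, small_geometry):
        big = sg.ClaustrumGeometry(center_um=(128.0, 128.0), axes_um=(300.0, 30.0))
        with pytest.raises(ValueError, match="along x"):
            _sample(big, {"enriched": {"retro": 100.0}}, {})

    def test_determinism(self, small_geometry):
        d = {"enriched": {"retro": 2000.0}, "ring": {"tle4": 1000.0}}
        f = {("retro", "tle4"): 0.3}
        t1 = _sample(small_geometry, d, f, seed=11)
        t2 = _sample(small_geometry, d, f, seed=11)
        pd.testing.assert_frame_equal(t1.cells, t2.cells)


class TestRenderSlice:
    def test_no_cells_no_noise_renders_zero(self, small_config):
        cfg = sg.GeneratorConfig(
            frame_px=64, noise_gauss_sd=0.0, noise_poisson_gain=0.0,
            zone_geometry=sg.ClaustrumGeometry(center_um=(32, 32), axes_um=(10, 5)),
            densities={}, coloc_fractions={}, channels=("retro",),
        )
        truth = _sample(cfg.zone_geometry, {}, {}, frame_um=64.0, channels=("retro",))
        vol = sg.render_slice(truth, cfg)
        assert vol.data.shape == (1, 11, 64, 64)
        assert vol.data.max() == 0

    def test_single_cell_spot_peaks_at_true_centroid(self):
        cfg = sg.GeneratorConfig(
            frame_px=64, noise_gauss_sd=0.0, noise_poisson_gain=0.0,
            zone_geometry=sg.ClaustrumGeometry(center_um=(32, 32), axes_um=(10, 5)),
            densities={}, coloc_fractions={}, channels=("retro",),
        )
        cells = pd.DataFrame(
            {"id": [0], "x_um": [20.3], "y_um": [41.7], "z_um": [10.0],
             "zone": ["enriched"], "primary_channel": ["retro"], "member_retro": [True]}
        )
        truth = sg.GroundTruth(cells=cells, geometry=cfg.zone_geometry, channels=("retro",))
        proj = max_project(sg.render_slice(truth, cfg), "retro")
        iy, ix = np.unravel_index(np.argmax(proj.data), proj.data.shape)
        assert abs(ix - 20.3) <= 1.0 and abs(iy - 41.7) <= 1.0

    def test_equal_integrated_intensity_per_spot(self):
        """Non-overlapping cells deposit equal mass across the whole stack."""
        rng = np.random.default_rng(4)
        n = 50
        frame = 512
        from conftest import nonoverlapping_points

        pts = nonoverlapping_points(rng, n, frame, min_sep_um=45.0)
        cfg = sg.GeneratorConfig(
            frame_px=frame, noise_gauss_sd=0.0, noise_poisson_gain=0.0,
            zone_geometry=sg.ClaustrumGeometry(center_um=(256, 256), axes_um=(50, 25)),
            densities={}, coloc_fractions={}, channels=("retro",),
        )
        cells = pd.DataFrame(
            {"id": np.arange(n), "x_um": pts[:, 0], "y_um": pts[:, 1],
             "z_um": rng.uniform(0, 20, n), "zone": "background",
             "primary_channel": "retro", "member_retro": True}
        )
        truth = sg.GroundTruth(cells=cells, geometry=cfg.zone_geometry, channels=("retro",))
        stack = sg.render_slice(truth, cfg).data[0].astype(float)
        total = stack.sum(axis=0)
        masses = []
        for x, y in pts:
            xi, yi = int(round(x)), int(round(y))
            masses.append(total[yi - 22 : yi + 23, xi - 22 : xi + 23].sum())
        masses = np.asarray(masses)
        assert masses.std() / masses.mean() < 0.01

    def test_render_deterministic_for_seed(self, small_config, small_geometry):
        truth = _sample(small_geometry, {"enriched": {"retro": 2000.0}}, {}, seed=9)
        v1 = sg.render_slice(truth, small_config, channels=("retro",), rng=np.random.default_rng(1))
        v2 = sg.render_slice(truth, small_config, channels=("retro",), rng=np.random.default_rng(1))
        assert np.array_equal(v1.data, v2.data)


class TestConfig:
    def test_plane_count_follows_z_range(self):
        assert sg.GeneratorConfig().n_z == 11  # 2 um steps over a 20 um volume
        assert sg.GeneratorConfig(z_depth_um=10.0, z_step_um=2.0).n_z == 6
        with pytest.raises(ValueError, match="n_z"):
            sg.GeneratorConfig(n_z=10)

    def test_invalid_fractions_and_densities_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            sg.GeneratorConfig(coloc_fractions={("retro", "nurr1"): 1.2})
        with pytest.raises(ValueError, match="negative"):
            sg.GeneratorConfig(densities={"enriched": {"retro": -1.0}})


class TestGenerateCohort:
    def test_counts_and_manifest(self, small_config, tmp_path):
        man = sg.generate_cohort(small_config, n_mice=1, slices_per_subdivision=1, out_dir=tmp_path)
        assert len(man) == 3
        assert sorted(man["subdivision"]) == ["anterior", "middle", "posterior"]
        assert len(list(tmp_path.glob("*.tif"))) == 3
        assert len(list(tmp_path.glob("*_truth.csv"))) == 3
        assert (tmp_path / "manifest.csv").exists()
        for _, row in man.iterrows():
            lo, hi = sg.SUBDIVISION_AP_MM[row["subdivision"]]
            assert lo <= row["ap_mm"] <= hi

    def test_default_layout_is_six_slices_per_mouse(self, small_config, tmp_path):
        # 6 mice x (2 slices x 3 subdivisions) = 36 stacks
        man = sg.generate_cohort(small_config, n_mice=6, out_dir=tmp_path)
        assert len(man) == 36
        assert len(list(tmp_path.glob("*.tif"))) == 36

    def test_same_master_seed_reproduces_truth_tables(self, small_config, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sg.generate_cohort(small_config, 1, 1, d1, master_seed=5)
        sg.generate_cohort(small_config, 1, 1, d2, master_seed=5)
        for f1 in sorted(d1.glob("*_truth.csv")):
            f2 = d2 / f1.name
            assert f1.read_bytes() == f2.read_bytes()
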