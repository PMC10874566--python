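import numpy as np
import pandas as pd
import pytest

from claumap.detect import CellSet
from claumap.stack_io import SliceMeta
from claumap.synthgen import ClaustrumGeometry, GeneratorConfig


def make_small_geometry() -> ClaustrumGeometry:
    return ClaustrumGeometry(
        center_um=(128.0, 128.0),
        axes_um=(60.0, 30.0),
        orientation_deg=20.0,
        ring_width_um=30.0,
        devoid_margin_um=10.0,
    )


def make_small_config(small_geometry: ClaustrumGeometry) -> GeneratorConfig:
    """Quarter-scale slice (256 um frame) for fast end-to-end tests."""
    return GeneratorConfig(
        frame_px=256,
        zone_geometry=small_geometry,
        densities={
            "enriched": {"retro": 4000.0, "nurr1": 800.0, "cfos": 500.0},
            "ring": {"tle4": 4000.0, "nurr1": 400.0, "cfos": 300.0},
            "background": {"tle4": 800.0, "nurr1": 200.0, "cfos": 200.0},
        },
        channels=("retro", "nurr1", "tle4", "cfos"),
        coloc_fractions={
            ("retro", "nurr1"): 0.87,
            ("retro", "tle4"): 0.01,
            ("nurr1", "cfos"): 0.10,
        },
        seed=7,
    )


@pytest.fixture
def small_geometry() -> ClaustrumGeometry:
    return make_small_geometry()


@pytest.fixture
def small_config(small_geometry) -> GeneratorConfig:
    return make_small_config(small_geometry)


def make_cellset(xy, channel="retro", slice_id="s0", mouse_id="m0", subdivision=None, ap_mm=1.0):
    """CellSet from an (n, 2) array of centroids in um."""
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    df = pd.DataFrame(
        {
            "id": np.arange(len(xy)),
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "area_um2": 50.0,
            "mean_intensity": 1.0,
        }
    )
    meta = SliceMeta(mouse_id=mouse_id, slice_id=slice_id, subdivision=subdivision, ap_mm=ap_mm)
    return CellSet(channel=channel, cells=df, meta=meta)


def nonoverlapping_points(rng, n, frame_um, min_sep_um, margin_um=30.0):
    """Rejection-sample n points at pairwise distance >= min_sep_um."""
    pts: list[np.ndarray] = []
    while len(pts) < n:
        p = rng.uniform(margin_um, frame_um - margin_um, size=2)
        if all(np.hypot(*(p - q)) >= min_sep_um for q in pts):
            pts.append(p)
    return np.asarray(pts)
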