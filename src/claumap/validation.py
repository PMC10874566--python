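"""Self-validation on synthetic ground truth.

Convenience routines that exercise the full pipeline against the generator's
known ground truth: enriched-zone containment, colocalization-fraction
recovery, detection fidelity, and profile alignment.  They are what the
repository's reproduction script runs, and they are handy when tuning
generator or detection parameters for new geometries.
"""

from __future__ import annotations

import math

import numpy as np

from . import synthgen as sg
from .coloc import match_cells, venn_counts
from .detect import DetectionConfig, detect_cells
from .profiles import AxisSpec, profile_axis, realign_and_average, zscore
from .stack_io import SliceMeta, max_project
from .zones import ZoneConfig, delineate_enriched_zone

__all__ = [
    "enrichment_containment",
    "fraction_recovery",
    "detection_fidelity",
    "aligned_cohort_envelope",
]


def _slice_rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def enrichment_containment(
    seeds,
    config: sg.GeneratorConfig | None = None,
    detection: DetectionConfig | None = None,
    zone: ZoneConfig | None = None,
) -> list[float]:
    """Contained fraction of detected retro cells per synthetic slice.

    For each seed: generate a slice at the configured defaults, render the
    retro channel, detect cells on the max projection, delineate the
    enriched zone, and measure the fraction of detected cells inside the
    polygon with an exact point-in-polygon test.
    """
    import shapely

    config = config or sg.GeneratorConfig()
    detection = detection or DetectionConfig()
    zone = zone or ZoneConfig()
    fractions = []
    for seed in seeds:
        rng = _slice_rng(seed)
        truth = sg.sample_cells(
            config.zone_geometry,
            config.densities,
            config.coloc_fractions,
            rng,
            frame_um=config.frame_um,
            z_depth_um=config.z_depth_um,
            channels=config.channels,
        )
        vol = sg.render_slice(truth, config, channels=("retro",), rng=rng)
        cells = detect_cells(max_project(vol, "retro"), detection)
        poly = delineate_enriched_zone(cells, zone)
        xy = cells.xy_um
        inside = shapely.contains_xy(poly.as_shapely().buffer(1e-9), xy[:, 0], xy[:, 1])
        fractions.append(float(inside.mean()))
    return fractions


def fraction_recovery(
    f: float,
    min_cells: int = 2000,
    seed: int = 0,
    match_radius_um: float = 5.0,
) -> tuple[float, int]:
    """Pooled retro/Tle4 colocalization estimate over generated slices.

    Slices at the default densities with f(retro, tle4) = ``f`` are pooled
    until at least ``min_cells`` retro cells have been seen; returns
    (estimated fraction, n cells).  Tle4 has no independent cells inside the
    enriched zone, so chance matches are negligible and the estimator is
    binomial to a good approximation.
    """
    fractions = {("retro", "tle4"): f}
    n_a = n_ab = 0
    i = 0
    while n_a < min_cells:
        rng = _slice_rng((seed, i))
        truth = sg.sample_cells(
            sg.ClaustrumGeometry(), sg.default_densities(), fractions, rng
        )
        sets = sg.ground_truth_cellsets(truth, SliceMeta(slice_id=f"s{i}"))
        cc = venn_counts(match_cells(sets["retro"], sets["tle4"], match_radius_um))
        n_a += cc.n_a
        n_ab += cc.n_ab
        i += 1
    return n_ab / n_a, n_a


def detection_fidelity(
    n_cells: int = 30,
    seed: int = 0,
    frame_px: int = 512,
    min_sep_um: float = 30.0,
) -> dict[str, float]:
    """Recall, precision and centroid error on a zero-noise sparse slice.

    Ground-truth matching uses the cell radius as the match distance.
    """
    import pandas as pd

    cfg = sg.GeneratorConfig(
        frame_px=frame_px,
        noise_gauss_sd=0.0,
        noise_poisson_gain=0.0,
        zone_geometry=sg.ClaustrumGeometry(
            center_um=(frame_px / 2.0, frame_px / 2.0), axes_um=(50.0, 25.0)
        ),
        densities={},
        coloc_fractions={},
        channels=("retro",),
    )
    rng = _slice_rng(seed)
    pts: list[np.ndarray] = []
    while len(pts) < n_cells:
        p = rng.uniform(30.0, cfg.frame_um - 30.0, size=2)
        if all(np.hypot(*(p - q)) >= min_sep_um for q in pts):
            pts.append(p)
    pts = np.asarray(pts)
    cells = pd.DataFrame(
        {
            "id": np.arange(n_cells),
            "x_um": pts[:, 0],
            "y_um": pts[:, 1],
            "z_um": rng.uniform(2.0, cfg.z_depth_um - 2.0, n_cells),
            "zone": "background",
            "primary_channel": "retro",
            "member_retro": True,
        }
    )
    truth = sg.GroundTruth(cells=cells, geometry=cfg.zone_geometry, channels=("retro",))
    det = detect_cells(max_project(sg.render_slice(truth, cfg), "retro"))
    xy = det.xy_um
    radius = cfg.cell_radius_um
    hits = 0
    errs = []
    used = np.zeros(len(xy), dtype=bool)
    for p in pts:
        if len(xy) == 0:
            break
        d = np.hypot(xy[:, 0] - p[0], xy[:, 1] - p[1])
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= radius:
            hits += 1
            used[j] = True
            errs.append(float(d[j]))
    recall = hits / n_cells
    precision = hits / len(xy) if len(xy) else 0.0
    return {
        "recall": recall,
        "precision": precision,
        "max_centroid_error_um": max(errs) if errs else math.inf,
        "n_true": n_cells,
        "n_detected": len(xy),
    }


def aligned_cohort_envelope(
    n_slices: int = 12,
    seed: int = 0,
    config: sg.GeneratorConfig | None = None,
    channels: tuple[str, ...] = ("retro", "tle4"),
    jitter: bool = True,
):
    """Peak-aligned cohort profiles perpendicular to the claustrum axis.

    Generates ``n_slices`` slices (per-slice anatomical jitter as in cohort
    generation), profiles the requested channels along the axis
    perpendicular to the slice's orientation through the zone centre,
    z-scores, realigns to the retro peak and averages.  Returns the
    envelope table together with the per-slice profiles.
    """
    config = config or sg.GeneratorConfig()
    slice_profiles = []
    for i in range(n_slices):
        rng = _slice_rng((seed, i))
        geom = sg.jittered_geometry(config.zone_geometry, rng) if jitter else config.zone_geometry
        truth = sg.sample_cells(
            geom,
            config.densities,
            config.coloc_fractions,
            rng,
            frame_um=config.frame_um,
            z_depth_um=config.z_depth_um,
            channels=config.channels,
        )
        vol = sg.render_slice(truth, config, channels=channels, rng=rng)
        ax = AxisSpec(
            origin_um=geom.center_um, direction_deg=geom.orientation_deg
        ).perpendicular()
        slice_profiles.append(
            {ch: zscore(profile_axis(max_project(vol, ch), ax)) for ch in channels}
        )
    env = realign_and_average(slice_profiles, "retro")
    return env, slice_profiles
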