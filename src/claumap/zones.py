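"""Enriched/devoid zone polygons and cross-animal centroid registration.

The operator step of outlining "the zone enriched with labelled cells" is
replaced by a kernel-density superlevel set: the retro (or marker) cell
centroids are smoothed with a Gaussian kernel on a regular grid and the
polygon is the outer contour of the largest connected region above the
highest density level that still contains at least the configured fraction
(default 90%) of the cells.  The devoid zone is the complementary
construction on Tle4 centroids: the connected low-density region (relative
to the median density where Tle4 cells sit) that contains a given anchor.

Polygon centroids are the unweighted mean of the vertex coordinates — not
the area centroid — and cross-animal overlays translate each mouse's
polygon pair so that the reference (retro) polygon's vertex centroid sits at
the origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter, map_coordinates
from shapely.geometry import Polygon
from skimage.measure import find_contours, label

from .detect import CellSet
from .stack_io import SliceMeta

__all__ = [
    "ZoneConfig",
    "ZonePolygon",
    "ZoneOverlay",
    "delineate_enriched_zone",
    "delineate_devoid_zone",
    "vertex_centroid",
    "overlay_cohort",
]

MAX_VERTICES = 200


@dataclass
class ZoneConfig:
    enrichment_fraction: float = 0.90
    kde_bandwidth_um: float = 25.0
    grid_um: float = 8.0
    devoid_rel_threshold: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 < self.enrichment_fraction < 1.0):
            raise ValueError("enrichment_fraction must lie in (0, 1)")
        if self.kde_bandwidth_um <= 0 or self.grid_um <= 0:
            raise ValueError("bandwidth and grid spacing must be positive")
        if not (0.0 < self.devoid_rel_threshold < 1.0):
            raise ValueError("devoid_rel_threshold must lie in (0, 1)")


@dataclass
class ZonePolygon:
    """A closed polygon (vertices in um, open ring) delineating a zone."""

    vertices: np.ndarray  # (n, 2) x/y um; implicitly closed
    kind: str  # "enriched" or "devoid"
    channel: str = ""
    contained_fraction: float = float("nan")
    meta: SliceMeta = field(default_factory=SliceMeta)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 (x, y) vertices")
        # drop an explicit closing vertex so the centroid is over distinct vertices
        if np.allclose(self.vertices[0], self.vertices[-1]):
            self.vertices = self.vertices[:-1]
        if len(self.vertices) < 3:
            raise ValueError("degenerate polygon")

    @property
    def centroid(self) -> np.ndarray:
        """Vertex centroid: arithmetic mean of the vertex coordinates."""
        return self.vertices.mean(axis=0)

    def as_shapely(self) -> Polygon:
        return Polygon(self.vertices)

    def translated(self, dx: float, dy: float) -> "ZonePolygon":
        return ZonePolygon(
            vertices=self.vertices + np.array([dx, dy]),
            kind=self.kind,
            channel=self.channel,
            contained_fraction=self.contained_fraction,
            meta=self.meta,
        )

    def to_geojson(self, path: str | Path) -> Path:
        path = Path(path)
        ring = np.vstack([self.vertices, self.vertices[:1]])
        obj = {
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring.tolist()]},
            "properties": {
                "kind": self.kind,
                "channel": self.channel,
                "contained_fraction": self.contained_fraction,
                "units": "um",
                "meta": self.meta.to_dict(),
            },
        }
        path.write_text(json.dumps(obj))
        return path

    @classmethod
    def from_geojson(cls, path: str | Path) -> "ZonePolygon":
        obj = json.loads(Path(path).read_text())
        props = obj.get("properties", {})
        return cls(
            vertices=np.asarray(obj["geometry"]["coordinates"][0], dtype=float),
            kind=props.get("kind", ""),
            channel=props.get("channel", ""),
            contained_fraction=props.get("contained_fraction", float("nan")),
            meta=SliceMeta.from_dict(props.get("meta", {})),
        )


def vertex_centroid(p: ZonePolygon) -> np.ndarray:
    """Unweighted mean of the polygon's vertices (NOT the area centroid)."""
    return p.centroid


@dataclass
class ZoneOverlay:
    """Centroid-registered polygons of a cohort plus a gridded occupancy map."""

    subdivision: str
    reference_channel: str
    pairing: str
    polygons: list[tuple[ZonePolygon, ZonePolygon]]  # translated (reference, partner)
    grid_x_um: np.ndarray
    grid_y_um: np.ndarray
    occupancy_reference: np.ndarray  # (ny, nx) counts of mice covering each point
    occupancy_partner: np.ndarray


class _KDEGrid:
    """Gaussian KDE of a point set on a grid anchored at multiples of grid_um."""

    def __init__(self, xy: np.ndarray, bandwidth_um: float, grid_um: float,
                 include: np.ndarray | None = None):
        pad = 4.0 * bandwidth_um
        pts = xy if include is None else np.vstack([xy, include])
        x0 = np.floor((pts[:, 0].min() - pad) / grid_um) * grid_um
        y0 = np.floor((pts[:, 1].min() - pad) / grid_um) * grid_um
        x1 = np.ceil((pts[:, 0].max() + pad) / grid_um) * grid_um
        y1 = np.ceil((pts[:, 1].max() + pad) / grid_um) * grid_um
        self.grid_um = grid_um
        self.x = np.arange(x0, x1 + grid_um / 2, grid_um)
        self.y = np.arange(y0, y1 + grid_um / 2, grid_um)
        hist = np.zeros((len(self.y), len(self.x)))
        ix = np.rint((xy[:, 0] - x0) / grid_um).astype(int)
        iy = np.rint((xy[:, 1] - y0) / grid_um).astype(int)
        np.add.at(hist, (iy, ix), 1.0)
        self.density = gaussian_filter(hist, sigma=bandwidth_um / grid_um, truncate=4.0)
        self.x0, self.y0 = x0, y0

    def at(self, xy: np.ndarray) -> np.ndarray:
        cols = (xy[:, 0] - self.x0) / self.grid_um
        rows = (xy[:, 1] - self.y0) / self.grid_um
        return map_coordinates(self.density, np.vstack([rows, cols]), order=1, mode="nearest")


def _mask_to_polygon(mask: np.ndarray, kde: _KDEGrid, tol_um: float) -> Polygon | None:
    """Outer contour of a binary grid mask as a simplified shapely polygon."""
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        return None
    best, best_area = None, -1.0
    for c in contours:
        ring = np.column_stack(
            [(c[:, 1] - 1.0) * kde.grid_um + kde.x0, (c[:, 0] - 1.0) * kde.grid_um + kde.y0]
        )
        if len(ring) < 4:
            continue
        poly = Polygon(ring)
        if not poly.is_valid:
            poly = poly.buffer(0)
            if poly.geom_type == "MultiPolygon":
                poly = max(poly.geoms, key=lambda g: g.area)
        if poly.area > best_area:
            best, best_area = poly, poly.area
    if best is None:
        return None
    while True:
        simp = best.simplify(tol_um, preserve_topology=True)
        if len(simp.exterior.coords) - 1 <= MAX_VERTICES:
            return simp
        tol_um *= 2.0


def _contained_fraction(poly: Polygon, xy: np.ndarray) -> float:
    if len(xy) == 0:
        return float("nan")
    inside = shapely.contains_xy(poly.buffer(1e-9), xy[:, 0], xy[:, 1])
    return float(inside.mean())


def delineate_enriched_zone(cells: CellSet, cfg: ZoneConfig | None = None) -> ZonePolygon:
    """Polygon around the densest region containing >= the target cell fraction.

    The density threshold is chosen as the highest level whose largest
    connected superlevel region contains at least ``enrichment_fraction`` of
    the cells (verified by an exact point-in-polygon test on the simplified
    contour); ties between regions are broken by area, the zone being a
    single blob in practice.
    """
    cfg = cfg or ZoneConfig()
    if len(cells) < 10:
        raise ValueError(f"enriched zone undefined with {len(cells)} < 10 cells")
    xy = cells.xy_um
    kde = _KDEGrid(xy, cfg.kde_bandwidth_um, cfg.grid_um)
    levels = np.unique(kde.at(xy))[::-1]
    for t in levels:
        mask = kde.density >= t
        lab = label(mask)
        if lab.max() == 0:
            continue
        largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
        poly = _mask_to_polygon(lab == largest, kde, cfg.grid_um / 2.0)
        if poly is None:
            continue
        frac = _contained_fraction(poly, xy)
        if frac >= cfg.enrichment_fraction:
            return ZonePolygon(
                vertices=np.asarray(poly.exterior.coords)[:-1],
                kind="enriched",
                channel=cells.channel,
                contained_fraction=frac,
                meta=cells.meta,
            )
    raise ValueError(
        "no single connected region contains the target cell fraction "
        "(cells too scattered for an enriched zone)"
    )


def delineate_devoid_zone(
    tle4_cells: CellSet, anchor: tuple[float, float], cfg: ZoneConfig | None = None
) -> ZonePolygon:
    """Polygon around the low-density (devoid) region containing ``anchor``.

    The devoid region is the connected component of
    {density <= devoid_rel_threshold x median density at the Tle4 cells}
    that contains the anchor (the retro enriched-zone centroid in the
    pipeline).  An anchor inside normally-dense labelling is an error.
    """
    cfg = cfg or ZoneConfig()
    if len(tle4_cells) < 10:
        raise ValueError(f"devoid zone undefined with {len(tle4_cells)} < 10 cells")
    anchor = np.asarray(anchor, dtype=float)
    xy = tle4_cells.xy_um
    kde = _KDEGrid(xy, cfg.kde_bandwidth_um, cfg.grid_um, include=anchor[None, :])
    ref = float(np.median(kde.at(xy)))
    thr = cfg.devoid_rel_threshold * ref
    mask = kde.density <= thr
    lab = label(mask)
    col = int(np.rint((anchor[0] - kde.x0) / kde.grid_um))
    row = int(np.rint((anchor[1] - kde.y0) / kde.grid_um))
    if not (0 <= row < lab.shape[0] and 0 <= col < lab.shape[1]) or lab[row, col] == 0:
        raise ValueError("anchor does not lie in any sub-threshold (devoid) region")
    poly = _mask_to_polygon(lab == lab[row, col], kde, cfg.grid_um / 2.0)
    if poly is None:
        raise ValueError("devoid region too small to outline")
    return ZonePolygon(
        vertices=np.asarray(poly.exterior.coords)[:-1],
        kind="devoid",
        channel=tle4_cells.channel,
        contained_fraction=_contained_fraction(poly, xy),
        meta=tle4_cells.meta,
    )


def overlay_cohort(
    polygon_pairs: list[tuple[ZonePolygon, ZonePolygon]],
    subdivision: str,
    grid_um: float = 8.0,
    pairing: str = "",
) -> ZoneOverlay:
    """Overlay per-mouse polygon pairs aligned on the reference centroid.

    Each pair is (reference polygon, partner polygon) from the same slice;
    both are translated by minus the reference polygon's vertex centroid, so
    every translated reference centroid sits at the origin.  Occupancy maps
    count, per grid point, how many mice's polygons cover it.
    """
    if not polygon_pairs:
        raise ValueError("no polygon pairs to overlay")
    moved: list[tuple[ZonePolygon, ZonePolygon]] = []
    for ref, partner in polygon_pairs:
        for p in (ref, partner):
            if p.meta.subdivision and p.meta.subdivision != subdivision:
                raise ValueError(
                    f"polygon from subdivision {p.meta.subdivision!r} in {subdivision!r} overlay"
                )
        c = ref.centroid
        moved.append((ref.translated(-c[0], -c[1]), partner.translated(-c[0], -c[1])))

    allv = np.vstack([np.vstack([r.vertices, p.vertices]) for r, p in moved])
    pad = 2 * grid_um
    x = np.arange(np.floor(allv[:, 0].min() - pad), np.ceil(allv[:, 0].max() + pad) + grid_um, grid_um)
    y = np.arange(np.floor(allv[:, 1].min() - pad), np.ceil(allv[:, 1].max() + pad) + grid_um, grid_um)
    gx, gy = np.meshgrid(x, y)
    occ_ref = np.zeros(gx.shape, dtype=int)
    occ_par = np.zeros(gx.shape, dtype=int)
    for r, p in moved:
        occ_ref += shapely.contains_xy(r.as_shapely(), gx.ravel(), gy.ravel()).reshape(gx.shape)
        occ_par += shapely.contains_xy(p.as_shapely(), gx.ravel(), gy.ravel()).reshape(gx.shape)
    ref_ch = moved[0][0].channel
    par_ch = moved[0][1].channel
    return ZoneOverlay(
        subdivision=subdivision,
        reference_channel=ref_ch,
        pairing=pairing or f"{ref_ch}/{par_ch}",
        polygons=moved,
        grid_x_um=x,
        grid_y_um=y,
        occupancy_reference=occ_ref,
        occupancy_partner=occ_par,
    )
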