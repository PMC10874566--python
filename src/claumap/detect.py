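"""Automated cell detection on maximum-intensity projections.

Fixed pipeline: Gaussian smoothing, global threshold (Otsu by default),
connected components, watershed splitting of touching components at local
maxima separated by at least ``min_separation_um``, an area filter, and
intensity-weighted (sub-pixel) centroids reported in micrometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import watershed

from .stack_io import ProjectionImage, SliceMeta

__all__ = ["DetectionConfig", "CellSet", "detect_cells", "count_summary"]


@dataclass
class DetectionConfig:
    smooth_sigma_um: float = 1.0
    threshold_mode: str = "otsu"  # or "fixed"
    fixed_threshold: float = 0.0
    min_area_um2: float = 10.0
    max_area_um2: float = 1000.0
    min_separation_um: float = 6.0

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError("threshold_mode must be 'otsu' or 'fixed'")
        if not self.min_area_um2 < self.max_area_um2:
            raise ValueError("min_area_um2 must be < max_area_um2")
        if self.min_separation_um < 0:
            raise ValueError("min_separation_um must be >= 0")


@dataclass
class CellSet:
    """Detected cells for one channel of one slice.

    ``cells`` columns: id, x_um, y_um, area_um2, mean_intensity.
    """

    channel: str
    cells: pd.DataFrame
    meta: SliceMeta = field(default_factory=SliceMeta)

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def xy_um(self) -> np.ndarray:
        return self.cells[["x_um", "y_um"]].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = self.cells.copy()
        df.insert(0, "channel", self.channel)
        for k, v in self.meta.to_dict().items():
            df[k] = v
        df.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "CellSet":
        df = pd.read_csv(path)
        meta = SliceMeta.from_dict(
            {k: df[k].iloc[0] for k in df.columns if k in SliceMeta().to_dict()}
        ) if len(df) else SliceMeta()
        channel = df["channel"].iloc[0] if len(df) else ""
        keep = ["id", "x_um", "y_um", "area_um2", "mean_intensity"]
        cells = df[keep] if len(df) else pd.DataFrame(columns=keep)
        return cls(channel=channel, cells=cells.reset_index(drop=True), meta=meta)


def _empty_cells() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": pd.Series(dtype=int),
            "x_um": pd.Series(dtype=float),
            "y_um": pd.Series(dtype=float),
            "area_um2": pd.Series(dtype=float),
            "mean_intensity": pd.Series(dtype=float),
        }
    )


def detect_cells(img: ProjectionImage, cfg: DetectionConfig | None = None) -> CellSet:
    """Detect labelled cells in a projection image.

    Deterministic; an empty or constant image yields an empty set.
    """
    cfg = cfg or DetectionConfig()
    data = np.asarray(img.data, dtype=float)
    if np.any(data < 0):
        raise ValueError("projection image must be nonnegative")
    px = img.pixel_um
    empty = CellSet(channel=img.channel, cells=_empty_cells(), meta=img.meta)

    sm = gaussian(data, sigma=cfg.smooth_sigma_um / px, preserve_range=True)
    if sm.max() == sm.min():
        if sm.max() > 0:
            warnings.warn("constant (saturated) image: no cells detected", stacklevel=2)
        return empty
    thr = threshold_otsu(sm) if cfg.threshold_mode == "otsu" else cfg.fixed_threshold
    mask = sm > thr
    if not mask.any():
        return empty

    comp = label(mask)
    min_dist = max(int(round(cfg.min_separation_um / px)), 1)
    peaks = peak_local_max(sm, min_distance=min_dist, labels=comp, exclude_border=False)
    if len(peaks) == 0:
        labels = comp
    else:
        markers = np.zeros_like(comp)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-sm, markers=markers, mask=mask)
        # components that received no marker (flat plateaus) keep their own id
        orphan = mask & (labels == 0)
        if orphan.any():
            labels = np.where(orphan, comp + labels.max(), labels)

    rows = []
    for i, rp in enumerate(regionprops(labels, intensity_image=data)):
        area = rp.area * px * px
        if not (cfg.min_area_um2 <= area <= cfg.max_area_um2):
            continue
        cy, cx = rp.centroid_weighted
        rows.append(
            {
                "id": len(rows),
                "x_um": cx * px,
                "y_um": cy * px,
                "area_um2": area,
                "mean_intensity": rp.intensity_mean,
            }
        )
    cells = pd.DataFrame(rows) if rows else _empty_cells()
    return CellSet(channel=img.channel, cells=cells, meta=img.meta)


def count_summary(cellsets: list[CellSet]) -> pd.DataFrame:
    """Per-mouse mean/SD cells per slice by channel and subdivision.

    Rows with ``subdivision == "all"`` pool every slice of the mouse, the
    analogue of averaging counts across anterior, middle and posterior
    planes.  SD uses ddof=1 and is reported as 0 with ``n_slices == 1``.
    """
    if not cellsets:
        return pd.DataFrame(
            columns=["mouse_id", "channel", "subdivision", "mean_cells", "sd_cells", "n_slices"]
        )
    rows = []
    for cs in cellsets:
        if not cs.meta.subdivision:
            raise ValueError(f"slice {cs.meta.slice_id!r} has no subdivision label")
        rows.append(
            {
                "mouse_id": cs.meta.mouse_id,
                "channel": cs.channel,
                "subdivision": cs.meta.subdivision,
                "n_cells": len(cs),
            }
        )
    df = pd.DataFrame(rows)
    pooled = df.assign(subdivision="all")
    both = pd.concat([df, pooled], ignore_index=True)
    out = (
        both.groupby(["mouse_id", "channel", "subdivision"], as_index=False)
        .agg(mean_cells=("n_cells", "mean"), sd_cells=("n_cells", "std"), n_slices=("n_cells", "size"))
    )
    out["sd_cells"] = out["sd_cells"].fillna(0.0)
    return out
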