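"""Strip-averaged fluorescence intensity profiles along two anatomical axes.

Axis 1 runs parallel to the external capsule (the configured zone
orientation); axis 2 is perpendicular.  For each bin along an axis, the
profile value is the mean intensity of all pixels whose projection onto the
axis falls in that bin and whose perpendicular offset is at most half the
strip width (default 100 um, i.e. the 0.1 mm section).  Profiles are
z-scored (population SD) and realigned so the retrograde channel's peak sits
at position 0, enabling averaging across sections and mice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .stack_io import ProjectionImage, SliceMeta

__all__ = ["AxisSpec", "IntensityProfile", "profile_axis", "zscore", "realign_and_average"]


@dataclass(frozen=True)
class AxisSpec:
    origin_um: tuple[float, float]
    direction_deg: float
    strip_width_um: float = 100.0
    bin_um: float = 20.0
    extent_um: float = 400.0

    def __post_init__(self) -> None:
        if self.strip_width_um <= 0 or self.bin_um <= 0 or self.extent_um <= 0:
            raise ValueError("strip_width_um, bin_um and extent_um must be positive")

    def perpendicular(self) -> "AxisSpec":
        """The orthogonal axis through the same origin."""
        d = self.direction_deg + 90.0
        d = ((d + 180.0) % 360.0) - 180.0
        return replace(self, direction_deg=d)


@dataclass
class IntensityProfile:
    channel: str
    axis: AxisSpec
    positions_mm: np.ndarray  # bin centres, relative to the axis origin
    values: np.ndarray  # mean intensity or z-score; NaN where no pixels fell
    zscored: bool = False
    degenerate: bool = False
    meta: SliceMeta = field(default_factory=SliceMeta)

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions_mm.shape != self.values.shape:
            raise ValueError("positions and values must have the same length")

    @property
    def peak_index(self) -> int:
        """Index of the maximum value; ties go to the bin nearest the origin."""
        finite = np.isfinite(self.values)
        if not finite.any():
            raise ValueError("profile has no present bins")
        vmax = np.nanmax(self.values)
        cand = np.flatnonzero(finite & (self.values == vmax))
        return int(cand[np.argmin(np.abs(self.positions_mm[cand]))])


def profile_axis(img: ProjectionImage, axis: AxisSpec) -> IntensityProfile:
    """Mean pixel intensity in successive bins along an axis strip.

    Exact pixel binning: a pixel (centre) belongs to a bin when its signed
    projection onto the axis direction falls inside the bin and its
    perpendicular offset is at most ``strip_width_um / 2``.  Bins that
    receive no pixels are marked absent (NaN).
    """
    data = np.asarray(img.data, dtype=float)
    px = img.pixel_um
    ny, nx = data.shape
    th = math.radians(axis.direction_deg)
    ux, uy = math.cos(th), math.sin(th)
    xs = np.arange(nx) * px - axis.origin_um[0]
    ys = np.arange(ny) * px - axis.origin_um[1]
    gx, gy = np.meshgrid(xs, ys)
    s = gx * ux + gy * uy
    perp = -gx * uy + gy * ux
    in_strip = np.abs(perp) <= axis.strip_width_um / 2.0
    n_bins = int(round(2.0 * axis.extent_um / axis.bin_um))
    edges0 = -axis.extent_um
    idx = np.floor((s - edges0) / axis.bin_um).astype(int)
    ok = in_strip & (idx >= 0) & (idx < n_bins)
    if not ok.any():
        raise ValueError("axis strip lies entirely outside the image")
    sums = np.bincount(idx[ok], weights=data[ok], minlength=n_bins)
    counts = np.bincount(idx[ok], minlength=n_bins)
    values = np.full(n_bins, np.nan)
    nz = counts > 0
    values[nz] = sums[nz] / counts[nz]
    centres_um = edges0 + (np.arange(n_bins) + 0.5) * axis.bin_um
    return IntensityProfile(
        channel=img.channel,
        axis=axis,
        positions_mm=centres_um / 1000.0,
        values=values,
        meta=img.meta,
    )


def zscore(p: IntensityProfile) -> IntensityProfile:
    """Standardize a profile to mean 0, SD 1 over its present bins.

    Population (ddof=0) SD; a constant profile maps to all zeros with the
    ``degenerate`` flag set.
    """
    finite = np.isfinite(p.values)
    if finite.sum() < 2:
        raise ValueError("need at least 2 present bins to z-score")
    vals = p.values.copy()
    mu = vals[finite].mean()
    sd = vals[finite].std(ddof=0)
    if sd == 0.0:
        vals[finite] = 0.0
        degenerate = True
    else:
        vals[finite] = (vals[finite] - mu) / sd
        degenerate = False
    return IntensityProfile(
        channel=p.channel,
        axis=p.axis,
        positions_mm=p.positions_mm.copy(),
        values=vals,
        zscored=True,
        degenerate=degenerate,
        meta=p.meta,
    )


def realign_and_average(
    slice_profiles: list[dict[str, IntensityProfile]],
    reference_channel: str,
) -> pd.DataFrame:
    """Realign each slice's profiles to the reference peak and average.

    All channels of a slice are shifted by the same amount so the reference
    channel's peak lands at position 0.  Averaging runs over the common bin
    lattice and keeps bins present in at least half of the slices.  Returns a
    long-form table (channel, position_mm, mean, sd, n); SD is the
    population SD across slices.
    """
    if not slice_profiles:
        raise ValueError("no profiles to average")
    n_slices = len(slice_profiles)
    acc: dict[tuple[str, int], list[float]] = {}
    bin_mm = None
    for prof_by_ch in slice_profiles:
        if reference_channel not in prof_by_ch:
            raise KeyError(f"slice lacks a {reference_channel!r} profile")
        ref = prof_by_ch[reference_channel]
        if ref.degenerate:
            raise ValueError("reference profile is degenerate (flat): no unique peak")
        shift = ref.positions_mm[ref.peak_index]
        for ch, prof in prof_by_ch.items():
            if bin_mm is None:
                bin_mm = prof.axis.bin_um / 1000.0
            pos = prof.positions_mm - shift
            for pmm, v in zip(pos, prof.values):
                if not np.isfinite(v):
                    continue
                key = (ch, int(round(pmm / bin_mm)))
                acc.setdefault(key, []).append(float(v))
    rows = []
    for (ch, k), vals in sorted(acc.items()):
        if 2 * len(vals) < n_slices:
            continue
        arr = np.asarray(vals)
        rows.append(
            {
                "channel": ch,
                "position_mm": k * bin_mm,
                "mean": arr.mean(),
                "sd": arr.std(ddof=0),
                "n": len(arr),
            }
        )
    return pd.DataFrame(rows)
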