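"""Image-stack IO and maximum-intensity projection.

One multi-page grayscale TIFF per slice, page order channel-major then z
(``data[c, z]`` is page ``c * n_z + z``).  Calibration and slice metadata are
stored as JSON in the TIFF description tag, so a written stack round-trips
losslessly for integer data.

Coordinate convention (package-wide): 0-based pixel indices; physical
coordinates in micrometres with the origin at the centre of the top-left
pixel, x rightward (columns), y downward (rows).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "SliceMeta",
    "ImageVolume",
    "ProjectionImage",
    "read_stack",
    "write_stack",
    "max_project",
]


@dataclass
class SliceMeta:
    """Provenance of one coronal slice image."""

    mouse_id: str = ""
    sex: str = ""
    age_group: str = ""
    hemisphere: str = ""
    ap_mm: float = math.nan
    subdivision: str | None = None
    condition: str | None = None
    slice_id: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SliceMeta":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass
class ImageVolume:
    """A multi-channel z-stack with physical calibration.

    ``data`` is indexed ``(channel, z, y, x)`` and must be nonnegative.
    """

    data: np.ndarray
    channel_names: tuple[str, ...]
    pixel_um: float
    z_step_um: float
    meta: SliceMeta = field(default_factory=SliceMeta)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4-D (channel, z, y, x), got {self.data.ndim}-D")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    def channel_index(self, channel: str) -> int:
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel {channel!r}; have {self.channel_names}") from None


@dataclass
class ProjectionImage:
    """A 2-D (y, x) image for one channel, usually a max projection."""

    data: np.ndarray
    channel: str
    pixel_um: float
    meta: SliceMeta = field(default_factory=SliceMeta)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("projection data must be 2-D (y, x)")


def write_stack(vol: ImageVolume, path: str | Path) -> Path:
    """Write an :class:`ImageVolume` as a multi-page TIFF with JSON metadata."""
    path = Path(path)
    c, z, y, x = vol.data.shape
    desc = json.dumps(
        {
            "channel_names": list(vol.channel_names),
            "pixel_um": vol.pixel_um,
            "z_step_um": vol.z_step_um,
            "n_z": z,
            "meta": vol.meta.to_dict(),
        }
    )
    tifffile.imwrite(
        path, vol.data.reshape(c * z, y, x), photometric="minisblack", description=desc
    )
    return path


def read_stack(path: str | Path) -> ImageVolume:
    """Read a stack written by :func:`write_stack`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    try:
        info = json.loads(desc) if desc else {}
    except json.JSONDecodeError:
        info = {}
    if "channel_names" not in info or "n_z" not in info:
        raise ValueError(f"{path}: missing stack metadata (channel names unknown)")
    names = tuple(info["channel_names"])
    n_z = int(info["n_z"])
    if pages.ndim == 2:
        pages = pages[None]
    n_pages = pages.shape[0]
    if n_pages % n_z != 0 or n_pages // n_z != len(names):
        raise ValueError(
            f"{path}: {n_pages} pages incompatible with {len(names)} channels x {n_z} planes"
        )
    data = pages.reshape(len(names), n_z, pages.shape[1], pages.shape[2])
    return ImageVolume(
        data=data,
        channel_names=names,
        pixel_um=float(info["pixel_um"]),
        z_step_um=float(info["z_step_um"]),
        meta=SliceMeta.from_dict(info.get("meta", {})),
    )


def max_project(vol: ImageVolume, channel: str) -> ProjectionImage:
    """Maximum-intensity projection over z for one channel."""
    ci = vol.channel_index(channel)
    return ProjectionImage(
        data=vol.data[ci].max(axis=0),
        channel=channel,
        pixel_um=vol.pixel_um,
        meta=vol.meta,
    )
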