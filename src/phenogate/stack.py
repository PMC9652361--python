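"""Named multi-channel 2D image stacks and their TIFF round trip.

An :class:`ImageStack` is the unit every imaging stage consumes: a dict of
named, equal-shape, non-negative 2D float arrays plus optional pixel-size
metadata (µm/pixel).  Geometry everywhere downstream is in pixels; the
physical pixel size is carried as metadata only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import FormatError

__all__ = ["ImageStack", "read_image_stack", "write_image_stack"]


@dataclass
class ImageStack:
    """Named 2D intensity channels sharing one shape.

    Parameters
    ----------
    channels
        Mapping from channel name (e.g. ``"marker"``, ``"nucleus"``,
        ``"golgi"``) to a 2D non-negative float array.
    pixel_size
        Optional physical pixel size in µm/pixel; metadata only.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise FormatError("an ImageStack needs at least one channel")
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        ref = next(iter(shapes.values()))
        if len(ref) != 2:
            raise FormatError(f"channels must be 2D, got shape {ref}")
        for name, shp in shapes.items():
            if shp != ref:
                raise FormatError(
                    f"channel {name!r} has shape {shp}, expected {ref}"
                )
        clean = {}
        for name, arr in self.channels.items():
            a = np.asarray(arr, dtype=np.float64)
            if np.any(a < 0):
                raise FormatError(f"channel {name!r} contains negative intensities")
            clean[name] = a
        self.channels = clean

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise FormatError(
                f"channel {name!r} not present; have {sorted(self.channels)}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self.channels


def write_image_stack(path, stack: ImageStack) -> None:
    """Write the stack as a (C, H, W) TIFF; channel names go in the description."""
    names = list(stack.channels)
    data = np.stack([stack.channels[n] for n in names]).astype(np.float32)
    desc = json.dumps(
        {"channels": names, "pixel_size": stack.pixel_size, "meta": stack.meta}
    )
    tifffile.imwrite(path, data, description=desc, photometric="minisblack")


def read_image_stack(path, channel_map: dict[str, int] | None = None) -> ImageStack:
    """Read a multi-channel TIFF into an :class:`ImageStack`.

    Channel names come from ``channel_map`` ({name: page/plane index}) when
    given, else from the JSON description written by :func:`write_image_stack`.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"expected a 2D or (C,H,W) TIFF, got ndim={data.ndim}")
    n = data.shape[0]
    pixel_size = None
    meta: dict = {}
    if channel_map is None:
        try:
            info = json.loads(desc)
            names = info["channels"]
            pixel_size = info.get("pixel_size")
            meta = info.get("meta", {})
        except (json.JSONDecodeError, KeyError, TypeError):
            raise FormatError(
                "no channel_map given and no channel names found in TIFF metadata"
            ) from None
        if len(names) != n:
            raise FormatError(
                f"metadata names {names} do not match {n} planes in the file"
            )
        channel_map = {name: i for i, name in enumerate(names)}
    for name, idx in channel_map.items():
        if not 0 <= idx < n:
            raise FormatError(
                f"channel {name!r} maps to plane {idx} but the file has {n} planes"
            )
    channels = {name: data[idx] for name, idx in channel_map.items()}
    return ImageStack(channels, pixel_size=pixel_size, meta=meta)
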