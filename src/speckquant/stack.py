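"""Multi-channel 3D image stacks and their TIFF serialization.

An :class:`ImageStack` is the raw input of every pipeline stage: a mapping
from channel name (e.g. ``"dapi"``, ``"malat1"``) to a ``(z, y, x)`` intensity
volume, plus the physical voxel size in micrometres. Stacks are written as a
single multi-page TIFF in CZYX page order with a JSON sidecar of metadata
embedded in the TIFF description, so a round trip is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile


class StackError(ValueError):
    """Raised for malformed or inconsistent image stacks."""


@dataclass
class ImageStack:
    """A multi-channel 3D intensity volume with voxel-size metadata.

    Parameters
    ----------
    channels
        Mapping of channel name to a 3D ``(z, y, x)`` float array. All
        channels must share one shape; intensities must be non-negative.
    voxel_size
        Physical size of one voxel as ``(z, y, x)`` in micrometres.
    provenance
        Free-form origin string (source path or simulator parameter hash).
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise StackError("an ImageStack needs at least one channel")
        shapes = {name: v.shape for name, v in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise StackError(f"channels disagree on shape: {shapes}")
        shape = next(iter(shapes.values()))
        if len(shape) != 3:
            raise StackError(f"channel volumes must be 3D (z, y, x), got {shape}")
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise StackError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        for name, vol in self.channels.items():
            if vol.size and float(vol.min()) < 0:
                raise StackError(f"channel {name!r} has negative intensities")
        self.voxel_size = tuple(float(s) for s in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        """Shape ``(n_z, n_y, n_x)`` shared by all channels."""
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def require(self, name: str) -> np.ndarray:
        """Return a channel volume, with a descriptive error if absent."""
        try:
            return self.channels[name]
        except KeyError:
            raise StackError(
                f"channel {name!r} not present; available: {sorted(self.channels)}"
            ) from None


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as one multi-page TIFF, pages in CZYX order.

    Channel names and voxel size go into the TIFF description as JSON so
    :func:`read_stack` can reconstruct the stack without a config override.
    """
    path = Path(path)
    names = stack.channel_names
    data = np.stack([stack.channels[n] for n in names]).astype(np.float32)
    meta = {
        "channels": names,
        "voxel_size_um_zyx": list(stack.voxel_size),
        "axes": "CZYX",
        "provenance": stack.provenance,
    }
    tifffile.imwrite(path, data, description=json.dumps(meta), photometric="minisblack")
    return path


def read_stack(
    path: str | Path,
    channel_map: Mapping[str, int] | None = None,
    voxel_size: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    Parameters
    ----------
    path
        TIFF file with pages in CZYX order (C = channel, outermost).
    channel_map
        Optional mapping of channel name to channel index. When omitted the
        channel names are taken from the embedded JSON metadata.
    voxel_size
        Overrides the voxel size from metadata; required if the file carries
        none.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or ""
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}

    if data.ndim == 3:
        data = data[None]  # single channel file
    if data.ndim != 4:
        raise StackError(f"expected CZYX pages (4D), got array of shape {data.shape}")

    n_channels = data.shape[0]
    if channel_map is not None:
        bad = {n: i for n, i in channel_map.items() if not 0 <= i < n_channels}
        if bad:
            raise StackError(
                f"channel indices out of range for {n_channels} channels: {bad}"
            )
        channels = {name: np.asarray(data[i], dtype=np.float32) for name, i in channel_map.items()}
    else:
        names = meta.get("channels")
        if not names or len(names) != n_channels:
            raise StackError(
                f"{path} carries no usable channel names; pass a channel_map "
                f"(file has {n_channels} channels)"
            )
        channels = {
            name: np.asarray(data[i], dtype=np.float32) for i, name in enumerate(names)
        }

    vs = voxel_size or meta.get("voxel_size_um_zyx")
    if vs is None:
        raise StackError(
            f"{path} has no voxel-size metadata ('voxel_size_um_zyx') and no "
            "override was given; voxel size in um (z, y, x) is required"
        )
    return ImageStack(channels=channels, voxel_size=tuple(vs), provenance=str(path))
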