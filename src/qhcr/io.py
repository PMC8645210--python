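"""Multichannel TIFF I/O with physical pixel size metadata.

Stacks are written as plain multi-page TIFF, one page per channel, with a
JSON ImageDescription block carrying the pixel size (µm) and channel
names.  OME-XML PhysicalSizeX is honoured on read.  Writes are
deterministic: the same stack always produces byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass(frozen=True)
class ImageStack:
    """Channel-major image data (C, rows, cols) with physical metadata."""

    data: np.ndarray
    pixel_size_um: float
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=np.float64)
        if d.ndim == 2:
            d = d[None]
        if d.ndim != 3:
            raise ValueError(f"stack data must be 2D or 3D, got shape {d.shape}")
        if d.shape[0] == 0:
            raise ValueError("stack must have at least one channel")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        names = tuple(self.channel_names) if self.channel_names else tuple(
            f"ch{i}" for i in range(d.shape[0]))
        if len(names) != d.shape[0]:
            raise ValueError(
                f"{len(names)} channel names for {d.shape[0]} channels")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "channel_names", names)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def channel(self, index: int) -> np.ndarray:
        return self.data[index]


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write one page per channel, float32, with a JSON description block."""
    path = Path(path)
    meta = {"pixel_size_um": stack.pixel_size_um,
            "channel_names": list(stack.channel_names)}
    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        photometric="minisblack",
        description=json.dumps(meta, sort_keys=True),
        software="qhcr",
    )
    return path


def read_stack(path: str | Path,
               pixel_size_um: float | None = None) -> ImageStack:
    """Read a multi-page TIFF as a channel-major stack.

    Pixel size is taken from the JSON description block, from OME metadata,
    or from the ``pixel_size_um`` override, in that order; if none is
    available an error is raised.  Integer data are promoted to float.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
        if not pages:
            raise ValueError(f"{path} contains no pages")
        shapes = {p.shape for p in pages}
        if len(shapes) > 1:
            raise ValueError(f"{path} has pages of differing shapes: {sorted(shapes)}")
        meta_px = None
        names: tuple[str, ...] | None = None
        desc = tif.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
                meta_px = meta.get("pixel_size_um")
                if meta.get("channel_names"):
                    names = tuple(meta["channel_names"])
            except (json.JSONDecodeError, AttributeError, TypeError):
                pass
        if meta_px is None and tif.ome_metadata:
            try:
                import xml.etree.ElementTree as ET
                root = ET.fromstring(tif.ome_metadata)
                for el in root.iter():
                    if el.tag.endswith("Pixels") and "PhysicalSizeX" in el.attrib:
                        meta_px = float(el.attrib["PhysicalSizeX"])
                        break
            except ET.ParseError:
                pass
    px = meta_px if meta_px is not None else pixel_size_um
    if px is None:
        raise ValueError(
            f"{path} carries no pixel size metadata; pass pixel_size_um explicitly")
    data = np.stack([np.asarray(p, dtype=np.float64) for p in pages])
    if names is None or len(names) != data.shape[0]:
        names = tuple(f"ch{i}" for i in range(data.shape[0]))
    return ImageStack(data=data, pixel_size_um=float(px), channel_names=names)


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean pixel mask as a single-page uint8 TIFF (255 = True)."""
    path = Path(path)
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)),
                     photometric="minisblack", software="qhcr")
    return path


def read_mask(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"mask {path} must be single-page 2D, got shape {arr.shape}")
    return np.asarray(arr) > 0


__all__ = ["ImageStack", "write_stack", "read_stack", "write_mask", "read_mask"]
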