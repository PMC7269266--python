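"""Calibrated raster container and TIFF round-trip helpers.

A :class:`PelletImage` is the package's in-memory currency for every 2-D
grayscale raster (brightfield frames, single CLSM channels).  Calibration is a
single isotropic pixel size in micrometres per pixel; the brightfield study
resolution this package targets is 4.5 μm/px.

TIFF files are written with the pixel size in the ImageJ-style resolution tags
and, because resolution tags are routinely mangled by converters, also in a
``<stem>.json`` sidecar that takes precedence when reading.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["PelletImage", "read_tiff", "write_tiff"]


@dataclass(frozen=True)
class PelletImage:
    """A 2-D grayscale raster with isotropic spatial calibration.

    Parameters
    ----------
    pixels
        Non-empty 2-D array of intensities (any numeric dtype).
    pixel_size_um
        Edge length of one pixel in μm; must be positive.
    """

    pixels: np.ndarray
    pixel_size_um: float = 4.5

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def pixel_area_um2(self) -> float:
        return float(self.pixel_size_um) ** 2


def write_tiff(image: PelletImage, path: str | Path) -> Path:
    """Write ``image`` as a single-channel TIFF plus a calibration sidecar."""
    path = Path(path)
    px = image.pixels
    if px.dtype == np.float64:  # keep files compact; precision is cosmetic
        px = px.astype(np.float32)
    res = 1.0 / image.pixel_size_um  # pixels per micrometre
    tifffile.imwrite(path, px, resolution=(res, res), metadata={"unit": "um"})
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"pixel_size_um": image.pixel_size_um}))
    return path


def read_tiff(path: str | Path, pixel_size_um: float | None = None) -> PelletImage:
    """Read a single-channel TIFF; calibration from (in order of precedence)
    the explicit argument, the JSON sidecar, or the TIFF resolution tags."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        if pixel_size_um is None:
            sidecar = path.with_suffix(".json")
            if sidecar.exists():
                pixel_size_um = float(json.loads(sidecar.read_text())["pixel_size_um"])
            else:
                page = tf.pages[0]
                xres = page.tags.get("XResolution")
                if xres is not None:
                    num, den = xres.value
                    if num:
                        pixel_size_um = den / num
    if pixel_size_um is None:
        raise ValueError(f"no pixel size found for {path}; pass pixel_size_um")
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a single-channel 2-D image")
    return PelletImage(arr, float(pixel_size_um))
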