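"""Render a spectrum as the axis-free trace image that box counting consumes.

The pipeline mirrors how a plotted absorbance curve is exported for fractal
software: normalize the amplitude, draw the curve as a dark 1-px polyline on
a light canvas with no axes/grids/margins (8-bit grayscale), then threshold
to a binary mask whose foreground is the trace.

Amplitude normalization before drawing is what makes the downstream
multifractal number independent of overall signal intensity (and hence of
the cell concentration placed on the ATR crystal): scaling the spectrum by
any c > 0 leaves the min-max normalized curve, and therefore the rendered
image, unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .spectra_io import Spectrum, resample_uniform

__all__ = [
    "RasterConfig",
    "GrayImage",
    "BinaryImage",
    "RasterError",
    "normalize_amplitude",
    "render_trace",
    "binarize",
    "spectrum_to_binary",
    "save_image",
    "load_binary_image",
]


class RasterError(ValueError):
    """Raised on invalid rasterization inputs or empty results."""


@dataclass(frozen=True)
class RasterConfig:
    """Canvas geometry and binarization settings.

    Height defaults to 128 px — the amplitude quantization this method is
    typically run at (7 bits of trace resolution) — and width to 1024 px,
    about one column per 3.3 cm^-1 over the 4000-650 cm^-1 range.
    """

    width: int = 1024
    height: int = 128
    line_thickness: int = 1
    threshold: int = 128
    normalize: str = "minmax"  # "minmax" | "fixed"
    fixed_range: tuple[float, float] | None = None
    connect_columns: bool = True

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 16:
            raise ValueError("canvas must be at least 64x16 px")
        if not 0 < self.threshold < 255:
            raise ValueError("threshold must be in (0, 255)")
        if self.line_thickness < 1:
            raise ValueError("line_thickness must be >= 1")
        if self.normalize not in {"minmax", "fixed"}:
            raise ValueError("normalize must be 'minmax' or 'fixed'")
        if self.normalize == "fixed":
            if self.fixed_range is None or not self.fixed_range[0] < self.fixed_range[1]:
                raise ValueError("fixed mode needs fixed_range=(lo, hi) with lo < hi")


@dataclass
class GrayImage:
    """8-bit grayscale image; ``values[row, col]``, row 0 at the top."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.dtype != np.uint8:
            raise ValueError("GrayImage values must be a 2-D uint8 array")
        self.values = v

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class BinaryImage:
    """Binary mask; 1 = trace foreground, 0 = background."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("BinaryImage mask must be 2-D")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("BinaryImage values must be 0/1")
        m = m.astype(np.uint8)
        if m.sum() == 0:
            raise RasterError("binary image has no foreground pixels")
        self.mask = m

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]

    @property
    def foreground_count(self) -> int:
        return int(self.mask.sum())


def normalize_amplitude(
    s: Spectrum, mode: str = "minmax", fixed_range: tuple[float, float] | None = None
) -> Spectrum:
    """Map absorbance to [0, 1].

    ``minmax`` spans the spectrum's own range (scale-invariant); ``fixed``
    maps a caller-chosen [lo, hi] affinely to [0, 1] and clips.
    """
    a = s.absorbance
    if mode == "minmax":
        lo, hi = float(a.min()), float(a.max())
        if hi <= lo:
            raise RasterError(
                "constant spectrum cannot be min-max normalized; use mode='fixed'"
            )
    elif mode == "fixed":
        if fixed_range is None:
            raise ValueError("fixed mode requires fixed_range=(lo, hi)")
        lo, hi = map(float, fixed_range)
        if not lo < hi:
            raise ValueError("fixed_range must satisfy lo < hi")
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    vals = np.clip((a - lo) / (hi - lo), 0.0, 1.0)
    return Spectrum(s.wavenumbers.copy(), vals, dict(s.meta))


def _rows_for(values: np.ndarray, height: int) -> np.ndarray:
    # absorbance 0 -> bottom row, 1 -> top row; ties round toward the top
    rows = np.floor((1.0 - values) * (height - 1) + 0.5).astype(int)
    return np.clip(rows, 0, height - 1)


def render_trace(s: Spectrum, cfg: RasterConfig = RasterConfig()) -> GrayImage:
    """Draw the normalized spectrum as a dark polyline on a light canvas.

    Wavenumber maps linearly to column (descending wavenumber left to
    right); the spectrum is resampled so each column holds exactly one
    sample.  With ``connect_columns`` consecutive rows are joined by
    vertical runs, making the trace a connected curve; ``line_thickness``
    thickens the line downward.  Background 255, trace 0; no axes or
    margins.
    """
    a = s.absorbance
    if a.min() < -1e-9 or a.max() > 1 + 1e-9:
        raise RasterError("render_trace expects a spectrum normalized to [0, 1]")
    rs = resample_uniform(s, cfg.width)  # descending grid -> column order
    rows = _rows_for(np.clip(rs.absorbance, 0.0, 1.0), cfg.height)

    canvas = np.full((cfg.height, cfg.width), 255, dtype=np.uint8)
    prev = rows[0]
    for col, r in enumerate(rows):
        if cfg.connect_columns and col > 0 and r != prev:
            lo, hi = (r, prev) if r < prev else (prev, r)
            canvas[lo : hi + 1, col] = 0
        else:
            canvas[r, col] = 0
        if cfg.line_thickness > 1:
            lo, hi = (min(r, prev), max(r, prev)) if cfg.connect_columns and col > 0 else (r, r)
            canvas[lo : min(hi + cfg.line_thickness, cfg.height), col] = 0
        prev = r
    return GrayImage(canvas)


def binarize(g: GrayImage, threshold: int = 128) -> BinaryImage:
    """Threshold a grayscale image; pixels darker than ``threshold`` become 1."""
    mask = (g.values < threshold).astype(np.uint8)
    if mask.sum() == 0:
        raise RasterError("thresholding produced an empty trace")
    return BinaryImage(mask)


def spectrum_to_binary(s: Spectrum, cfg: RasterConfig = RasterConfig()) -> BinaryImage:
    """Full raster pipeline: normalize -> render -> binarize."""
    ns = normalize_amplitude(s, cfg.normalize, cfg.fixed_range)
    return binarize(render_trace(ns, cfg), cfg.threshold)


def save_image(img: GrayImage | BinaryImage, path) -> None:
    """Write PNG or BMP (by suffix); binary masks are saved as 0/255."""
    path = Path(path)
    if isinstance(img, BinaryImage):
        arr = (1 - img.mask) * np.uint8(255)  # foreground black, like the plot
    else:
        arr = img.values
    Image.fromarray(arr, mode="L").save(path)


def load_binary_image(path, threshold: int = 128) -> BinaryImage:
    """Load a pre-rendered trace image (PNG/BMP); dark pixels are foreground."""
    arr = np.asarray(Image.open(path).convert("L"))
    return binarize(GrayImage(arr.astype(np.uint8)), threshold)
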