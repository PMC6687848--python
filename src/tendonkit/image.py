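"""Calibrated image grids and polygonal regions of interest.

These are the common substrate of the speckle spatial-frequency analysis and
the color-Doppler area quantification: a pixel grid with a physical
millimetre-per-pixel calibration (possibly anisotropic), and a simple polygon
in pixel coordinates that selects the tendon body.

Conventions
-----------
* Images are row-major with the origin at the top-left pixel; indices are
  0-based ``(row, col)``.
* ``pixel_size_mm`` is the ``(row, col)`` pair of physical pixel pitches.
* A pixel belongs to a :class:`PolygonROI` iff its *center* (the integer
  coordinate) lies strictly inside the polygon; boundary pixels are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = ["CalibratedImage", "PolygonROI"]


@dataclass(frozen=True)
class CalibratedImage:
    """A 2D grayscale intensity grid with physical pixel calibration.

    Parameters
    ----------
    pixels:
        2D array of finite, nonnegative intensities.
    pixel_size_mm:
        ``(row_mm, col_mm)`` physical size of one pixel; both positive.
    """

    pixels: np.ndarray
    pixel_size_mm: tuple[float, float]

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")
        if np.any(px < 0):
            raise ValueError("pixel intensities must be nonnegative")
        object.__setattr__(self, "pixels", px)
        rs, cs = float(self.pixel_size_mm[0]), float(self.pixel_size_mm[1])
        if rs <= 0 or cs <= 0:
            raise ValueError("pixel sizes must be positive")
        object.__setattr__(self, "pixel_size_mm", (rs, cs))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def nyquist_mm_inv(self) -> float:
        """Radial Nyquist frequency, limited by the coarser axis."""
        return 1.0 / (2.0 * max(self.pixel_size_mm))


@dataclass(frozen=True)
class PolygonROI:
    """Simple polygon in pixel ``(row, col)`` coordinates.

    Containment follows the even-odd rule applied to pixel centers, with
    boundary pixels excluded (strict interior).
    """

    vertices: np.ndarray
    _poly: _ShapelyPolygon = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("ROI needs >= 3 (row, col) vertices")
        object.__setattr__(self, "vertices", v)
        # shapely works in (x, y); map x=col, y=row
        poly = _ShapelyPolygon(np.column_stack([v[:, 1], v[:, 0]]))
        if not poly.is_valid:
            raise ValueError("ROI polygon must be simple (non-self-intersecting)")
        object.__setattr__(self, "_poly", poly)

    @property
    def area_px(self) -> float:
        return self._poly.area

    def area_mm2(self, pixel_size_mm: tuple[float, float]) -> float:
        return self._poly.area * pixel_size_mm[0] * pixel_size_mm[1]

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Strict-interior containment test for pixel centers."""
        rows = np.asarray(rows, dtype=float)
        cols = np.asarray(cols, dtype=float)
        return shapely.contains_xy(self._poly, cols, rows)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean interior mask for an image of ``shape`` (rows, cols)."""
        n_rows, n_cols = shape
        v = self.vertices
        if (v[:, 0].min() < -0.5 or v[:, 1].min() < -0.5
                or v[:, 0].max() > n_rows - 0.5 or v[:, 1].max() > n_cols - 0.5):
            raise ValueError("ROI polygon extends beyond image bounds")
        rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
        return self.contains(rr.ravel(), cc.ravel()).reshape(n_rows, n_cols)

    @staticmethod
    def rectangle(row0: float, col0: float, row1: float, col1: float) -> "PolygonROI":
        """Axis-aligned rectangular ROI covering pixel centers in the open box."""
        return PolygonROI(np.array([
            [row0, col0], [row0, col1], [row1, col1], [row1, col0],
        ]))
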