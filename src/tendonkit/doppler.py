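"""Color-Doppler neovascularization area inside a tendon ROI.

Doppler overlays chromatic flow pixels on a grayscale B-mode background, so a
pixel is "colored" when its RGB channel spread — ``max(|R-G|, |G-B|, |R-B|)``
— reaches a threshold (default 30 of 255). The vascularization index is the
total colored-pixel area inside the polygonal tendon ROI, and the outcome for
a captured video sequence is the maximum area over its frames (first frame on
ties). Pixel containment uses the same strict-interior pixel-center rule as
the micromorphology ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import PolygonROI

__all__ = [
    "DopplerSequence",
    "ColorAreaResult",
    "detect_color_pixels",
    "color_area",
    "sequence_max_area",
]


@dataclass(frozen=True)
class DopplerSequence:
    """RGB frame sequence with pixel calibration and tendon ROI."""

    frames: list
    pixel_size_mm: tuple[float, float]
    roi: PolygonROI

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("sequence needs at least one frame")
        shape = np.asarray(self.frames[0]).shape
        for f in self.frames:
            a = np.asarray(f)
            if a.shape != shape:
                raise ValueError("all frames must share one shape")
            if a.ndim != 3 or a.shape[2] != 3:
                raise ValueError("frames must be RGB (rows, cols, 3)")


@dataclass(frozen=True)
class ColorAreaResult:
    """Per-frame colored areas, their maximum, and the frame attaining it."""

    per_frame_area_mm2: list
    max_area_mm2: float
    argmax_frame: int
    chroma_threshold: int

    def __post_init__(self) -> None:
        if self.per_frame_area_mm2:
            if not np.isclose(self.max_area_mm2, max(self.per_frame_area_mm2)):
                raise ValueError("max must equal the largest per-frame area")


def detect_color_pixels(frame: np.ndarray, roi: PolygonROI, chroma_threshold: int = 30) -> np.ndarray:
    """Boolean mask of chromatic pixels whose centers lie inside the ROI."""
    if chroma_threshold < 1:
        raise ValueError("chroma threshold must be >= 1")
    a = np.asarray(frame).astype(np.int64)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError("frame must be RGB")
    r, g, b = a[..., 0], a[..., 1], a[..., 2]
    spread = np.maximum(np.maximum(np.abs(r - g), np.abs(g - b)), np.abs(r - b))
    return (spread >= chroma_threshold) & roi.mask(a.shape[:2])


def color_area(mask: np.ndarray, pixel_size_mm: tuple[float, float]) -> float:
    """Colored area in mm^2: pixel count times pixel area."""
    return float(np.count_nonzero(mask)) * pixel_size_mm[0] * pixel_size_mm[1]


def sequence_max_area(seq: DopplerSequence, chroma_threshold: int = 30) -> ColorAreaResult:
    """Maximal colored area over the sequence (first frame wins ties)."""
    areas = [
        color_area(detect_color_pixels(f, seq.roi, chroma_threshold), seq.pixel_size_mm)
        for f in seq.frames
    ]
    argmax = int(np.argmax(areas))  # np.argmax returns the first maximum
    return ColorAreaResult(
        per_frame_area_mm2=areas,
        max_area_mm2=float(areas[argmax]),
        argmax_frame=argmax,
        chroma_threshold=int(chroma_threshold),
    )
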