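"""Flat-file exchange: calibrated images, ROIs, trials, cohorts, configs.

All formats are plain and inspectable: PNG/TIFF images with a JSON sidecar
carrying the millimetre pixel calibration (and, for float data, the intensity
scale), ROIs and configurations as JSON/YAML, trial time series and cohort
tables as CSV with documented headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .image import CalibratedImage, PolygonROI
from .mechanics import RampTrial
from .pipeline import RunConfig

__all__ = [
    "save_image", "load_image",
    "save_roi", "load_roi",
    "save_trial", "load_trial",
    "save_config", "load_config",
]

TRIAL_COLUMNS = ["time_s", "dyn_moment_Nm", "knee_angle_deg",
                 "antagonist_emg", "elongation_mm"]


def save_image(path, image: CalibratedImage) -> None:
    """Write a 16-bit PNG/TIFF plus a ``.json`` calibration sidecar.

    Float intensities are scaled to the full 16-bit range; the scale factor
    is stored in the sidecar so :func:`load_image` reconstructs the values.
    """
    path = Path(path)
    peak = float(image.pixels.max())
    scale = 65535.0 / peak if peak > 0 else 1.0
    iio.imwrite(path, np.round(image.pixels * scale).astype(np.uint16))
    sidecar = {"pixel_size_mm": list(image.pixel_size_mm), "intensity_scale": scale}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_image(path) -> CalibratedImage:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    pixels = np.asarray(iio.imread(path), dtype=float) / sidecar["intensity_scale"]
    return CalibratedImage(pixels=pixels, pixel_size_mm=tuple(sidecar["pixel_size_mm"]))


def save_roi(path, roi: PolygonROI) -> None:
    """ROI as a JSON list of ``[row, col]`` vertices."""
    Path(path).write_text(json.dumps({"vertices": roi.vertices.tolist()}))


def load_roi(path) -> PolygonROI:
    return PolygonROI(np.asarray(json.loads(Path(path).read_text())["vertices"]))


def save_trial(path, trial: RampTrial) -> None:
    """Trial time series as CSV with the documented column header."""
    pd.DataFrame({c: getattr(trial, c) for c in TRIAL_COLUMNS}).to_csv(path, index=False)


def load_trial(path) -> RampTrial:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    return RampTrial(**{c: df[c].to_numpy() for c in TRIAL_COLUMNS})


def save_config(path, config: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))
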