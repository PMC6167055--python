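"""Reading and writing the package's on-disk formats.

Images are 16-bit unsigned single- or multi-page TIFF (one page per channel)
with ground truth or ROI metadata in a JSON sidecar; tables are CSV with a
header row; calibrations are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .density import SurfaceDensityCalibration


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_scene_tiff(path: str | Path, image: np.ndarray,
                     record: dict | None = None) -> Path:
    """Write a (C, H, W) image as 16-bit multi-page TIFF plus JSON sidecar."""
    path = Path(path)
    data = np.clip(np.rint(np.asarray(image)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    if record is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(_jsonable(record), indent=1))
    return path


def read_scene_tiff(path: str | Path) -> tuple[np.ndarray, dict | None]:
    """Read a scene TIFF back as float array plus its sidecar (if present)."""
    path = Path(path)
    image = tifffile.imread(path).astype(float)
    sidecar = path.with_suffix(path.suffix + ".json")
    record = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return image, record


def save_calibration(path: str | Path, cal: SurfaceDensityCalibration) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(cal), indent=1))
    return path


def load_calibration(path: str | Path) -> SurfaceDensityCalibration:
    return SurfaceDensityCalibration(**json.loads(Path(path).read_text()))
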