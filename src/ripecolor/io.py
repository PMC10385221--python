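"""File plumbing: images, Lab CSVs, brightness standards, stage tables."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .colorimetry import LabColor, StageTable
from .errors import InvalidInputError
from .illumination import BrightnessComponents, StandardBrightness

__all__ = [
    "load_image", "save_image",
    "read_lab_csv", "write_lab_csv",
    "load_standard_brightness", "save_standard_brightness",
    "load_stage_table", "save_stage_table",
]


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG photograph as an H×W×3 uint8 RGB raster.

    Grayscale images are broadcast to three channels; an alpha channel is
    dropped.
    """
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise InvalidInputError(f"{path}: not an RGB image (shape {arr.shape})")
    return np.ascontiguousarray(arr[:, :, :3]).astype(np.uint8)


def save_image(path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_lab_csv(path) -> list[LabColor]:
    """Read spectrometer readings from a CSV with header ``L,a,b``."""
    df = pd.read_csv(path)
    missing = {"L", "a", "b"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    return [LabColor(float(r.L), float(r.a), float(r.b)) for r in df.itertuples()]


def write_lab_csv(path, readings) -> None:
    pd.DataFrame([(r.L, r.a, r.b) for r in readings],
                 columns=["L", "a", "b"]).to_csv(path, index=False)


# Component keys as they appear in the reference-brightness schema
_SB_KEYS = {"ob": "OB", "br": "BR", "bg": "BG", "bb": "BB",
            "cr": "CR", "cg": "CG", "cb": "CB",
            "gr": "GR", "gg": "GG", "gb": "GB"}


def save_standard_brightness(path, sb: StandardBrightness) -> None:
    d = sb.components.to_dict()
    payload = {_SB_KEYS[k]: v for k, v in d.items()}
    payload["n_images"] = sb.n_images
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_standard_brightness(path) -> StandardBrightness:
    payload = json.loads(Path(path).read_text())
    inv = {v: k for k, v in _SB_KEYS.items()}
    try:
        comps = BrightnessComponents(**{inv[k]: float(payload[k]) for k in _SB_KEYS.values()})
    except KeyError as e:
        raise InvalidInputError(f"{path}: missing brightness component {e}") from e
    return StandardBrightness(comps, int(payload.get("n_images", 1)))


def save_stage_table(path, table: StageTable) -> None:
    Path(path).write_text(json.dumps(table.to_dict(), indent=2) + "\n")


def load_stage_table(path) -> StageTable:
    return StageTable.from_dict(json.loads(Path(path).read_text()))
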