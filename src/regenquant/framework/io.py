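"""File I/O helpers: TIFF stacks, tables, annotations, configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from ..errors import InputError

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "write_table",
    "read_json",
    "write_json",
    "load_yaml_config",
]


def read_image_stack(path):
    """Read a TIFF as ``(array, metadata)``; pages keep acquisition order.

    ``metadata['pixel_size_um']`` is populated from the TIFF resolution
    tags when present, else ``None`` (callers must then require an
    explicit ``--pixel-size`` flag).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        array = tif.asarray()
        pixel_size = None
        page = tif.pages[0]
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is not None and res.value[0] and unit is not None:
            num, den = res.value
            per_unit = num / den
            if per_unit > 0:
                scale = {2: 25400.0, 3: 10000.0}.get(
                    getattr(unit.value, "value", unit.value)
                )
                if scale:
                    pixel_size = scale / per_unit
    return array, {"pixel_size_um": pixel_size, "n_pages": array.shape[0] if array.ndim == 3 else 1}


def write_image_stack(array, path, pixel_size_um: float | None = None):
    """Write a 2D image or 3D stack as multi-page TIFF."""
    array = np.asarray(array)
    kwargs = {}
    if pixel_size_um:
        per_cm = 10000.0 / pixel_size_um
        kwargs = {"resolution": (per_cm, per_cm), "resolutionunit": "CENTIMETER"}
    tifffile.imwrite(Path(path), array.astype(np.float32), **kwargs)


def write_table(records, path):
    """Write records (DataFrame or list of dicts) to CSV with headers."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    df.to_csv(Path(path), index=False)
    return df


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path):
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def load_yaml_config(path):
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
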