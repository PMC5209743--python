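"""File formats: TIFF/OME-TIFF stacks, label masks, descriptor CSVs, JSON.

TIFF handling goes through tifffile; tables through pandas.  Descriptor
CSVs carry one row per nucleus with the 104 named columns plus
``nucleus_id``, ``condition`` and ``source_file``, and a JSON sidecar
records the extraction configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .image import DEFAULT_PIXEL_SIZE_UM, Channel, ImageStack
from .texture import TextureConfig, descriptor_names

META_COLUMNS = ["nucleus_id", "condition", "source_file"]


def read_stack(
    path,
    channel: Channel = Channel.COMPOSITE,
    pixel_size_um: float | None = None,
) -> ImageStack:
    """Read a (multi-page) TIFF/OME-TIFF as a z-stack of one channel.

    Pixel size is taken from OME metadata when present, else the default
    acquisition geometry (23.25 um field at 1024 px) unless overridden.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        planes = tif.asarray()
        if pixel_size_um is None:
            pixel_size_um = _ome_pixel_size(tif) or DEFAULT_PIXEL_SIZE_UM
    planes = np.atleast_2d(np.asarray(planes, dtype=float))
    if planes.ndim == 2:
        planes = planes[None]
    if planes.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D or 3-D grayscale TIFF")
    return ImageStack(planes, channel=channel, pixel_size_um=pixel_size_um)


def _ome_pixel_size(tif: tifffile.TiffFile) -> float | None:
    try:
        import xml.etree.ElementTree as ET

        if not tif.ome_metadata:
            return None
        root = ET.fromstring(tif.ome_metadata)
        for el in root.iter():
            size = el.attrib.get("PhysicalSizeX")
            if size is not None:
                return float(size)
    except Exception:
        return None
    return None


def write_stack(path, stack: ImageStack) -> None:
    """Write a z-stack as multi-page OME-TIFF with pixel-size metadata."""
    tifffile.imwrite(
        Path(path),
        stack.planes.astype(np.float32),
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeY": stack.pixel_size_um,
        },
    )


def read_mask(path) -> np.ndarray:
    """Read a label image (0 = background) as a boolean mask."""
    arr = tifffile.imread(Path(path))
    return np.asarray(arr) > 0


def write_mask(path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(mask, dtype=np.uint8))


def write_descriptors(
    path,
    features: pd.DataFrame,
    conditions,
    source_files=None,
    cfg: TextureConfig | None = None,
) -> None:
    """Write the per-nucleus descriptor table plus its config sidecar."""
    path = Path(path)
    out = features.copy()
    out.insert(0, "source_file", source_files if source_files is not None else "")
    out.insert(0, "condition", list(conditions))
    out.insert(0, "nucleus_id", [f"nucleus_{i:04d}" for i in range(len(out))])
    out.to_csv(path, index=False)
    cfg = cfg or TextureConfig()
    sidecar = {"texture_config": asdict(cfg), "schema": "chromatex-descriptors-v1"}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_descriptors(path):
    """Read a descriptor CSV back into (features, conditions)."""
    df = pd.read_csv(Path(path))
    feature_cols = [c for c in df.columns if c not in META_COLUMNS]
    missing = set(descriptor_names()) - set(feature_cols)
    if missing:
        raise ValueError(f"descriptor CSV missing columns: {sorted(missing)[:3]}...")
    return df[descriptor_names()], df["condition"]


def read_iem_counts(path) -> pd.DataFrame:
    """Immunogold count table: condition, k4_eu, k27_eu, k4_het, k27_het."""
    df = pd.read_csv(Path(path))
    required = {"condition", "k4_eu", "k27_eu", "k4_het", "k27_het"}
    if not required.issubset(df.columns):
        raise ValueError(f"IEM CSV needs columns {sorted(required)}")
    return df


def read_fret_table(path, calibration_path=None) -> pd.DataFrame:
    """FRET intensity triples (A, B, C); calibration JSON/CSV adds b, c, a."""
    df = pd.read_csv(Path(path))
    if not {"A", "B", "C"}.issubset(df.columns):
        raise ValueError("FRET CSV needs columns A, B, C")
    if calibration_path is not None:
        cal_path = Path(calibration_path)
        if cal_path.suffix == ".json":
            cal = json.loads(cal_path.read_text())
        else:
            cal = pd.read_csv(cal_path).iloc[0].to_dict()
        for key in ("b", "c"):
            df[key] = float(cal[key])
        df["a"] = float(cal.get("a", 0.0))
    return df
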