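"""Reading and writing stacks, manifests, label images and measurement tables.

Stacks are stored as OME-TIFF with axes CZYX and physical voxel sizes in µm;
reading honors the precedence: explicit spacing override > embedded metadata
> error.  Ground-truth manifests are JSON; measurements and comparison
reports are CSV with '.' decimal separator and unit-suffixed column names.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .image import ImageStack
from .segmentation import SegmentedObject
from .synthetic import NucleusGroundTruth

__all__ = [
    "write_stack",
    "read_stack",
    "write_manifest",
    "read_manifest",
    "write_label_image",
    "records_to_frame",
    "write_records_csv",
]


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a multi-channel stack as OME-TIFF with spacing metadata."""
    dz, dy, dx = stack.spacing
    tifffile.imwrite(
        str(path),
        stack.voxels,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": list(stack.channel_names)},
        },
    )


def _spacing_from_ome(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        pixels = root.find(".//ome:Pixels", ns)
        if pixels is None:
            return None
        dz = pixels.get("PhysicalSizeZ")
        dy = pixels.get("PhysicalSizeY")
        dx = pixels.get("PhysicalSizeX")
        if None in (dz, dy, dx):
            return None
        return float(dz), float(dy), float(dx)
    except Exception:
        return None


def _channel_names_from_ome(tif: tifffile.TiffFile, n: int) -> tuple[str, ...]:
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        names = [c.get("Name") for c in root.findall(".//ome:Channel", ns)]
        if len(names) == n and all(names):
            return tuple(names)
    except Exception:
        pass
    return tuple(f"ch{i}" for i in range(n))


def read_stack(
    path: str | Path,
    spacing_override: Sequence[float] | None = None,
    channel_names: Sequence[str] | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF stack.

    ``spacing_override`` (dz, dy, dx in µm) takes precedence over embedded
    metadata; a plain TIFF without metadata and without an override is an
    error.  2D/3D files are promoted to (C, Z, Y, X).
    """
    if spacing_override is not None:
        if len(spacing_override) != 3 or any(s <= 0 for s in spacing_override):
            raise ValueError(
                f"spacing override must be 3 positive values (dz, dy, dx), got {spacing_override}"
            )
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes  # e.g. "CZYX", "ZYX", "ZCYX"
        # tifffile guesses "S" (samples) or "Q" (unknown) for plain TIFFs;
        # treat them as channel / z axes respectively
        axes = axes.replace("S", "C").replace("Q", "Z")
        spacing = None if spacing_override else (
            _spacing_from_ome(tif) if tif.ome_metadata else None
        )
        # normalize axis order to CZYX
        if axes in ("CZYX", "ZYX", "YX"):
            pass
        elif axes == "ZCYX":
            data = np.moveaxis(data, 1, 0)
        elif set(axes) <= set("CZYX"):
            order = [axes.index(a) for a in "CZYX" if a in axes]
            data = np.transpose(data, order)
        else:
            raise ValueError(f"unsupported axis layout {axes!r} in {path}")
        while data.ndim < 4:
            data = data[None]
        names = None
        if channel_names is not None:
            names = tuple(channel_names)
        elif tif.ome_metadata:
            names = _channel_names_from_ome(tif, data.shape[0])
    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    if spacing is None:
        raise ValueError(
            f"{path} carries no voxel-spacing metadata; pass --spacing dz dy dx"
        )
    if data.dtype != np.uint8:
        data = np.clip(data, 0, 255).astype(np.uint8)
    return ImageStack(
        voxels=data,
        spacing=spacing,
        channel_names=names or (),
    )


def write_manifest(truths: Sequence[NucleusGroundTruth], path: str | Path) -> None:
    """Write the ground-truth manifest of a population as JSON."""
    Path(path).write_text(
        json.dumps({"nuclei": [t.to_dict() for t in truths]}, indent=1)
    )


def read_manifest(path: str | Path) -> list[NucleusGroundTruth]:
    doc = json.loads(Path(path).read_text())
    return [NucleusGroundTruth.from_dict(d) for d in doc["nuclei"]]


def write_label_image(
    objects: Sequence[SegmentedObject],
    shape: tuple[int, int, int],
    path: str | Path,
) -> None:
    """Write a 16-bit label image (0 background, object labels elsewhere)."""
    labels = np.zeros(shape, dtype=np.uint16)
    for obj in objects:
        labels[tuple(obj.voxels.T)] = obj.label
    tifffile.imwrite(str(path), labels)


def records_to_frame(rows: Sequence[dict]) -> pd.DataFrame:
    df = pd.DataFrame(list(rows))
    if "nucleus_id" in df.columns:
        df = df.sort_values("nucleus_id").reset_index(drop=True)
    return df


def write_records_csv(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write a measurements/report CSV; an optional comment line records provenance."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False, float_format="%.6g")
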