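"""OME-TIFF and table I/O.

Volumes are stored as multichannel OME-TIFF with axes ``CZYX``, channel names
(``nucleus`` / ``pdl1`` / ``lipid``) and physical voxel sizes in the OME
metadata; a round trip reproduces the arrays exactly.  Ground-truth and cell
tables are plain CSV with documented column schemas.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .image import CHANNEL_ROLES, VolumeImage
from .phantom import GroundTruth

TRUTH_COLUMNS = ["cell_id", "z_um", "y_um", "x_um", "radius_um", "is_tumor", "is_pdl1_positive"]


class MissingMetadataError(ValueError):
    """Required acquisition metadata is absent and no override was supplied."""


def write_volume(volume: VolumeImage, path: str | Path) -> Path:
    """Write a volume as OME-TIFF with channel names and voxel sizes."""
    path = Path(path)
    names = [None] * volume.n_channels
    for role, idx in volume.channel_roles.items():
        names[idx] = role
    names = [n or f"channel{i}" for i, n in enumerate(names)]
    vz, vy, vx = volume.voxel_size_um
    tifffile.imwrite(
        path,
        volume.data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeZ": vz,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": vy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": vx,
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": names},
        },
    )
    return path


def _parse_ome(ome_xml: str) -> tuple[dict, list[str]]:
    """Physical sizes and channel names from an OME-XML string."""
    root = ET.fromstring(ome_xml)

    def _local(tag: str) -> str:
        return tag.rsplit("}", 1)[-1]

    pixels = None
    for el in root.iter():
        if _local(el.tag) == "Pixels":
            pixels = el
            break
    sizes: dict = {}
    names: list[str] = []
    if pixels is not None:
        for key in ("PhysicalSizeZ", "PhysicalSizeY", "PhysicalSizeX"):
            if key in pixels.attrib:
                sizes[key] = float(pixels.attrib[key])
        for el in pixels:
            if _local(el.tag) == "Channel":
                names.append(el.attrib.get("Name", ""))
    return sizes, names


def read_volume(
    path: str | Path,
    voxel_size_um: tuple[float, float, float] | None = None,
    channel_roles: dict[str, int] | None = None,
    expected_channels: int | None = None,
) -> VolumeImage:
    """Read an OME-TIFF (or plain TIFF with overrides) as a VolumeImage.

    ``voxel_size_um`` and ``channel_roles`` override whatever the metadata
    carries; a plain TIFF without voxel-size metadata *requires* the
    ``voxel_size_um`` override and raises :class:`MissingMetadataError`
    otherwise.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        axes = series.axes
        ome_xml = tif.ome_metadata

    # normalize axes to CZYX; unknown axes (Q/S/I...) are assigned, in order,
    # to whichever of C then Z is still missing; leftover singletons squeeze
    if "S" in axes and "C" not in axes:
        axes = axes.replace("S", "C")
    unknown = [i for i, a in enumerate(axes) if a not in "CZYX"]
    missing = [a for a in "CZ" if a not in axes]
    chars = list(axes)
    for i in unknown:
        if missing:
            chars[i] = missing.pop(0)
        elif data.shape[i] == 1:
            chars[i] = "_"
        else:
            raise ValueError(f"unsupported TIFF axes {axes!r} for shape {data.shape}")
    if "_" in chars:
        keep = tuple(i for i, a in enumerate(chars) if a != "_")
        data = data.reshape([data.shape[i] for i in keep])
        chars = [a for a in chars if a != "_"]
    axes = "".join(chars)
    if len(set(axes)) != len(axes):
        raise ValueError(f"unsupported TIFF axes {axes!r}")
    for missing in set("CZYX") - set(axes):
        data = data[np.newaxis]
        axes = missing + axes
    order = [axes.index(a) for a in "CZYX"]
    data = np.transpose(data, order)

    sizes: dict = {}
    names: list[str] = []
    if ome_xml:
        sizes, names = _parse_ome(ome_xml)

    if voxel_size_um is None:
        try:
            voxel_size_um = (sizes["PhysicalSizeZ"], sizes["PhysicalSizeY"], sizes["PhysicalSizeX"])
        except KeyError as exc:
            raise MissingMetadataError(
                f"{path.name}: voxel size {exc.args[0]} missing from metadata; "
                "pass voxel_size_um explicitly"
            ) from None

    if channel_roles is None:
        channel_roles = {n: i for i, n in enumerate(names) if n in CHANNEL_ROLES}
        if not channel_roles:
            raise MissingMetadataError(
                f"{path.name}: no recognizable channel names in metadata "
                f"(found {names or 'none'}); pass channel_roles explicitly"
            )
    if expected_channels is not None and data.shape[0] != expected_channels:
        raise ValueError(
            f"{path.name}: expected {expected_channels} channels, found {data.shape[0]} "
            f"(names: {names or 'unnamed'})"
        )
    return VolumeImage(data=data, voxel_size_um=voxel_size_um, channel_roles=channel_roles)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_truth_csv(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    truth.cells.to_csv(path, index=False, columns=TRUTH_COLUMNS)
    return path


def read_truth_csv(path: str | Path, depth_um: float) -> GroundTruth:
    cells = pd.read_csv(path)
    missing = set(TRUTH_COLUMNS) - set(cells.columns)
    if missing:
        raise ValueError(f"truth CSV is missing columns: {sorted(missing)}")
    cells["is_tumor"] = cells["is_tumor"].astype(bool)
    cells["is_pdl1_positive"] = cells["is_pdl1_positive"].astype(bool)
    return GroundTruth(cells, depth_um=depth_um)


def write_phantom(volume: VolumeImage, truth: GroundTruth, directory: str | Path,
                  stem: str = "phantom") -> tuple[Path, Path]:
    """Write one phantom as ``<stem>.ome.tif`` plus ``<stem>_truth.csv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tif = write_volume(volume, directory / f"{stem}.ome.tif")
    csv = write_truth_csv(truth, directory / f"{stem}_truth.csv")
    return tif, csv


def write_label_stack(labelmaps, path: str | Path) -> Path:
    """Per-plane nucleus label maps as a multi-page TIFF."""
    path = Path(path)
    stack = np.stack([lm.labels.astype(np.int32) for lm in labelmaps])
    tifffile.imwrite(path, stack)
    return path


def write_mask_stack(masks, path: str | Path) -> Path:
    """Per-plane tumor masks as a multi-page TIFF (uint8 0/1)."""
    path = Path(path)
    stack = np.stack([m.mask.astype(np.uint8) for m in masks])
    tifffile.imwrite(path, stack)
    return path
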