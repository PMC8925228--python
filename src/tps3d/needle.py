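"""Pseudo-needle-biopsy construction.

A core-needle biopsy is simulated by cropping an axis-aligned track — by
default 8 mm long and 1 mm wide, spanning the entire z extent — through the
volume's intensity-weighted centre of mass.  When the track would exceed the
volume laterally it is shifted inward to fit (with the full 8 mm track in an
8 mm field, any off-centre centre of mass would otherwise always fail), and
a track longer than the volume is clamped to the full extent with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .image import VolumeImage
from .phantom import GroundTruth


@dataclass
class NeedleTrack:
    """Geometry of one pseudo-needle crop.

    ``bounds_vox`` are 0-based half-open voxel ranges ``(z, y, x)``; the z
    range always covers the full depth.
    """

    length_um: float
    width_um: float
    center_um: tuple[float, float]  # (y, x) of the centre of mass
    axis: str  # "x" or "y": which lateral axis carries the length
    bounds_vox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def bounds_um(self, voxel_size_um: tuple[float, float, float]):
        """Half-open physical bounds of the crop box, (z, y, x) pairs in μm."""
        return tuple(
            (lo * v, hi * v) for (lo, hi), v in zip(self.bounds_vox, voxel_size_um)
        )

    def to_dict(self, voxel_size_um: tuple[float, float, float] | None = None) -> dict:
        d = {
            "length_um": self.length_um,
            "width_um": self.width_um,
            "center_um": list(self.center_um),
            "axis": self.axis,
            "bounds_vox": [list(b) for b in self.bounds_vox],
        }
        if voxel_size_um is not None:
            d["bounds_um"] = [list(b) for b in self.bounds_um(voxel_size_um)]
        return d


def center_of_mass(volume: VolumeImage, channel_role: str = "nucleus") -> tuple[float, float, float]:
    """Intensity-weighted mean coordinate of one channel, in μm (z, y, x).

    The nucleus channel is the default tissue-density proxy.  Raises on an
    all-zero channel (the centre of mass is undefined).
    """
    chan = np.asarray(volume.channel(channel_role), dtype=np.float64)
    total = chan.sum()
    if total <= 0:
        raise ValueError(f"channel {channel_role!r} has zero total intensity; centre of mass undefined")
    com_vox = ndi.center_of_mass(chan)
    return tuple(c * v for c, v in zip(com_vox, volume.voxel_size_um))


def _clamped_range(center_vox: float, span_vox: int, n: int, what: str) -> tuple[int, int]:
    if span_vox >= n:
        if span_vox > n:
            warnings.warn(
                f"requested needle {what} exceeds the volume; clamping to full extent",
                stacklevel=3,
            )
        return 0, n
    lo = int(round(center_vox - span_vox / 2))
    lo = min(max(lo, 0), n - span_vox)
    return lo, lo + span_vox


def plan_track(
    volume: VolumeImage,
    length_um: float = 8000.0,
    width_um: float = 1000.0,
    axis: str = "x",
    channel_role: str = "nucleus",
) -> NeedleTrack:
    """Plan the needle crop box through the volume's centre of mass."""
    if axis not in ("x", "y"):
        raise ValueError("needle axis must be 'x' or 'y'")
    if length_um <= 0 or width_um <= 0:
        raise ValueError("needle length and width must be positive")
    _, vy, vx = volume.voxel_size_um
    _, ny, nx = volume.shape_zyx
    comz, comy, comx = center_of_mass(volume, channel_role)

    len_y_um, len_x_um = (width_um, length_um) if axis == "x" else (length_um, width_um)
    span_y = max(1, round(len_y_um / vy))
    span_x = max(1, round(len_x_um / vx))
    ybounds = _clamped_range(comy / vy, span_y, ny, "width" if axis == "x" else "length")
    xbounds = _clamped_range(comx / vx, span_x, nx, "length" if axis == "x" else "width")
    return NeedleTrack(
        length_um=length_um,
        width_um=width_um,
        center_um=(comy, comx),
        axis=axis,
        bounds_vox=((0, volume.n_planes), ybounds, xbounds),
    )


def crop_pseudo_needle(
    volume: VolumeImage, track: NeedleTrack
) -> tuple[VolumeImage, tuple[float, float, float]]:
    """Extract the needle subvolume.

    Returns the cropped :class:`VolumeImage` plus the physical offset
    ``(z, y, x)`` in μm that maps coordinates in the crop back to the parent
    frame (``parent = crop + offset``).
    """
    (z0, z1), (y0, y1), (x0, x1) = track.bounds_vox
    nz, ny, nx = volume.shape_zyx
    if not (0 <= z0 < z1 <= nz and 0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
        raise ValueError(f"track bounds {track.bounds_vox} do not fit volume shape {volume.shape_zyx}")
    sub = VolumeImage(
        data=volume.data[:, z0:z1, y0:y1, x0:x1].copy(),
        voxel_size_um=volume.voxel_size_um,
        channel_roles=dict(volume.channel_roles),
    )
    vz, vy, vx = volume.voxel_size_um
    return sub, (z0 * vz, y0 * vy, x0 * vx)


def crop_truth(truth: GroundTruth, track: NeedleTrack,
               voxel_size_um: tuple[float, float, float]) -> GroundTruth:
    """Ground-truth cells whose centroids fall inside the crop box.

    Coordinates in the returned truth are shifted into the crop frame so that
    they compare directly against cells detected on the cropped volume.
    """
    (z_rng, y_rng, x_rng) = track.bounds_um(voxel_size_um)
    sub = truth.subset(z_um=z_rng, y_um=y_rng, x_um=x_rng)
    cells = sub.cells.copy()
    cells["z_um"] -= z_rng[0]
    cells["y_um"] -= y_rng[0]
    cells["x_um"] -= x_rng[0]
    depth = z_rng[1] - z_rng[0]
    return GroundTruth(cells, depth_um=depth)
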