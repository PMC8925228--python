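"""In-memory container for multichannel 3D fluorescence volumes.

Conventions used throughout the package:

* array axis order is ``(channel, z, y, x)``;
* voxel indices are 0-based and intervals are half-open;
* the physical coordinate of voxel ``i`` along an axis with voxel size ``v``
  is ``i * v`` micrometres (voxel centres on a grid anchored at 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical channel roles: nuclear dye, PD-L1 marker, lipophilic counterstain
CHANNEL_ROLES = ("nucleus", "pdl1", "lipid")


class ChannelRoleError(KeyError):
    """A requested channel role is not mapped to any channel of the volume."""


class ShapeMismatchError(ValueError):
    """Two per-plane arrays that must share a shape do not."""


@dataclass
class VolumeImage:
    """A 3-channel (or more) z-stack with physical voxel sizes.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_z, n_y, n_x)``.
    voxel_size_um
        Physical voxel size ``(z, y, x)`` in micrometres.
    channel_roles
        Mapping from role name (e.g. ``"nucleus"``) to channel index.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    channel_roles: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"volume data must be 4-D (channel, z, y, x); got shape {self.data.shape}"
            )
        if min(self.data.shape) < 1:
            raise ValueError("every volume axis must have extent >= 1")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel_size_um must be three positive values (z, y, x)")
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < self.data.shape[0]:
                raise ChannelRoleError(
                    f"role {role!r} maps to channel {idx}, but the volume has "
                    f"{self.data.shape[0]} channels"
                )

    # -- basic geometry ----------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def depth_um(self) -> float:
        """Axial extent covered by the plane grid, in micrometres."""
        return self.n_planes * self.voxel_size_um[0]

    # -- channel access ----------------------------------------------------
    def channel_index(self, role: str) -> int:
        try:
            return self.channel_roles[role]
        except KeyError:
            raise ChannelRoleError(
                f"channel role {role!r} not found; available roles: "
                f"{sorted(self.channel_roles)}"
            ) from None

    def channel(self, role: str) -> np.ndarray:
        """3-D array (z, y, x) for one channel role."""
        return self.data[self.channel_index(role)]

    def plane(self, role: str, z: int) -> np.ndarray:
        """Single 2-D plane (y, x) of one channel."""
        return self.data[self.channel_index(role), z]

    def multichannel_plane(self, z: int) -> np.ndarray:
        """All channels of one plane, shape (channel, y, x)."""
        return self.data[:, z]

    def plane_depth_um(self, z: int) -> float:
        return z * self.voxel_size_um[0]
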