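"""Per-plane tumor-region masks and the cell-instance accuracy metric.

The tumor-region stage is pluggable: any object implementing
:class:`MaskerInterface` can produce the per-plane boolean mask (so a trained
segmentation network can be dropped in).  The shipped baseline is a classical
density heuristic — a smoothed nuclear-intensity map thresholded relative to
its maximum, then morphologically closed — documented as a baseline, not as a
learned model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian

from .image import ShapeMismatchError
from .nuclei import NucleusLabelMap


class UndefinedMetricError(ZeroDivisionError):
    """An evaluation metric has an empty denominator."""


@dataclass
class TumorMask:
    plane_index: int
    mask: np.ndarray  # 2-D boolean

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.dtype != bool:
            raise ValueError("tumor mask must be strictly boolean")
        if self.mask.ndim != 2:
            raise ValueError("tumor mask must be 2-D")


@runtime_checkable
class MaskerInterface(Protocol):
    """Contract for tumor-region models.

    ``predict`` must be deterministic for fixed parameters; ``metadata``
    identifies the model and its parameters for run logs.
    """

    name: str

    def predict(self, plane: np.ndarray, voxel_size_yx: tuple[float, float],
                plane_index: int) -> TumorMask: ...

    def metadata(self) -> dict: ...


@dataclass
class BaselineMasker:
    """Nuclear-density tumor-region baseline.

    The nucleus channel is first segmented into nuclear foreground (the same
    contrast-guarded Li threshold the nucleus segmentation uses); the binary
    foreground is smoothed with a wide Gaussian (``smooth_sigma_um``) into a
    local nuclear-coverage map, which is thresholded at the absolute level
    ``min_density`` (fraction of area covered by nuclei within the kernel)
    and morphologically closed.  Cell-dense regions therefore mask as tumor,
    cell-free regions do not.
    """

    smooth_sigma_um: float = 20.0
    min_density: float = 0.05
    closing_radius_um: float = 10.0
    name: str = field(default="baseline-density", init=False)

    def predict(self, plane: np.ndarray, voxel_size_yx: tuple[float, float] = (1.0, 1.0),
                plane_index: int = 0) -> TumorMask:
        """``plane`` is the multichannel plane (channel, y, x) or a bare
        nucleus-channel plane (y, x); channel 0 is taken as the nucleus dye
        in the multichannel case."""
        from .nuclei import _threshold_foreground

        arr = np.asarray(plane, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[0]
        if arr.max() == arr.min():
            return TumorMask(plane_index, np.zeros(arr.shape, dtype=bool))
        fg = _threshold_foreground(arr, min_contrast=5.0)
        if fg is None or not fg.any():
            return TumorMask(plane_index, np.zeros(arr.shape, dtype=bool))
        vy, vx = voxel_size_yx
        density = gaussian(fg.astype(np.float32),
                           sigma=(self.smooth_sigma_um / vy, self.smooth_sigma_um / vx),
                           preserve_range=True)
        mask = density > self.min_density
        r = max(1, round(self.closing_radius_um / min(vy, vx)))
        yy, xx = np.ogrid[-r : r + 1, -r : r + 1]
        disk = yy**2 + xx**2 <= r**2
        mask = ndi.binary_closing(mask, structure=disk)
        return TumorMask(plane_index, mask)

    def metadata(self) -> dict:
        return {
            "name": self.name,
            "smooth_sigma_um": self.smooth_sigma_um,
            "min_density": self.min_density,
            "closing_radius_um": self.closing_radius_um,
        }


@dataclass
class ConstantMasker:
    """Trivial masker marking the whole plane as tumor (or none of it).

    Useful for specimens known to be tumor throughout and for phantom studies
    where tumor status has no spatial structure.
    """

    value: bool = True
    name: str = field(default="constant", init=False)

    def predict(self, plane: np.ndarray, voxel_size_yx: tuple[float, float] = (1.0, 1.0),
                plane_index: int = 0) -> TumorMask:
        arr = np.asarray(plane)
        shape = arr.shape[-2:]
        return TumorMask(plane_index, np.full(shape, self.value, dtype=bool))

    def metadata(self) -> dict:
        return {"name": self.name, "value": self.value}


def assign_tumor_status(
    nuclei: NucleusLabelMap, mask: TumorMask, voxel_size_yx: tuple[float, float] = (1.0, 1.0)
) -> np.ndarray:
    """Boolean tumor flag per nucleus: centroid voxel inside the mask.

    The membership rule is centroid-in-mask, which is unambiguous for nuclei
    partially overlapping the mask border.
    """
    if nuclei.labels.shape != mask.mask.shape:
        raise ShapeMismatchError(
            f"label map shape {nuclei.labels.shape} != mask shape {mask.mask.shape}"
        )
    if nuclei.n_nuclei == 0:
        return np.zeros(0, dtype=bool)
    vy, vx = voxel_size_yx
    iy = np.clip(np.round(nuclei.centroids_um[:, 0] / vy).astype(int), 0, mask.mask.shape[0] - 1)
    ix = np.clip(np.round(nuclei.centroids_um[:, 1] / vx).astype(int), 0, mask.mask.shape[1] - 1)
    return mask.mask[iy, ix]


def cell_instance_accuracy(
    predicted_flags: np.ndarray, truth_flags: np.ndarray
) -> tuple[float, float]:
    """Primary precision-style metric plus symmetric overall accuracy.

    Primary: the fraction of predicted-tumor cells whose truth flag is also
    tumor.  Secondary: the fraction of cells on which the two flag vectors
    agree.  Raises :class:`UndefinedMetricError` when no cell is predicted
    tumor (the primary metric has no denominator).
    """
    pred = np.asarray(predicted_flags, dtype=bool)
    truth = np.asarray(truth_flags, dtype=bool)
    if pred.shape != truth.shape:
        raise ShapeMismatchError("predicted and truth flag vectors differ in length")
    n_pred = int(pred.sum())
    if n_pred == 0:
        raise UndefinedMetricError("no predicted tumor cells; instance accuracy undefined")
    primary = float((pred & truth).sum()) / n_pred
    overall = float((pred == truth).mean()) if len(pred) else 1.0
    return primary, overall
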