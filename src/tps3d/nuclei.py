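"""Per-plane nuclear segmentation and the count-error evaluation metric.

The segmentation follows a fixed classical recipe on the nuclear-dye channel
of each z plane, processed independently (no 3-D linking — one physical cell
therefore contributes a detection to every plane its nucleus crosses, which is
exactly how the per-plane tumor proportion score is defined downstream):

1. Li minimum-cross-entropy threshold separates foreground from background;
2. holes in the foreground are filled;
3. connected components give rough nucleus labels;
4. within each rough component, local maxima of the Euclidean distance
   transform seed a watershed (run on the negated distance transform) that
   splits touching nuclei.  The watershed can only split rough components,
   never merge them.

A small-object filter then removes fragments below a configurable fraction of
the expected nucleus area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_li
from skimage.segmentation import watershed

from .image import ChannelRoleError, VolumeImage


@dataclass
class SegmentationParams:
    """Tunable knobs of the nuclear segmentation.

    expected_radius_um
        Typical nucleus radius; sets the minimum separation of watershed
        seeds and the small-object cutoff.
    min_size_fraction
        Objects smaller than this fraction of the expected nucleus
        cross-section area are removed (default 0.25).
    smooth_sigma_um
        Optional Gaussian pre-filter before thresholding; 0 disables it.
    min_contrast
        Guard against the threshold collapsing into the background noise on
        nearly-empty planes: the foreground and background class means must
        differ by at least this many background standard deviations.  Until
        they do, Li is re-applied to the above-threshold tail (iterative tail
        thresholding); if separation is never achieved the plane is declared
        background-only.  Must be comfortably below the image signal-to-noise
        ratio.
    """

    expected_radius_um: float = 4.0
    min_size_fraction: float = 0.25
    smooth_sigma_um: float = 0.0
    min_contrast: float = 5.0

    def min_area_px(self, voxel_size_yx: tuple[float, float]) -> float:
        vy, vx = voxel_size_yx
        return self.min_size_fraction * math.pi * self.expected_radius_um**2 / (vy * vx)


@dataclass
class NucleusLabelMap:
    """Segmentation result for one plane.

    ``labels`` is a 2-D integer map (0 = background, k > 0 = nucleus k with
    labels numbered 1..n consecutively); ``centroids_um`` holds the unweighted
    mean voxel coordinate of each nucleus, converted to micrometres, ordered
    by label.
    """

    plane_index: int
    labels: np.ndarray
    centroids_um: np.ndarray  # (n, 2) as (y, x)
    areas_px: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_nuclei(self) -> int:
        return len(self.centroids_um)


def segment_nuclei_plane(
    plane: np.ndarray,
    voxel_size_yx: tuple[float, float] = (1.0, 1.0),
    params: SegmentationParams | None = None,
    plane_index: int = 0,
) -> NucleusLabelMap:
    """Segment the nuclei of a single nuclear-channel plane.

    An all-background or constant plane yields a valid empty result
    (``n_nuclei == 0``), not an error.
    """
    params = params or SegmentationParams()
    plane = np.asarray(plane, dtype=np.float32)
    if plane.ndim != 2 or plane.size == 0:
        raise ValueError("plane must be a non-empty 2-D array")
    if not np.all(np.isfinite(plane)):
        raise ValueError("plane intensities must be finite")
    vy, vx = voxel_size_yx

    work = plane
    if params.smooth_sigma_um > 0:
        work = gaussian(plane, sigma=(params.smooth_sigma_um / vy, params.smooth_sigma_um / vx),
                        preserve_range=True)

    if work.max() == work.min():  # constant plane: nothing to threshold
        return _empty_result(plane_index, plane.shape)

    fg = _threshold_foreground(work, params.min_contrast)
    if fg is None or not fg.any():
        return _empty_result(plane_index, plane.shape)
    fg = ndi.binary_fill_holes(fg)

    rough, n_rough = ndi.label(fg)
    dist = ndi.distance_transform_edt(fg, sampling=(vy, vx))
    min_dist_px = max(1, round(params.expected_radius_um / min(vy, vx)))
    peaks = peak_local_max(
        dist, min_distance=min_dist_px, labels=rough, exclude_border=False
    )
    marker_mask = np.zeros(fg.shape, dtype=bool)
    marker_mask[tuple(peaks.T)] = True
    markers, _ = ndi.label(marker_mask)
    labels = watershed(-dist, markers, mask=fg)

    # rough components that received no seed (possible for tiny fragments)
    # keep their rough label rather than vanishing
    orphan = fg & (labels == 0)
    if orphan.any():
        extra, n_extra = ndi.label(orphan)
        labels = labels + np.where(extra > 0, extra + labels.max(), 0)

    # small-object filter
    min_area = params.min_area_px((vy, vx))
    areas = np.bincount(labels.ravel())
    keep = np.flatnonzero(areas >= min_area)
    keep = keep[keep > 0]
    remap = np.zeros(len(areas), dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1)
    labels = remap[labels]

    if len(keep) == 0:
        return _empty_result(plane_index, plane.shape)
    centroids_px = np.array(ndi.center_of_mass(np.ones_like(labels), labels,
                                               index=np.arange(1, len(keep) + 1)))
    centroids_um = centroids_px * np.array([vy, vx])
    return NucleusLabelMap(
        plane_index=plane_index,
        labels=labels,
        centroids_um=centroids_um,
        areas_px=areas[keep],
    )


def _threshold_foreground(work: np.ndarray, min_contrast: float) -> np.ndarray | None:
    """Li threshold with an iterative tail guard.

    On sparse-signal planes Li's fixed point can sit inside the background
    noise, flagging half the plane as foreground.  While the class means are
    separated by fewer than ``min_contrast`` background standard deviations,
    the threshold is recomputed on the above-threshold tail.  Returns the
    foreground mask, or ``None`` when no acceptable separation exists
    (background-only plane).
    """
    t = threshold_li(work)
    for _ in range(12):
        fg = work > t
        if not fg.any() or fg.all():
            return None
        bg_vals = work[~fg]
        sigma = float(bg_vals.std())
        contrast = float(work[fg].mean() - bg_vals.mean())
        if contrast >= min_contrast * max(sigma, 1e-12):
            return fg
        tail = work[fg]
        if tail.max() == tail.min():
            return None
        t_new = threshold_li(tail)
        if not t_new > t:  # no progress; give up rather than loop
            return None
        t = t_new
    return None


def _empty_result(plane_index: int, shape: tuple[int, int]) -> NucleusLabelMap:
    return NucleusLabelMap(
        plane_index=plane_index,
        labels=np.zeros(shape, dtype=np.int32),
        centroids_um=np.empty((0, 2)),
        areas_px=np.empty(0, dtype=int),
    )


def segment_nuclei_volume(
    volume: VolumeImage, params: SegmentationParams | None = None
) -> list[NucleusLabelMap]:
    """Apply :func:`segment_nuclei_plane` independently to every z plane."""
    if "nucleus" not in volume.channel_roles:
        raise ChannelRoleError("volume has no 'nucleus' channel role configured")
    vy, vx = volume.voxel_size_um[1:]
    chan = volume.channel("nucleus")
    return [
        segment_nuclei_plane(chan[z], (vy, vx), params, plane_index=z)
        for z in range(volume.n_planes)
    ]


def count_error(
    predicted_counts: list[int] | np.ndarray, true_counts: list[int] | np.ndarray
) -> tuple[float, float]:
    """Mean and s.d. of the per-image relative count error.

    The per-image error is ``|predicted - true| / true``; the standard
    deviation uses the n-1 denominator and is reported as 0.0 for a single
    image (documented convention).
    """
    pred = np.asarray(predicted_counts, dtype=float)
    true = np.asarray(true_counts, dtype=float)
    if pred.shape != true.shape or pred.ndim != 1 or len(pred) == 0:
        raise ValueError("predicted and true counts must be equal-length non-empty 1-D lists")
    if np.any(true <= 0):
        raise ValueError("relative count error is undefined for true counts <= 0")
    rel = np.abs(pred - true) / true
    sd = float(np.std(rel, ddof=1)) if len(rel) > 1 else 0.0
    return float(np.mean(rel)), sd
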