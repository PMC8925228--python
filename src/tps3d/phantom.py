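"""Synthetic 3-channel fluorescence phantoms with exact per-cell ground truth.

The generator emulates a cleared-tissue confocal acquisition: a thick section
(default 150 μm deep) imaged in three channels — a nuclear dye, a membranous
PD-L1 marker and a lipophilic counterstain.  Cells are non-overlapping spheres;
every cell contributes a uniform-intensity nuclear blob and a cytoplasmic
lipid blob, and PD-L1-positive tumor cells additionally carry a bright annular
membrane shell in the marker channel.  Positivity is assigned per cell from a
programmable function of depth, so depth gradients in the tumor proportion
score can be simulated with known truth.

Noise model: constant background plus Poisson shot noise plus Gaussian read
noise.  ``snr`` is the peak signal amplitude divided by the background noise
standard deviation; ``snr=None`` produces a noise-free, zero-background volume
(useful for exact-recovery tests).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .image import CHANNEL_ROLES, VolumeImage


class PackingError(RuntimeError):
    """The requested cell count cannot be placed at the minimum spacing."""


class PositivityProfile(BaseModel):
    """Per-depth probability that a tumor cell is PD-L1 positive.

    ``constant``  : probability ``p`` everywhere.
    ``linear``    : probability interpolates from ``p_top`` at depth 0 to
                    ``p_bottom`` at the full depth.
    ``piecewise`` : step function; ``breaks_um`` are the ``len(values)-1``
                    depths at which the probability changes.
    """

    kind: Literal["constant", "linear", "piecewise"] = "constant"
    p: float = 0.2
    p_top: float = 0.0
    p_bottom: float = 0.3
    breaks_um: tuple[float, ...] = ()
    values: tuple[float, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "PositivityProfile":
        probs: tuple[float, ...]
        if self.kind == "constant":
            probs = (self.p,)
        elif self.kind == "linear":
            probs = (self.p_top, self.p_bottom)
        else:
            if len(self.values) != len(self.breaks_um) + 1:
                raise ValueError("piecewise profile needs len(values) == len(breaks_um) + 1")
            if any(b2 <= b1 for b1, b2 in zip(self.breaks_um, self.breaks_um[1:])):
                raise ValueError("breaks_um must be strictly increasing")
            probs = self.values
        if any(not 0.0 <= q <= 1.0 for q in probs):
            raise ValueError("positivity probabilities must lie in [0, 1]")
        return self

    def __call__(self, z_um: float, depth_um: float) -> float:
        if self.kind == "constant":
            return self.p
        if self.kind == "linear":
            t = min(max(z_um / depth_um, 0.0), 1.0)
            return self.p_top + t * (self.p_bottom - self.p_top)
        idx = int(np.searchsorted(np.asarray(self.breaks_um), z_um, side="right"))
        return self.values[idx]


class PhantomConfig(BaseModel):
    """Full description of one synthetic acquisition.

    All physical quantities are micrometres.  The default lateral field is a
    512 μm square at 1 μm/voxel (a scaled-down stand-in for an 8 mm × 8 mm
    region of interest); the default depth of 150 μm matches a thick cleared
    section.  Identical seeds give bit-identical volumes and ground truth.
    """

    field_size_um: tuple[float, float] = (512.0, 512.0)  # (y, x)
    depth_um: float = 150.0
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (z, y, x)
    n_cells: int = 3000
    tumor_fraction: float = 1.0
    positivity_profile: PositivityProfile = Field(default_factory=PositivityProfile)
    nucleus_radius_um: tuple[float, float] = (4.0, 0.5)  # mean, sd (truncated at ±2 sd)
    membrane_thickness_um: float = 1.5
    min_center_distance_um: float | None = None
    #: optional lateral box (y0, y1, x0, x1): tumor cells are placed inside it,
    #: non-tumor cells outside, giving the tumor region spatial structure
    tumor_region_um: tuple[float, float, float, float] | None = None
    snr: float | tuple[float, float, float] | None = 10.0  # per (nucleus, pdl1, lipid)
    background: float = 50.0
    read_noise: float = 2.0
    amplitude: float = 100.0  # noise-free peak signal level
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PhantomConfig":
        if min(self.field_size_um) <= 0 or self.depth_um <= 0:
            raise ValueError("field_size_um and depth_um must be positive")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        mean_r, sd_r = self.nucleus_radius_um
        if mean_r <= 0 or sd_r < 0:
            raise ValueError("nucleus radius mean must be > 0 and sd >= 0")
        if self.membrane_thickness_um <= 0:
            raise ValueError("membrane_thickness_um must be positive")
        if self.background < 0 or self.read_noise < 0:
            raise ValueError("background and read_noise must be >= 0")
        return self

    # -- derived geometry --------------------------------------------------
    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        nz = max(1, round(self.depth_um / self.voxel_size_um[0]))
        ny = max(1, round(self.field_size_um[0] / self.voxel_size_um[1]))
        nx = max(1, round(self.field_size_um[1] / self.voxel_size_um[2]))
        return nz, ny, nx

    @property
    def max_radius_um(self) -> float:
        mean_r, sd_r = self.nucleus_radius_um
        return mean_r + 2.0 * sd_r

    @property
    def spacing_um(self) -> float:
        """Minimum allowed distance between cell centres."""
        if self.min_center_distance_um is not None:
            return self.min_center_distance_um
        return 2.0 * self.max_radius_um + 1.0

    def snr_tuple(self) -> tuple[float, float, float] | None:
        if self.snr is None:
            return None
        if isinstance(self.snr, (int, float)):
            return (float(self.snr),) * 3
        return tuple(float(s) for s in self.snr)  # type: ignore[return-value]

    def signal_amplitudes(self) -> tuple[float, float, float]:
        """Peak signal per channel, in the same units as the background."""
        snr = self.snr_tuple()
        if snr is None:
            return (self.amplitude,) * 3
        sigma_bg = math.sqrt(self.background + self.read_noise**2)
        return tuple(s * sigma_bg for s in snr)  # type: ignore[return-value]


@dataclasses.dataclass
class GroundTruth:
    """Exact per-cell truth for one phantom.

    ``cells`` columns: cell_id, z_um, y_um, x_um, radius_um, is_tumor,
    is_pdl1_positive.  Positivity is defined for tumor cells only.
    """

    cells: pd.DataFrame
    depth_um: float

    def __post_init__(self) -> None:
        if len(self.cells):
            bad = self.cells["is_pdl1_positive"] & ~self.cells["is_tumor"]
            if bad.any():
                raise ValueError("PD-L1 positivity is defined only for tumor cells")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def tps_by_depth(self, bin_um: float = 5.0) -> dict[int, float | None]:
        """Exact TPS (percent) per half-open depth bin, from the truth labels.

        Bins are ``[k*bin_um, (k+1)*bin_um)`` covering ``[0, depth_um]``;
        a cell exactly at ``depth_um`` goes to the last bin.  Bins with no
        tumor cells map to ``None``.
        """
        n_bins = max(1, math.ceil(self.depth_um / bin_um - 1e-9))
        out: dict[int, float | None] = {}
        z = self.cells["z_um"].to_numpy() if len(self.cells) else np.empty(0)
        idx = np.minimum((z / bin_um).astype(int), n_bins - 1) if len(z) else np.empty(0, int)
        for k in range(n_bins):
            sel = self.cells.iloc[np.flatnonzero(idx == k)] if len(z) else self.cells
            tum = sel["is_tumor"].sum() if len(sel) else 0
            if tum == 0:
                out[k] = None
            else:
                out[k] = 100.0 * float(sel["is_pdl1_positive"].sum()) / float(tum)
        return out

    @property
    def per_depth_bin_tps(self) -> dict[int, float | None]:
        return self.tps_by_depth(5.0)

    def subset(
        self,
        z_um: tuple[float, float] | None = None,
        y_um: tuple[float, float] | None = None,
        x_um: tuple[float, float] | None = None,
    ) -> "GroundTruth":
        """Cells whose centroids fall in the given half-open physical box."""
        keep = np.ones(len(self.cells), dtype=bool)
        for col, rng in (("z_um", z_um), ("y_um", y_um), ("x_um", x_um)):
            if rng is not None:
                v = self.cells[col].to_numpy()
                keep &= (v >= rng[0]) & (v < rng[1])
        return GroundTruth(self.cells.loc[keep].reset_index(drop=True), self.depth_um)


# ---------------------------------------------------------------------------
# cell placement and labeling
# ---------------------------------------------------------------------------

def sample_cells(config: PhantomConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw cell centres, radii and labels without rendering the volume.

    Placement is dart-throwing with a uniform-grid neighbour search; the
    minimum centre distance guarantees non-overlapping cells.  A margin of
    ``radius + membrane + 1`` keeps every cell (including its membrane shell)
    fully inside the field, so border handling never enters truth-based
    comparisons.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    nz, ny, nx = config.shape_zyx
    vz, vy, vx = config.voxel_size_um
    extent = np.array([(nz - 1) * vz, (ny - 1) * vy, (nx - 1) * vx])
    spacing = config.spacing_um
    mean_r, sd_r = config.nucleus_radius_um

    # grid hash for neighbour queries
    cell_size = spacing
    grid: dict[tuple[int, int, int], list[int]] = {}
    centers: list[np.ndarray] = []
    radii: list[float] = []

    region = config.tumor_region_um
    tumor_flags: list[bool] = []
    max_tries = 200 * max(config.n_cells, 1)
    tries = 0
    while len(centers) < config.n_cells:
        if tries >= max_tries:
            raise PackingError(
                f"placed only {len(centers)} of {config.n_cells} cells after "
                f"{max_tries} attempts at spacing {spacing:.1f} um; reduce n_cells, "
                "the minimum centre distance, or enlarge the field"
            )
        tries += 1
        r = float(np.clip(rng.normal(mean_r, sd_r), mean_r - 2 * sd_r, mean_r + 2 * sd_r)) \
            if sd_r > 0 else mean_r
        flag = bool(rng.random() < config.tumor_fraction)
        margin = r + config.membrane_thickness_um + 1.0
        lo = np.array([margin] * 3)
        hi = extent - margin
        if np.any(hi <= lo):
            raise PackingError("field too small for even a single cell at this radius")
        pos = rng.uniform(lo, hi)
        if region is not None:
            y0, y1, x0, x1 = region
            inside = (y0 <= pos[1] < y1) and (x0 <= pos[2] < x1)
            if inside != flag:  # tumor cells belong inside the region
                continue
        key = tuple((pos // cell_size).astype(int))
        ok = True
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for j in grid.get((key[0] + dz, key[1] + dy, key[2] + dx), ()):
                        if np.sum((centers[j] - pos) ** 2) < spacing**2:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if not ok:
                break
        if not ok:
            continue
        grid.setdefault(key, []).append(len(centers))
        centers.append(pos)
        radii.append(r)
        tumor_flags.append(flag)

    n = len(centers)
    pos_arr = np.array(centers).reshape(n, 3)
    is_tumor = np.array(tumor_flags, dtype=bool)
    p = np.array([config.positivity_profile(z, config.depth_um) for z in pos_arr[:, 0]])
    is_pos = is_tumor & (rng.random(n) < p)

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "z_um": pos_arr[:, 0] if n else np.empty(0),
            "y_um": pos_arr[:, 1] if n else np.empty(0),
            "x_um": pos_arr[:, 2] if n else np.empty(0),
            "radius_um": np.array(radii),
            "is_tumor": is_tumor,
            "is_pdl1_positive": is_pos,
        }
    )
    return GroundTruth(cells, depth_um=nz * vz)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _render_clean(config: PhantomConfig, truth: GroundTruth) -> np.ndarray:
    """Noise-free signal, shape (3, z, y, x), float32."""
    nz, ny, nx = config.shape_zyx
    vz, vy, vx = config.voxel_size_um
    amp = config.signal_amplitudes()
    lipid_amp = 0.6 * amp[2]  # cytoplasm dimmer than the nuclear/membrane peaks
    vol = np.zeros((3, nz, ny, nx), dtype=np.float32)
    t = config.membrane_thickness_um
    for row in truth.cells.itertuples(index=False):
        r_out = row.radius_um + t
        zc, yc, xc = row.z_um, row.y_um, row.x_um
        z0, z1 = max(0, math.floor((zc - r_out) / vz)), min(nz - 1, math.ceil((zc + r_out) / vz))
        y0, y1 = max(0, math.floor((yc - r_out) / vy)), min(ny - 1, math.ceil((yc + r_out) / vy))
        x0, x1 = max(0, math.floor((xc - r_out) / vx)), min(nx - 1, math.ceil((xc + r_out) / vx))
        zz, yy, xx = np.ogrid[z0 : z1 + 1, y0 : y1 + 1, x0 : x1 + 1]
        d2 = ((zz * vz - zc) ** 2 + (yy * vy - yc) ** 2 + (xx * vx - xc) ** 2).astype(np.float32)
        r2 = row.radius_um**2
        nucleus = d2 <= r2
        cyto = d2 <= r_out**2
        box = (slice(z0, z1 + 1), slice(y0, y1 + 1), slice(x0, x1 + 1))
        vol[(0,) + box][nucleus] = amp[0]
        vol[(2,) + box][cyto] = np.maximum(vol[(2,) + box][cyto], lipid_amp)
        if row.is_pdl1_positive:
            shell = cyto & ~nucleus
            vol[(1,) + box][shell] = amp[1]
    return vol


def _add_noise(clean: np.ndarray, config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    if config.snr is None:
        return clean
    out = np.empty_like(clean)
    for c in range(clean.shape[0]):
        lam = clean[c] + np.float32(config.background)
        noisy = rng.poisson(lam).astype(np.float32)
        if config.read_noise > 0:
            noisy += rng.normal(0.0, config.read_noise, size=noisy.shape).astype(np.float32)
        out[c] = np.maximum(noisy, 0.0)
    return out


def generate_phantom(
    config: PhantomConfig, truth: GroundTruth | None = None
) -> tuple[VolumeImage, GroundTruth]:
    """Generate one synthetic acquisition and its exact ground truth.

    Deterministic: the same configuration (including ``seed``) yields
    bit-identical voxel data and an identical truth table.  Passing an
    explicit ``truth`` renders that cell table instead of sampling one
    (useful for hand-crafted scenarios); noise is still drawn from the
    configured seed.
    """
    rng = np.random.default_rng(config.seed)
    if truth is None:
        truth = sample_cells(config, rng)
    clean = _render_clean(config, truth)
    data = _add_noise(clean, config, rng)
    volume = VolumeImage(
        data=data,
        voxel_size_um=config.voxel_size_um,
        channel_roles={role: i for i, role in enumerate(CHANNEL_ROLES)},
    )
    return volume, truth


def geometric_plane_counts(
    truth: GroundTruth,
    config: PhantomConfig,
    min_area_px: float | None = None,
    expected_radius_um: float | None = None,
) -> list[int]:
    """Expected detectable-nucleus count per plane, from geometry alone.

    A cell is counted in plane ``iz`` when its rasterized nuclear
    cross-section (voxel centres within the truth sphere) contains at least
    ``min_area_px`` voxels — the same area cutoff the segmentation's small-
    object filter applies.  No image processing is involved.
    """
    nz, ny, nx = config.shape_zyx
    vz, vy, vx = config.voxel_size_um
    if min_area_px is None:
        r_exp = expected_radius_um or config.nucleus_radius_um[0]
        min_area_px = 0.25 * math.pi * r_exp**2 / (vy * vx)
    counts = [0] * nz
    for row in truth.cells.itertuples(index=False):
        r = row.radius_um
        z_lo = max(0, math.ceil((row.z_um - r) / vz))
        z_hi = min(nz - 1, math.floor((row.z_um + r) / vz))
        for iz in range(z_lo, z_hi + 1):
            rho2 = r**2 - (iz * vz - row.z_um) ** 2
            if rho2 <= 0:
                continue
            rho = math.sqrt(rho2)
            y_lo = max(0, math.ceil((row.y_um - rho) / vy))
            y_hi = min(ny - 1, math.floor((row.y_um + rho) / vy))
            area = 0
            for iy in range(y_lo, y_hi + 1):
                w2 = rho2 - (iy * vy - row.y_um) ** 2
                if w2 < 0:
                    continue
                w = math.sqrt(w2)
                x_lo = max(0, math.ceil((row.x_um - w) / vx))
                x_hi = min(nx - 1, math.floor((row.x_um + w) / vx))
                area += max(0, x_hi - x_lo + 1)
            if area >= min_area_px:
                counts[iz] += 1
    return counts
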