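"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately written as plain loops over definitions,
sharing no code with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def recount_tps(cells) -> float | None:
    """TPS by explicit row-by-row counting."""
    n_tumor = 0
    n_pos = 0
    for _, row in cells.iterrows():
        if bool(row["is_tumor"]):
            n_tumor += 1
            if bool(row["is_pdl1_positive"]):
                n_pos += 1
    if n_tumor == 0:
        return None
    return 100.0 * n_pos / n_tumor


def brute_weighted_kappa(counts: np.ndarray, weights: str = "linear") -> float:
    """Direct summation of the weighted-kappa formula."""
    counts = np.asarray(counts, dtype=float)
    k = counts.shape[0]
    n = counts.sum()
    num = 0.0
    den = 0.0
    for i in range(k):
        for j in range(k):
            d = abs(i - j) / (k - 1)
            w = d if weights == "linear" else d * d
            o_ij = counts[i, j] / n
            e_ij = (counts[i, :].sum() / n) * (counts[:, j].sum() / n)
            num += w * o_ij
            den += w * e_ij
    return 1.0 - num / den


def geometric_plane_counts_bruteforce(truth, config) -> list[int]:
    """Detectable nuclei per plane, by rasterizing each truth sphere.

    A nucleus counts in a plane when the number of voxel centres inside its
    cross-section disc is at least 25 % of the expected nucleus area (the
    segmentation's small-object cutoff), checked voxel by voxel.
    """
    nz, ny, nx = config.shape_zyx
    vz, vy, vx = config.voxel_size_um
    r_exp = config.nucleus_radius_um[0]
    min_area = 0.25 * math.pi * r_exp**2 / (vy * vx)
    counts = [0] * nz
    for row in truth.cells.itertuples(index=False):
        for iz in range(nz):
            rho2 = row.radius_um**2 - (iz * vz - row.z_um) ** 2
            if rho2 <= 0:
                continue
            area = 0
            for iy in range(int((row.y_um - row.radius_um) // vy), int((row.y_um + row.radius_um) // vy) + 2):
                if not 0 <= iy < ny:
                    continue
                w2 = rho2 - (iy * vy - row.y_um) ** 2
                if w2 < 0:
                    continue
                for ix in range(int((row.x_um - row.radius_um) // vx), int((row.x_um + row.radius_um) // vx) + 2):
                    if not 0 <= ix < nx:
                        continue
                    if (ix * vx - row.x_um) ** 2 <= w2:
                        area += 1
            if area >= min_area:
                counts[iz] += 1
    return counts


def truth_bin_counts(truth, bin_um: float = 5.0) -> dict[int, tuple[int, int]]:
    """(n_tumor, n_positive) per depth bin, by explicit counting."""
    n_bins = max(1, math.ceil(truth.depth_um / bin_um - 1e-9))
    out = {k: [0, 0] for k in range(n_bins)}
    for row in truth.cells.itertuples(index=False):
        k = min(int(row.z_um / bin_um), n_bins - 1)
        if row.is_tumor:
            out[k][0] += 1
            if row.is_pdl1_positive:
                out[k][1] += 1
    return {k: (v[0], v[1]) for k, v in out.items()}
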