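"""Tumor proportion score: per-plane score, depth profile, categories and
heterogeneity summaries.

TPS is the percentage of tumor cells with any membranous PD-L1 staining among
all tumor cells.  The clinical categories partition [0, 100] as
``< 1 %``, ``1–49 %`` (read as [1, 50)) and ``>= 50 %``.

The depth profile bins cell detections into half-open 5 μm depth windows
anchored at the first acquired plane; a detection exactly at the full depth
goes to the last bin.  Bins with no tumor cells are undefined and are excluded
from the maximum/minimum/average (zero-filling them would bias the max–min
spread).  The profile's headline "3-D average" is the mean of the defined
per-bin scores (matching per-depth plotting); the cell-pooled alternative is
reported alongside.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


class TPSCategory(enum.Enum):
    LT1 = "< 1%"
    MID = "1-49%"
    GE50 = ">= 50%"


def categorize(tps_percent: float) -> TPSCategory:
    """Clinical category of a TPS percentage: [0,1) / [1,50) / [50,100]."""
    t = float(tps_percent)
    if not 0.0 <= t <= 100.0:
        raise ValueError(f"TPS must lie in [0, 100], got {t}")
    if t < 1.0:
        return TPSCategory.LT1
    if t < 50.0:
        return TPSCategory.MID
    return TPSCategory.GE50


def compute_tps(cells: pd.DataFrame) -> float | None:
    """TPS of a tumor-cell table: 100 x positives / tumor cells.

    ``cells`` must contain only tumor cells (columns ``is_tumor`` and
    ``is_pdl1_positive``); passing a non-tumor cell is a contract violation.
    Returns ``None`` when the table is empty (undefined score).
    """
    if len(cells) == 0:
        return None
    if not cells["is_tumor"].astype(bool).all():
        raise ValueError("compute_tps expects tumor cells only")
    n_pos = int(cells["is_pdl1_positive"].astype(bool).sum())
    return 100.0 * n_pos / len(cells)


@dataclass
class BinStat:
    depth_start_um: float
    depth_end_um: float
    n_tumor: int
    n_positive: int

    @property
    def tps(self) -> float | None:
        if self.n_tumor == 0:
            return None
        return 100.0 * self.n_positive / self.n_tumor

    @property
    def category(self) -> TPSCategory | None:
        t = self.tps
        return None if t is None else categorize(t)


@dataclass
class TPSProfile:
    """Depth-binned TPS plus 3-D summaries."""

    bins: list[BinStat]
    bin_um: float

    # -- defined bins ------------------------------------------------------
    @property
    def defined_bins(self) -> list[BinStat]:
        return [b for b in self.bins if b.n_tumor > 0]

    @property
    def defined_tps(self) -> list[float]:
        return [b.tps for b in self.defined_bins]  # type: ignore[misc]

    # -- summaries ---------------------------------------------------------
    @property
    def average_tps(self) -> float | None:
        """Mean of the defined per-bin scores (primary 3-D average)."""
        vals = self.defined_tps
        return float(np.mean(vals)) if vals else None

    @property
    def pooled_tps(self) -> float | None:
        """Cell-pooled alternative: all positives over all tumor cells."""
        n_tum = sum(b.n_tumor for b in self.bins)
        if n_tum == 0:
            return None
        return 100.0 * sum(b.n_positive for b in self.bins) / n_tum

    @property
    def max_tps(self) -> float | None:
        vals = self.defined_tps
        return max(vals) if vals else None

    @property
    def min_tps(self) -> float | None:
        vals = self.defined_tps
        return min(vals) if vals else None

    @property
    def max_minus_min(self) -> float | None:
        vals = self.defined_tps
        return max(vals) - min(vals) if vals else None

    @property
    def category_per_bin(self) -> list[TPSCategory | None]:
        return [b.category for b in self.bins]

    @property
    def category_of_average(self) -> TPSCategory | None:
        avg = self.average_tps
        return None if avg is None else categorize(avg)

    @property
    def crosses_category(self) -> bool:
        cats = {b.category for b in self.defined_bins}
        return len(cats) >= 2

    @property
    def boundaries_crossed(self) -> set[str]:
        """Which clinical cut-offs the depth profile straddles."""
        out: set[str] = set()
        vals = self.defined_tps
        if not vals:
            return out
        lo, hi = min(vals), max(vals)
        if lo < 1.0 <= hi:
            out.add("1%")
        if lo < 50.0 <= hi:
            out.add("50%")
        return out

    # -- export ------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth_start_um": [b.depth_start_um for b in self.bins],
                "depth_end_um": [b.depth_end_um for b in self.bins],
                "n_tumor_cells": [b.n_tumor for b in self.bins],
                "n_positive_cells": [b.n_positive for b in self.bins],
                "tps_percent": [b.tps for b in self.bins],
                "category": [b.category.value if b.category else None for b in self.bins],
            }
        )

    def to_dict(self) -> dict:
        return {
            "bin_um": self.bin_um,
            "bins": self.to_frame().to_dict(orient="records"),
            "average_tps_percent": self.average_tps,
            "pooled_tps_percent": self.pooled_tps,
            "max_tps": self.max_tps,
            "min_tps": self.min_tps,
            "max_minus_min": self.max_minus_min,
            "category_of_average": (
                self.category_of_average.value if self.category_of_average else None
            ),
            "crosses_category": self.crosses_category,
            "boundaries_crossed": sorted(self.boundaries_crossed),
        }


def depth_profile(
    cells: pd.DataFrame, depth_um: float, bin_um: float = 5.0
) -> TPSProfile:
    """Bin cell detections by nucleus-centroid depth and score each bin.

    ``cells`` needs columns ``z_um``, ``is_tumor``, ``is_pdl1_positive`` and
    optionally ``excluded`` (excluded rows are dropped from numerator and
    denominator alike).  Non-tumor detections are carried but never counted.
    """
    if bin_um <= 0:
        raise ValueError("bin_um must be positive")
    if depth_um <= 0:
        raise ValueError("depth_um must be positive")
    work = cells
    if "excluded" in cells.columns:
        work = cells.loc[~cells["excluded"].astype(bool)]
    n_bins = max(1, math.ceil(depth_um / bin_um - 1e-9))
    z = work["z_um"].to_numpy(dtype=float) if len(work) else np.empty(0)
    if len(z) and (z.min() < 0 or z.max() > depth_um):
        raise ValueError("cell depth outside [0, depth_um]")
    idx = np.minimum((z / bin_um).astype(int), n_bins - 1)
    tumor = work["is_tumor"].to_numpy(dtype=bool) if len(work) else np.empty(0, bool)
    pos = (
        work["is_pdl1_positive"].fillna(False).to_numpy(dtype=bool)
        if len(work)
        else np.empty(0, bool)
    )
    n_tum = np.bincount(idx[tumor], minlength=n_bins) if len(z) else np.zeros(n_bins, int)
    n_pos = np.bincount(idx[tumor & pos], minlength=n_bins) if len(z) else np.zeros(n_bins, int)
    bins = [
        BinStat(k * bin_um, min((k + 1) * bin_um, depth_um), int(n_tum[k]), int(n_pos[k]))
        for k in range(n_bins)
    ]
    return TPSProfile(bins=bins, bin_um=bin_um)


def heterogeneity_summary(profiles: list[TPSProfile]) -> dict:
    """Cohort-level depth-heterogeneity summary across cases.

    Reports the mean of the per-case max–min TPS spread, how many cases
    spread by more than 10 percentage points, how many cross a clinical
    category boundary with depth, and which boundary (1 % vs 50 %) is
    crossed.  Cases with no defined bins are skipped and counted.
    """
    if not profiles:
        raise ValueError("heterogeneity_summary requires at least one profile")
    defined = [p for p in profiles if p.defined_bins]
    spreads = np.array([p.max_minus_min for p in defined], dtype=float)
    crossing = [p for p in defined if p.crosses_category]
    n = len(defined)
    return {
        "n_cases": len(profiles),
        "n_cases_defined": n,
        "mean_max_minus_min": float(spreads.mean()) if n else None,
        "n_spread_gt_10": int((spreads > 10.0).sum()) if n else 0,
        "frac_spread_gt_10": float((spreads > 10.0).mean()) if n else None,
        "n_crossing_category": len(crossing),
        "frac_crossing_category": len(crossing) / n if n else None,
        "n_crossing_1pct": sum("1%" in p.boundaries_crossed for p in defined),
        "n_crossing_50pct": sum("50%" in p.boundaries_crossed for p in defined),
    }


def plot_depth_profile(profile: TPSProfile, ax=None, **plot_kwargs):
    """Depth-versus-TPS curve (the per-case heterogeneity plot)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    depths = [0.5 * (b.depth_start_um + b.depth_end_um) for b in profile.defined_bins]
    vals = [b.tps for b in profile.defined_bins]
    ax.plot(depths, vals, marker="o", **plot_kwargs)
    for cut in (1.0, 50.0):
        ax.axhline(cut, color="grey", lw=0.6, ls="--")
    ax.set_xlabel("tissue depth (um)")
    ax.set_ylabel("TPS (%)")
    ax.set_ylim(bottom=0)
    return ax
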