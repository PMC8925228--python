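"""Membranous PD-L1 positivity per tumor cell, and the consensus protocol.

Membranous staining appears, in a 2-D plane, as a bright ring around the
nucleus.  For each segmented nucleus the module measures the marker channel
over an annulus (a dilation of the nucleus region minus the nucleus itself)
and summarizes it with four features:

* ``annulus_mean`` — mean marker intensity over the annulus;
* ``annulus_p90`` — 90th percentile over the annulus;
* ``annulus_to_nucleus_ratio`` — annulus mean over nucleus-interior mean,
  the explicit membranous-versus-cytoplasmic discriminator;
* ``ring_coverage_fraction`` — fraction of annulus voxels above a per-plane
  background reference (the Li threshold of the marker plane, which keeps the
  module self-calibrating).

The default classification rule encodes "any membranous staining": positive
iff ``ring_coverage_fraction >= coverage_min`` and
``annulus_to_nucleus_ratio >= ratio_min`` (both comparisons inclusive).  Any
plug-in honoring the same signature may replace it.

The consensus annotation protocol labels a cell positive only when all four
annotations (two readers, two rounds each) are positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_li
from skimage.segmentation import expand_labels

from .nuclei import NucleusLabelMap

FEATURE_NAMES = (
    "annulus_mean",
    "annulus_p90",
    "annulus_to_nucleus_ratio",
    "ring_coverage_fraction",
)

_EPS = 1e-9


@dataclass
class ClassifierRule:
    """Threshold rule for membranous positivity; thresholds are inclusive."""

    coverage_min: float = 0.3
    ratio_min: float = 1.2

    def metadata(self) -> dict:
        return {"name": "threshold-rule", "coverage_min": self.coverage_min,
                "ratio_min": self.ratio_min}


def extract_membrane_features(
    nuclei: NucleusLabelMap,
    pdl1_plane: np.ndarray,
    voxel_size_yx: tuple[float, float] = (1.0, 1.0),
    annulus_width_um: float = 1.5,
) -> pd.DataFrame:
    """Membrane features for every nucleus of one plane.

    Returns a frame with one row per nucleus (ordered by label) holding the
    four features plus ``annulus_px`` and a ``feature_ok`` flag; a nucleus
    whose annulus is empty (entirely squeezed off the image) gets
    ``feature_ok = False`` and NaN features, to be excluded from scoring.
    """
    if annulus_width_um <= 0:
        raise ValueError("annulus_width_um must be positive")
    plane = np.asarray(pdl1_plane, dtype=np.float32)
    if plane.shape != nuclei.labels.shape:
        raise ValueError("marker plane shape differs from the nucleus label map")
    n = nuclei.n_nuclei
    if n == 0:
        return _empty_features()

    vy, vx = voxel_size_yx
    dist_px = annulus_width_um / min(vy, vx)
    expanded = expand_labels(nuclei.labels, distance=dist_px)
    annulus = np.where(nuclei.labels == 0, expanded, 0)

    # per-plane background reference for ring coverage
    background_ref = float(threshold_li(plane)) if plane.max() > plane.min() else float(plane.max())

    idx = np.arange(1, n + 1)
    ann_counts = np.bincount(annulus.ravel(), minlength=n + 1)[1:]
    ann_sums = np.bincount(annulus.ravel(), weights=plane.ravel(), minlength=n + 1)[1:]
    above = (plane > background_ref).astype(np.float64)
    ann_above = np.bincount(annulus.ravel(), weights=above.ravel(), minlength=n + 1)[1:]
    nuc_counts = np.bincount(nuclei.labels.ravel(), minlength=n + 1)[1:]
    nuc_sums = np.bincount(nuclei.labels.ravel(), weights=plane.ravel(), minlength=n + 1)[1:]

    ok = ann_counts > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        ann_mean = np.where(ok, ann_sums / np.maximum(ann_counts, 1), np.nan)
        coverage = np.where(ok, ann_above / np.maximum(ann_counts, 1), np.nan)
        nuc_mean = nuc_sums / np.maximum(nuc_counts, 1)
        ratio = np.where(ok, ann_mean / (nuc_mean + _EPS), np.nan)

    p90 = np.full(n, np.nan)
    if ok.any():
        vals = ndi.labeled_comprehension(
            plane, annulus, idx[ok], lambda v: np.percentile(v, 90), float, np.nan
        )
        p90[ok] = vals

    return pd.DataFrame(
        {
            "label": idx,
            "annulus_mean": ann_mean,
            "annulus_p90": p90,
            "annulus_to_nucleus_ratio": ratio,
            "ring_coverage_fraction": coverage,
            "annulus_px": ann_counts,
            "feature_ok": ok,
        }
    )


def _empty_features() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": pd.Series(dtype=int),
            "annulus_mean": pd.Series(dtype=float),
            "annulus_p90": pd.Series(dtype=float),
            "annulus_to_nucleus_ratio": pd.Series(dtype=float),
            "ring_coverage_fraction": pd.Series(dtype=float),
            "annulus_px": pd.Series(dtype=int),
            "feature_ok": pd.Series(dtype=bool),
        }
    )


def classify_pdl1(features: pd.Series | dict, rule: ClassifierRule | None = None) -> bool:
    """Apply the threshold rule to one cell's membrane features."""
    rule = rule or ClassifierRule()
    cov = float(features["ring_coverage_fraction"])
    ratio = float(features["annulus_to_nucleus_ratio"])
    if not (np.isfinite(cov) and np.isfinite(ratio)):
        raise ValueError("cannot classify a cell with unset/NaN membrane features")
    return cov >= rule.coverage_min and ratio >= rule.ratio_min


def classify_pdl1_frame(features: pd.DataFrame, rule: ClassifierRule | None = None) -> np.ndarray:
    """Vectorized threshold rule over a feature frame (NaN rows -> error)."""
    rule = rule or ClassifierRule()
    cov = features["ring_coverage_fraction"].to_numpy(dtype=float)
    ratio = features["annulus_to_nucleus_ratio"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(cov)) and np.all(np.isfinite(ratio))):
        raise ValueError("cannot classify cells with unset/NaN membrane features")
    return (cov >= rule.coverage_min) & (ratio >= rule.ratio_min)


# ---------------------------------------------------------------------------
# consensus annotation protocol
# ---------------------------------------------------------------------------

def consensus_label(votes) -> bool:
    """Positive iff all four annotations (2 readers x 2 rounds) are positive."""
    votes = list(votes)
    if len(votes) != 4:
        raise ValueError(f"consensus requires exactly 4 votes, got {len(votes)}")
    return all(bool(v) for v in votes)


VOTE_COLUMNS = ("vote_a1", "vote_a2", "vote_b1", "vote_b2")


def consensus_labels(annotations: pd.DataFrame) -> pd.Series:
    """Consensus per cell for an annotation table with the four vote columns."""
    missing = [c for c in VOTE_COLUMNS if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotation table is missing vote columns: {missing}")
    votes = annotations[list(VOTE_COLUMNS)]
    if votes.isna().any().any():
        raise ValueError("annotation table contains missing votes")
    return votes.astype(bool).all(axis=1)
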