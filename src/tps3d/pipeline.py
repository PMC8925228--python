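"""End-to-end scoring pipeline and its configuration.

``run_pipeline`` chains the stages: per-plane nuclear segmentation → tumor
mask → per-nucleus tumor status → membrane feature extraction → membranous
positivity call → depth-resolved TPS profile, optionally after a
pseudo-needle crop.  The run is deterministic given the configuration, and
the result carries a QC account in which, for every plane,
``detected = scored + excluded`` with exclusion reasons enumerated.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .image import VolumeImage
from .nuclei import SegmentationParams, segment_nuclei_volume
from .pdl1 import ClassifierRule, classify_pdl1_frame, extract_membrane_features
from .tps import TPSProfile, depth_profile
from .tumor_mask import BaselineMasker, ConstantMasker, MaskerInterface, TumorMask, assign_tumor_status
from . import needle as needle_mod

CELL_COLUMNS = [
    "cell_id", "plane", "label", "z_um", "y_um", "x_um", "area_px", "is_tumor",
    "annulus_mean", "annulus_p90", "annulus_to_nucleus_ratio", "ring_coverage_fraction",
    "is_pdl1_positive", "excluded", "exclude_reason",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and plane index."""

    def __init__(self, stage: str, plane: int | None, original: Exception):
        self.stage, self.plane, self.original = stage, plane, original
        where = f" (plane {plane})" if plane is not None else ""
        super().__init__(f"stage {stage!r}{where}: {original}")


class PipelineConfig(BaseModel):
    """All tunable parameters of one scoring run (units are micrometres)."""

    channel_roles: dict[str, int] = Field(
        default_factory=lambda: {"nucleus": 0, "pdl1": 1, "lipid": 2}
    )
    voxel_size_um: tuple[float, float, float] | None = None  # metadata override

    # nuclear segmentation
    expected_radius_um: float = 4.0
    min_size_fraction: float = 0.25
    smooth_sigma_um: float = 0.0

    # tumor mask
    masker: Literal["baseline", "constant"] = "baseline"
    masker_params: dict = Field(default_factory=dict)

    # membranous classification
    annulus_width_um: float = 1.5
    coverage_min: float = 0.3
    ratio_min: float = 1.2

    # profiling
    bin_um: float = 5.0

    # pseudo-needle
    apply_needle: bool = False
    needle_length_um: float = 8000.0
    needle_width_um: float = 1000.0
    needle_axis: Literal["x", "y"] = "x"
    com_channel: str = "nucleus"

    kappa_weights: Literal["linear", "quadratic"] = "linear"
    seed: int = 0

    # -- helpers -------------------------------------------------------------
    def segmentation_params(self) -> SegmentationParams:
        return SegmentationParams(
            expected_radius_um=self.expected_radius_um,
            min_size_fraction=self.min_size_fraction,
            smooth_sigma_um=self.smooth_sigma_um,
        )

    def classifier_rule(self) -> ClassifierRule:
        return ClassifierRule(coverage_min=self.coverage_min, ratio_min=self.ratio_min)

    def build_masker(self) -> MaskerInterface:
        if self.masker == "baseline":
            return BaselineMasker(**self.masker_params)
        return ConstantMasker(**self.masker_params)

    # -- (de)serialization ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump({"pipeline": self.model_dump()}, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        section = doc.get("pipeline", doc) if isinstance(doc, dict) else doc
        return cls.model_validate(section)


@dataclass
class PipelineResult:
    """Everything one run produces."""

    cells: pd.DataFrame
    profile: TPSProfile
    qc: dict
    params: dict
    masks: list[TumorMask] = field(default_factory=list)
    track: dict | None = None

    def write_cells_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.cells.to_csv(path, index=False, columns=CELL_COLUMNS)
        return path


def run_pipeline(volume: VolumeImage, config: PipelineConfig | None = None,
                 keep_masks: bool = False) -> PipelineResult:
    """Score one volume end to end."""
    config = config or PipelineConfig()
    if config.voxel_size_um is not None:
        volume = VolumeImage(volume.data, config.voxel_size_um, dict(volume.channel_roles))
    if config.channel_roles:
        volume = VolumeImage(volume.data, volume.voxel_size_um, dict(config.channel_roles))

    track_info = None
    if config.apply_needle:
        try:
            track = needle_mod.plan_track(
                volume,
                length_um=config.needle_length_um,
                width_um=config.needle_width_um,
                axis=config.needle_axis,
                channel_role=config.com_channel,
            )
            volume, offset = needle_mod.crop_pseudo_needle(volume, track)
            track_info = track.to_dict(volume.voxel_size_um)
            track_info["offset_um"] = list(offset)
        except Exception as exc:  # noqa: BLE001 - annotate with stage
            raise StageError("needle", None, exc) from exc

    vz, vy, vx = volume.voxel_size_um
    seg_params = config.segmentation_params()
    rule = config.classifier_rule()
    masker = config.build_masker()

    try:
        labelmaps = segment_nuclei_volume(volume, seg_params)
    except Exception as exc:  # noqa: BLE001
        raise StageError("segment_nuclei", None, exc) from exc

    frames: list[pd.DataFrame] = []
    masks: list[TumorMask] = []
    qc_planes: list[dict] = []
    for lm in labelmaps:
        z = lm.plane_index
        try:
            mask = masker.predict(volume.multichannel_plane(z), (vy, vx), plane_index=z)
            tumor = assign_tumor_status(lm, mask, (vy, vx))
            feats = extract_membrane_features(
                lm, volume.plane("pdl1", z), (vy, vx), config.annulus_width_um
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("per_plane_scoring", z, exc) from exc
        if keep_masks:
            masks.append(mask)

        n = lm.n_nuclei
        excluded = ~feats["feature_ok"].to_numpy(bool) if n else np.zeros(0, bool)
        calls = pd.array([pd.NA] * n, dtype="boolean")
        scorable = tumor & ~excluded
        if scorable.any():
            calls[scorable] = classify_pdl1_frame(feats.loc[scorable], rule)
        frame = pd.DataFrame(
            {
                "cell_id": [f"z{z:04d}-n{lab:05d}" for lab in feats["label"]] if n else [],
                "plane": np.full(n, z, dtype=int),
                "label": feats["label"].to_numpy(int) if n else np.empty(0, int),
                "z_um": np.full(n, z * vz),
                "y_um": lm.centroids_um[:, 0] if n else np.empty(0),
                "x_um": lm.centroids_um[:, 1] if n else np.empty(0),
                "area_px": lm.areas_px,
                "is_tumor": tumor,
                "annulus_mean": feats["annulus_mean"].to_numpy(float) if n else np.empty(0),
                "annulus_p90": feats["annulus_p90"].to_numpy(float) if n else np.empty(0),
                "annulus_to_nucleus_ratio": (
                    feats["annulus_to_nucleus_ratio"].to_numpy(float) if n else np.empty(0)
                ),
                "ring_coverage_fraction": (
                    feats["ring_coverage_fraction"].to_numpy(float) if n else np.empty(0)
                ),
                "is_pdl1_positive": calls,
                "excluded": excluded,
                "exclude_reason": np.where(excluded, "unreliable_membrane_features", ""),
            }
        )
        frames.append(frame)
        qc_planes.append(
            {
                "plane": z,
                "detected": int(n),
                "scored": int((~excluded).sum()),
                "excluded": int(excluded.sum()),
                "tumor": int((tumor & ~excluded).sum()),
                "positive": int(pd.Series(calls)[scorable].fillna(False).sum()),
            }
        )

    cells = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=CELL_COLUMNS)
    )
    try:
        profile = depth_profile(cells, depth_um=volume.depth_um, bin_um=config.bin_um)
    except Exception as exc:  # noqa: BLE001
        raise StageError("depth_profile", None, exc) from exc

    qc = {
        "planes": qc_planes,
        "total_detected": int(sum(p["detected"] for p in qc_planes)),
        "total_excluded": int(sum(p["excluded"] for p in qc_planes)),
        "exclusion_reasons": (
            cells.loc[cells["excluded"], "exclude_reason"].value_counts().to_dict()
            if len(cells)
            else {}
        ),
    }
    params = {
        "config": config.model_dump(),
        "masker": masker.metadata(),
        "classifier": rule.metadata(),
        "volume_shape_czyx": list(volume.data.shape),
        "voxel_size_um": list(volume.voxel_size_um),
        "input_checksum": volume_checksum(volume),
    }
    return PipelineResult(cells=cells, profile=profile, qc=qc, params=params,
                          masks=masks, track=track_info)


def volume_checksum(volume: VolumeImage) -> str:
    """SHA-1 of the voxel data, for run-log provenance."""
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(volume.data).tobytes())
    return h.hexdigest()
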