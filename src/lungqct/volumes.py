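"""Domain containers for CT attenuation volumes, lung masks, and scan pairs.

Attenuation is carried in Hounsfield units (HU): air is about -1000 HU,
water 0 HU. Values are used exactly as stored; nothing here rescales or
clamps, but values outside the representable CT range [-1024, 3071] trigger
a logged warning because they usually indicate a calibration or format
problem upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import AlignmentError, EmptySegmentationError, ValidationError

logger = logging.getLogger(__name__)

HU_PLAUSIBLE_MIN = -1024.0
HU_PLAUSIBLE_MAX = 3071.0


class SmokingStatus(str, Enum):
    """Current vs former smoker; the emphysema cut-points depend on it."""

    CURRENT = "current"
    FORMER = "former"


class EmphysemaClass(str, Enum):
    ABSENT = "absent"
    INTERMEDIATE = "intermediate"
    SEVERE = "severe"


@dataclass(frozen=True)
class AttenuationVolume:
    """A 3D grid of HU values with physical voxel spacing in millimetres."""

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=np.float64)
        if grid.ndim != 3 or min(grid.shape) < 1:
            raise ValidationError(
                f"attenuation grid must be 3D with positive dimensions, got shape {grid.shape}"
            )
        if not np.all(np.isfinite(grid)):
            raise ValidationError("attenuation grid contains non-finite HU values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValidationError(f"voxel spacing must be three positive lengths, got {spacing}")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "spacing", spacing)
        lo, hi = grid.min(), grid.max()
        if lo < HU_PLAUSIBLE_MIN or hi > HU_PLAUSIBLE_MAX:
            logger.warning(
                "HU values outside [%d, %d] (range %.1f..%.1f); check calibration",
                HU_PLAUSIBLE_MIN, HU_PLAUSIBLE_MAX, lo, hi,
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class LungSegmentation:
    """Binary lung mask aligned voxel-for-voxel with an AttenuationVolume."""

    mask: np.ndarray

    def __post_init__(self):
        mask = np.asarray(self.mask)
        if mask.ndim != 3:
            raise ValidationError(f"mask must be 3D, got shape {mask.shape}")
        object.__setattr__(self, "mask", mask.astype(bool))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


def masked_values(volume: AttenuationVolume, mask: LungSegmentation) -> np.ndarray:
    """HU values of the lung voxels, validating alignment and non-emptiness."""
    if volume.shape != mask.shape:
        raise AlignmentError(
            f"alignment: mask shape {mask.shape} does not match volume shape {volume.shape}"
        )
    values = volume.grid[mask.mask]
    if values.size == 0:
        raise EmptySegmentationError("empty segmentation: no lung voxels in mask")
    return values


@dataclass(frozen=True)
class ScanPair:
    """One subject's paired inspiratory and expiratory acquisitions.

    The two phases are acquired separately, so the grids may differ in shape;
    all paired measures are histogram-level and need no registration.
    """

    insp_volume: AttenuationVolume
    insp_mask: LungSegmentation
    exp_volume: AttenuationVolume
    exp_mask: LungSegmentation
    smoking_status: SmokingStatus = SmokingStatus.FORMER
    subject_id: str = ""

    def __post_init__(self):
        if self.insp_volume.shape != self.insp_mask.shape:
            raise AlignmentError(
                f"alignment: inspiratory mask {self.insp_mask.shape} vs volume {self.insp_volume.shape}"
            )
        if self.exp_volume.shape != self.exp_mask.shape:
            raise AlignmentError(
                f"alignment: expiratory mask {self.exp_mask.shape} vs volume {self.exp_volume.shape}"
            )
        object.__setattr__(self, "smoking_status", SmokingStatus(self.smoking_status))
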