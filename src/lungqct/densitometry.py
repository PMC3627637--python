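"""Voxel-level densitometry for paired inspiratory-expiratory chest CT.

The emphysema index and the gas-trapping measures are density-mask and
histogram summaries of the segmented lung:

* ``Insp-950`` — percent of inspiratory lung voxels with HU < -950, the
  standard CT emphysema index.
* ``Exp-856`` — percent of expiratory lung voxels with HU < -856, the
  whole-lung gas-trapping index ("percent gas trapping").
* ``E/I MLA`` — expiratory-to-inspiratory ratio of mean lung attenuation;
  approaches 1 as trapped gas keeps the lung lucent on expiration.
* ``RVC 856-950`` — expiratory minus inspiratory relative lung volume, where
  the relative volume is the fraction of non-emphysematous lung
  (HU >= -950) occupying the -950..-856 HU band.

Threshold conventions: "below" is strict (HU < threshold), the band is
-950 <= HU < -856, and the non-emphysema denominator is HU >= -950, so the
emphysema set, the band, and the denser remainder partition the lung.

CT lung volumes follow from voxel counting: the inspiratory scan (full
inspiration) yields TLC and the expiratory scan (end-tidal expiration)
yields FRC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from .errors import (
    DegenerateAttenuationError,
    NoNonEmphysematousLungError,
    ValidationError,
)
from .volumes import (
    AttenuationVolume,
    EmphysemaClass,
    LungSegmentation,
    ScanPair,
    SmokingStatus,
    masked_values,
)

logger = logging.getLogger(__name__)

EMPHYSEMA_THRESHOLD_HU = -950.0
GAS_TRAPPING_THRESHOLD_HU = -856.0

#: Insp-950 cut-points (%) below/above which emphysema is called absent/severe.
#: Current smokers get lower cut-points because smoking raises lung density.
ABSENT_CUTPOINT = {SmokingStatus.FORMER: 5.0, SmokingStatus.CURRENT: 4.0}
SEVERE_CUTPOINT = {SmokingStatus.FORMER: 15.0, SmokingStatus.CURRENT: 14.0}


def percent_voxels_below(
    volume: AttenuationVolume, mask: LungSegmentation, threshold: float
) -> float:
    """Percent of lung voxels with attenuation strictly below ``threshold`` HU."""
    values = masked_values(volume, mask)
    return 100.0 * np.count_nonzero(values < threshold) / values.size


def mean_lung_attenuation(volume: AttenuationVolume, mask: LungSegmentation) -> float:
    """Arithmetic mean HU over the lung voxels (the density-histogram mean)."""
    return float(np.mean(masked_values(volume, mask)))


def ei_mla(pair: ScanPair) -> float:
    """Expiratory-to-inspiratory ratio of mean lung attenuation.

    For physiological lungs both means are negative and expiration densifies
    the parenchyma, so the ratio lies in (0, 1); gas trapping pushes it
    toward 1.
    """
    insp = mean_lung_attenuation(pair.insp_volume, pair.insp_mask)
    if abs(insp) <= 1.0:
        raise DegenerateAttenuationError(
            f"degenerate attenuation: inspiratory MLA {insp:.3f} HU is within 1 HU of zero"
        )
    return mean_lung_attenuation(pair.exp_volume, pair.exp_mask) / insp


def relative_lung_volume(volume: AttenuationVolume, mask: LungSegmentation) -> float:
    """Fraction of non-emphysematous lung in the -950..-856 HU band.

    Band count is ``-950 <= HU < -856``; the denominator ("lung volume
    without emphysema") is ``HU >= -950``.
    """
    values = masked_values(volume, mask)
    non_emphysema = values >= EMPHYSEMA_THRESHOLD_HU
    denominator = int(non_emphysema.sum())
    if denominator == 0:
        raise NoNonEmphysematousLungError(
            "no non-emphysematous lung: every voxel is below -950 HU"
        )
    band = int(np.count_nonzero(non_emphysema & (values < GAS_TRAPPING_THRESHOLD_HU)))
    return band / denominator


def rvc_856_950(pair: ScanPair) -> float:
    """Relative volume change: expiratory minus inspiratory relative lung volume."""
    try:
        insp = relative_lung_volume(pair.insp_volume, pair.insp_mask)
    except Exception as exc:
        raise type(exc)(f"inspiratory scan: {exc}") from exc
    try:
        exp = relative_lung_volume(pair.exp_volume, pair.exp_mask)
    except Exception as exc:
        raise type(exc)(f"expiratory scan: {exc}") from exc
    return exp - insp


def lung_volume_liters(volume: AttenuationVolume, mask: LungSegmentation) -> float:
    """Segmented lung volume in liters: voxel count x voxel volume.

    An empty mask yields 0.0 L with a warning; downstream ratios (FRC/TLC)
    will still fail loudly on a zero TLC.
    """
    if volume.shape != mask.shape:
        # reuse the alignment check without requiring a non-empty mask
        from .errors import AlignmentError

        raise AlignmentError(
            f"alignment: mask shape {mask.shape} does not match volume shape {volume.shape}"
        )
    count = mask.voxel_count
    if count == 0:
        logger.warning("lung_volume_liters: empty mask, returning 0.0 L")
        return 0.0
    return count * volume.voxel_volume_mm3 * 1e-6


def classify_emphysema_severity(
    insp_950: float, smoking_status: SmokingStatus | str
) -> EmphysemaClass:
    """Classify emphysema from the inspiratory density-mask percent.

    Former smokers: absent below 5%, severe above 15%. Current smokers:
    absent below 4%, severe above 14%. The inequalities are strict on both
    sides, so values exactly at a cut-point are intermediate.
    """
    if not 0.0 <= insp_950 <= 100.0:
        raise ValidationError(f"insp_950 must be a percent in [0, 100], got {insp_950}")
    status = SmokingStatus(smoking_status)
    if insp_950 < ABSENT_CUTPOINT[status]:
        return EmphysemaClass.ABSENT
    if insp_950 > SEVERE_CUTPOINT[status]:
        return EmphysemaClass.SEVERE
    return EmphysemaClass.INTERMEDIATE


@dataclass(frozen=True)
class DensityMetrics:
    """All per-subject CT densitometry outputs for one scan pair."""

    insp_950: float          # percent, inspiratory emphysema index
    exp_856: float           # percent, expiratory gas-trapping index
    ei_mla: float            # dimensionless ratio
    rvc_856_950: float       # dimensionless difference in [-1, 1]
    tlc_l: float             # liters, from the inspiratory scan
    frc_l: float             # liters, from the expiratory scan
    frc_tlc: float           # hyperinflation ratio
    emphysema_class: EmphysemaClass

    def to_dict(self) -> dict:
        d = asdict(self)
        d["emphysema_class"] = self.emphysema_class.value
        return d


def compute_scan_pair_metrics(pair: ScanPair) -> DensityMetrics:
    """Compute every densitometry metric for one inspiratory/expiratory pair."""

    def _step(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise type(exc)(f"{name}: {exc}") from exc

    insp_950 = _step(
        "insp_950",
        lambda: percent_voxels_below(pair.insp_volume, pair.insp_mask, EMPHYSEMA_THRESHOLD_HU),
    )
    exp_856 = _step(
        "exp_856",
        lambda: percent_voxels_below(pair.exp_volume, pair.exp_mask, GAS_TRAPPING_THRESHOLD_HU),
    )
    ratio = _step("ei_mla", lambda: ei_mla(pair))
    rvc = _step("rvc_856_950", lambda: rvc_856_950(pair))
    tlc = _step("tlc_l", lambda: lung_volume_liters(pair.insp_volume, pair.insp_mask))
    frc = _step("frc_l", lambda: lung_volume_liters(pair.exp_volume, pair.exp_mask))
    if tlc <= 0:
        raise ValidationError("frc_tlc: TLC is zero; ratio undefined")
    return DensityMetrics(
        insp_950=insp_950,
        exp_856=exp_856,
        ei_mla=ratio,
        rvc_856_950=rvc,
        tlc_l=tlc,
        frc_l=frc,
        frc_tlc=frc / tlc,
        emphysema_class=classify_emphysema_severity(insp_950, pair.smoking_status),
    )
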