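"""Lesion metric bundle and reference-organ uptake.

MATV uses binary voxel counting (region-grown VOIs are binary);
fractional voxel weights are used only for the sphere-defined VOIs
(SUVpeak spheres, liver and blood-pool reference spheres).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import (
    FractionalMask,
    VolumetricImage,
    make_sphere_mask,
    suv_peak,
)

__all__ = [
    "LesionRecord",
    "ReferenceUptake",
    "lesion_metrics",
    "reference_uptake",
    "uptake_ratios",
    "LIVER_VOI_DIAMETER_MM",
    "BLOODPOOL_VOI_DIAMETER_MM",
]

#: 3-cm-diameter spherical liver VOI (right upper lobe placement).
LIVER_VOI_DIAMETER_MM = 30.0
#: 1.5-cm spherical VOI in the lumen of the ascending aorta.
BLOODPOOL_VOI_DIAMETER_MM = 15.0


@dataclass
class LesionRecord:
    """Metric bundle for one lesion under one VOI method and reconstruction."""

    subject_id: str
    lesion_id: int
    voi_method: str  # SUV4 | MAX41 | A50P
    reconstruction: str  # EARL1 | EARL2 | EARL2F6 | EARL2F7
    matv_ml: float
    suv_max: float
    suv_mean: float
    suv_peak: float
    tlg: float  # ml * SUV, = MATV * SUVmean
    mask: np.ndarray | None = field(default=None, repr=False, compare=False)


@dataclass
class ReferenceUptake:
    """Liver and blood-pool uptake statistics from fixed spherical VOIs."""

    liver_suv_max: float
    liver_suv_peak: float
    liver_suv_mean: float
    bloodpool_suv_max: float
    bloodpool_suv_peak: float
    bloodpool_suv_mean: float


def lesion_metrics(
    img: VolumetricImage,
    mask: np.ndarray,
    voi_method: str,
    reconstruction: str,
    subject_id: str = "",
    lesion_id: int = 0,
) -> LesionRecord:
    """Compute MATV, SUVmax/mean/peak and TLG for a binary lesion mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.values.shape:
        raise ValueError("mask must share the image grid")
    if not mask.any():
        raise ValueError("empty lesion mask")
    matv = float(mask.sum()) * img.voxel_volume_ml
    inside = img.values[mask]
    mean = float(inside.mean())
    peak = suv_peak(img, FractionalMask(mask.astype(float), img.voxel_volume_ml))
    return LesionRecord(
        subject_id=subject_id,
        lesion_id=lesion_id,
        voi_method=voi_method,
        reconstruction=reconstruction,
        matv_ml=matv,
        suv_max=float(inside.max()),
        suv_mean=mean,
        suv_peak=peak,
        tlg=matv * mean,
        mask=mask,
    )


def _sphere_stats(img: VolumetricImage, center, diameter: float):
    lo, hi = img.world_bounds()
    c = np.asarray(center, dtype=float)
    r = diameter / 2.0
    if np.any(c - r < lo) or np.any(c + r > hi):
        raise ValueError(
            f"reference sphere at {c.tolist()} (diameter {diameter} mm) is "
            "partially outside the grid"
        )
    mask = make_sphere_mask(img, center, diameter)
    support = mask.weights > 0
    vmax = float(img.values[support].max())
    vmean = float(np.average(img.values, weights=mask.weights))
    vpeak = suv_peak(img, mask)
    return vmax, vpeak, vmean


def reference_uptake(
    img: VolumetricImage, liver_center, aorta_center
) -> ReferenceUptake:
    """Fractional-mask statistics for the liver and blood-pool VOIs."""
    lmax, lpeak, lmean = _sphere_stats(img, liver_center, LIVER_VOI_DIAMETER_MM)
    bmax, bpeak, bmean = _sphere_stats(img, aorta_center, BLOODPOOL_VOI_DIAMETER_MM)
    return ReferenceUptake(
        liver_suv_max=lmax,
        liver_suv_peak=lpeak,
        liver_suv_mean=lmean,
        bloodpool_suv_max=bmax,
        bloodpool_suv_peak=bpeak,
        bloodpool_suv_mean=bmean,
    )


def uptake_ratios(lesion: LesionRecord, ref: ReferenceUptake) -> dict[str, float]:
    """Tumor-to-liver and tumor-to-blood-pool ratios.

    Pairings follow the reported comparisons: lesion SUVmax over
    reference SUVmax and SUVmean, plus peak/peak and mean/mean variants.
    """
    refs = {
        "liver": (ref.liver_suv_max, ref.liver_suv_peak, ref.liver_suv_mean),
        "blood": (
            ref.bloodpool_suv_max,
            ref.bloodpool_suv_peak,
            ref.bloodpool_suv_mean,
        ),
    }
    out: dict[str, float] = {}
    for organ, (rmax, rpeak, rmean) in refs.items():
        if min(rmax, rpeak, rmean) <= 0:
            raise ValueError(f"nonpositive {organ} reference uptake")
        out[f"tumor_{organ}_max_max"] = lesion.suv_max / rmax
        out[f"tumor_{organ}_max_mean"] = lesion.suv_max / rmean
        out[f"tumor_{organ}_peak_peak"] = lesion.suv_peak / rpeak
        out[f"tumor_{organ}_mean_mean"] = lesion.suv_mean / rmean
    return out
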