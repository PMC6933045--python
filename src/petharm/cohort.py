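"""Synthetic two-arm patient cohort at two emulated reconstruction resolutions.

Each synthetic subject is a simple anthropomorphic torso in SUV units: an
elliptical-cylinder body at soft-tissue background uptake, a liver-like
ellipsoid at elevated uptake, an aorta-like cylinder at blood-pool
uptake, and one to three spherical lesions of uniform uptake placed away
from the reference organs and from each other. Two images per subject
emulate a sharper, resolution-recovered reconstruction ("EARL2-like")
and an older, smoother one ("EARL1-like"); they differ only in effective
Gaussian resolution, plus independent smoothed noise.

Lesion centers are snapped to voxel centers so that the recorded seed
voxel is exactly the lesion center and partial-volume behaviour is not
confounded by sub-voxel placement offsets (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .image import UNIT_SUV, VolumetricImage, gaussian_postfilter, make_sphere_mask
from .phantom import ellipse_cylinder_fraction

__all__ = [
    "CohortConfig",
    "LesionTruth",
    "SubjectTruth",
    "SubjectScans",
    "simulate_cohort",
    "RECON_EARL1",
    "RECON_EARL2",
]

RECON_EARL1 = "EARL1"
RECON_EARL2 = "EARL2"

ARM_LUNG = "lung"
ARM_LYMPHOMA = "lymphoma"

# Probability of 1/2/3 lesions per subject, tuned to the two arms'
# reported mean lesion counts (1.5 and 2.1).
_LESION_COUNT_PROBS = {
    ARM_LUNG: (0.6, 0.3, 0.1),
    ARM_LYMPHOMA: (0.25, 0.4, 0.35),
}


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the clinical cohort: 13 lung-cancer-like and 17
    lymphoma-like subjects, at most 3 lesions each, on a 4 mm grid, with
    the sharper reconstruction at 5 mm effective resolution and the
    older standard 7 mm (in quadrature) wider.
    """

    n_lung: int = 13
    n_lymphoma: int = 17
    max_lesions: int = 3
    lesion_diameter_range: tuple[float, float] = (12.0, 38.0)  # mm
    lesion_suv_range: tuple[float, float] = (4.5, 14.0)
    background_suv: float = 1.0
    liver_suv: float = 2.5
    liver_center: tuple[float, float, float] = (-20.0, 35.0, 60.0)  # (z, y, x) mm
    liver_semiaxes: tuple[float, float, float] = (35.0, 45.0, 55.0)
    bloodpool_suv: float = 2.0
    aorta_center_yx: tuple[float, float] = (-25.0, 0.0)
    aorta_radius: float = 14.0  # mm
    bloodpool_voi_center: tuple[float, float, float] = (20.0, -25.0, 0.0)
    earl2_psf_fwhm: float = 5.0  # mm
    earl1_extra_fwhm: float = 7.0  # mm, added in quadrature
    noise_sd_fraction: float = 0.08  # of background SUV, after smoothing
    exact_match: bool = False  # EARL1 := EARL2 (x) extra filter, same noise
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    shape: tuple[int, int, int] = (52, 56, 72)
    body_semiaxes: tuple[float, float] = (95.0, 130.0)  # (y, x) mm
    seed: int = 2019

    def __post_init__(self) -> None:
        if not (1 <= self.max_lesions <= 3):
            raise ValueError("max_lesions must be in [1, 3]")
        for v in (self.background_suv, self.liver_suv, self.bloodpool_suv):
            if v <= 0:
                raise ValueError("all uptake levels must be positive")
        if self.lesion_suv_range[0] <= 0:
            raise ValueError("lesion SUVs must be positive")
        if self.earl1_extra_fwhm < 0 or self.earl2_psf_fwhm < 0:
            raise ValueError("PSF FWHMs must be nonnegative")
        if self.noise_sd_fraction < 0:
            raise ValueError("noise_sd_fraction must be nonnegative")

    @property
    def earl1_psf_fwhm(self) -> float:
        """Effective resolution of the older-standard reconstruction."""
        return math.hypot(self.earl2_psf_fwhm, self.earl1_extra_fwhm)

    @property
    def body_length(self) -> float:
        return self.shape[0] * self.spacing[0]

    def grid(self) -> VolumetricImage:
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(self.shape, self.spacing))
        return VolumetricImage(
            values=np.zeros(self.shape), spacing=self.spacing, origin=origin,
            unit=UNIT_SUV,
        )


@dataclass
class LesionTruth:
    """Ground truth for one simulated lesion."""

    lesion_id: int
    center: tuple[float, float, float]  # mm, world (z, y, x)
    diameter: float  # mm
    suv: float
    seed_voxel: tuple[int, int, int]

    @property
    def volume_ml(self) -> float:
        return math.pi / 6.0 * self.diameter**3 / 1000.0


@dataclass
class SubjectTruth:
    subject_id: str
    arm: str
    lesions: list[LesionTruth]
    liver_voi_center: tuple[float, float, float]
    bloodpool_voi_center: tuple[float, float, float]
    psf_fwhm: dict[str, float]  # reconstruction label -> true FWHM (mm)


@dataclass
class SubjectScans:
    truth: SubjectTruth
    images: dict[str, VolumetricImage]  # RECON_EARL1 / RECON_EARL2


def _render_anatomy(cfg: CohortConfig, grid: VolumetricImage) -> np.ndarray:
    """Noise-free background + liver + blood pool, without lesions."""
    body = ellipse_cylinder_fraction(grid, cfg.body_semiaxes, cfg.body_length)
    values = cfg.background_suv * body

    org = np.asarray(grid.origin)
    sp = np.asarray(grid.spacing)
    zz, yy, xx = np.meshgrid(
        org[0] + np.arange(grid.shape[0]) * sp[0],
        org[1] + np.arange(grid.shape[1]) * sp[1],
        org[2] + np.arange(grid.shape[2]) * sp[2],
        indexing="ij",
    )
    lc = np.asarray(cfg.liver_center)
    la = np.asarray(cfg.liver_semiaxes)
    liver = (
        ((zz - lc[0]) / la[0]) ** 2
        + ((yy - lc[1]) / la[1]) ** 2
        + ((xx - lc[2]) / la[2]) ** 2
    ) <= 1.0
    liver &= body >= 1.0  # keep the organ inside the body outline
    values = values + (cfg.liver_suv - cfg.background_suv) * liver

    ay, ax = cfg.aorta_center_yx
    aorta = ((yy - ay) ** 2 + (xx - ax) ** 2 <= cfg.aorta_radius**2) & (
        np.abs(zz) <= cfg.body_length / 2.0 - sp[0]
    )
    values = values + (cfg.bloodpool_suv - cfg.background_suv) * aorta
    return values


def _lesion_position_ok(cfg: CohortConfig, center, radius, placed) -> bool:
    cz, cy, cx = center
    by, bx = cfg.body_semiaxes
    # fully inside the body with a 10 mm margin, conservatively
    margin = (radius + 10.0) / min(by, bx)
    if math.hypot(cy / by, cx / bx) + margin > 1.0:
        return False
    if abs(cz) + radius + 10.0 > cfg.body_length / 2.0:
        return False
    # clear of the liver (normalized ellipsoid coordinate) and the aorta
    lc = cfg.liver_center
    la = cfg.liver_semiaxes
    lnorm = math.sqrt(
        ((cz - lc[0]) / la[0]) ** 2
        + ((cy - lc[1]) / la[1]) ** 2
        + ((cx - lc[2]) / la[2]) ** 2
    )
    if lnorm < 1.0 + (radius + 20.0) / min(la):
        return False
    ay, ax = cfg.aorta_center_yx
    if math.hypot(cy - ay, cx - ax) < cfg.aorta_radius + radius + 15.0:
        return False
    for other_center, other_radius in placed:
        dist = math.dist(center, other_center)
        if dist < radius + other_radius + 20.0:
            return False
    return True


def _place_lesions(
    cfg: CohortConfig, grid: VolumetricImage, rng: np.random.Generator, n_lesions: int
) -> list[LesionTruth]:
    org = np.asarray(grid.origin)
    sp = np.asarray(grid.spacing)
    by, bx = cfg.body_semiaxes
    lesions: list[LesionTruth] = []
    placed: list[tuple[tuple[float, float, float], float]] = []
    for lesion_id in range(1, n_lesions + 1):
        diameter = float(rng.uniform(*cfg.lesion_diameter_range))
        suv = float(rng.uniform(*cfg.lesion_suv_range))
        radius = diameter / 2.0
        for _ in range(500):
            raw = (
                rng.uniform(-cfg.body_length / 2.0, cfg.body_length / 2.0),
                rng.uniform(-by, by),
                rng.uniform(-bx, bx),
            )
            # snap to the nearest voxel center
            idx = np.rint((np.asarray(raw) - org) / sp).astype(int)
            idx = np.clip(idx, 0, np.asarray(grid.shape) - 1)
            center = tuple(float(v) for v in org + idx * sp)
            if _lesion_position_ok(cfg, center, radius, placed):
                placed.append((center, radius))
                lesions.append(
                    LesionTruth(
                        lesion_id=lesion_id,
                        center=center,
                        diameter=diameter,
                        suv=suv,
                        seed_voxel=tuple(int(v) for v in idx),
                    )
                )
                break
        else:
            raise RuntimeError(
                f"could not place lesion {lesion_id} (diameter {diameter:.1f} mm) "
                "after 500 attempts; relax the geometry or lesion sizes"
            )
    return lesions


def _smoothed_noise(
    grid: VolumetricImage, rng: np.random.Generator, fwhm: float, sd: float
) -> np.ndarray:
    noise = rng.standard_normal(grid.shape)
    if fwhm > 0:
        noise = gaussian_postfilter(grid.with_values(noise), fwhm).values
        noise = noise / noise.std()
    return sd * noise


def simulate_subject(
    cfg: CohortConfig, subject_id: str, arm: str, rng: np.random.Generator
) -> SubjectScans:
    """Simulate one subject's paired images (sharper + older standard)."""
    grid = cfg.grid()
    probs = _LESION_COUNT_PROBS[arm][: cfg.max_lesions]
    probs = np.asarray(probs) / np.sum(probs)
    n_lesions = int(rng.choice(np.arange(1, len(probs) + 1), p=probs))
    lesions = _place_lesions(cfg, grid, rng, n_lesions)

    ideal = _render_anatomy(cfg, grid)
    for les in lesions:
        mask = make_sphere_mask(grid, les.center, les.diameter)
        ideal = ideal + (les.suv - cfg.background_suv) * mask.weights
    ideal_img = grid.with_values(ideal)

    noise_sd = cfg.noise_sd_fraction * cfg.background_suv
    earl2 = gaussian_postfilter(ideal_img, cfg.earl2_psf_fwhm)
    if noise_sd > 0:
        earl2 = earl2.with_values(
            earl2.values + _smoothed_noise(grid, rng, cfg.earl2_psf_fwhm, noise_sd)
        )
    if cfg.exact_match:
        earl1 = gaussian_postfilter(earl2, cfg.earl1_extra_fwhm)
    else:
        earl1 = gaussian_postfilter(ideal_img, cfg.earl1_psf_fwhm)
        if noise_sd > 0:
            earl1 = earl1.with_values(
                earl1.values + _smoothed_noise(grid, rng, cfg.earl1_psf_fwhm, noise_sd)
            )

    truth = SubjectTruth(
        subject_id=subject_id,
        arm=arm,
        lesions=lesions,
        liver_voi_center=cfg.liver_center,
        bloodpool_voi_center=cfg.bloodpool_voi_center,
        psf_fwhm={
            RECON_EARL2: cfg.earl2_psf_fwhm,
            RECON_EARL1: cfg.earl1_psf_fwhm,
        },
    )
    return SubjectScans(truth=truth, images={RECON_EARL1: earl1, RECON_EARL2: earl2})


def simulate_cohort(cfg: CohortConfig) -> list[SubjectScans]:
    """Simulate the full two-arm cohort, reproducibly for a fixed seed."""
    seq = np.random.SeedSequence(cfg.seed)
    n_total = cfg.n_lung + cfg.n_lymphoma
    children = seq.spawn(n_total)
    subjects: list[SubjectScans] = []
    arms = [ARM_LUNG] * cfg.n_lung + [ARM_LYMPHOMA] * cfg.n_lymphoma
    for i, (arm, child) in enumerate(zip(arms, children), start=1):
        rng = np.random.default_rng(child)
        subject_id = f"{arm[:4]}-{i:02d}"
        subjects.append(simulate_subject(cfg, subject_id, arm, rng))
    return subjects
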