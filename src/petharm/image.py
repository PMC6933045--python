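"""Voxel-grid primitives shared by every stage of the pipeline.

Conventions (used throughout the package):

* Arrays are indexed ``(z, y, x)``; ``spacing`` and ``origin`` follow the
  same axis order, in millimetres.
* ``origin`` is the world position of the *center* of voxel ``(0, 0, 0)``;
  the world coordinate of voxel ``(i, j, k)`` is ``origin + index * spacing``.
* SUV normalisation assumes a tissue density of 1 g/ml (standard
  body-weight SUV), so 1 kg of tissue occupies 1000 ml.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft

__all__ = [
    "VolumetricImage",
    "SubjectContext",
    "FractionalMask",
    "fwhm_to_sigma",
    "gaussian_postfilter",
    "suv_normalize",
    "make_sphere_mask",
    "suv_peak",
    "PEAK_SPHERE_DIAMETER_MM",
    "SUBVOXEL_SAMPLES",
]

#: Diameter of the SUVpeak sphere (12 mm, the "1.2-cm-diameter VOI").
PEAK_SPHERE_DIAMETER_MM: float = 12.0

#: Regular subvoxel sampling density used for fractional-volume estimates
#: (5 x 5 x 5 = 125 sample points per voxel).
SUBVOXEL_SAMPLES: int = 5

# FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian.
_FWHM_PER_SIGMA: float = 2.0 * math.sqrt(2.0 * math.log(2.0))

UNIT_KBQ_ML = "kBq/ml"
UNIT_SUV = "SUV"
_VALID_UNITS = (UNIT_KBQ_ML, UNIT_SUV)


@dataclass
class VolumetricImage:
    """A 3-D scalar image on a regular grid with physical spacing.

    Parameters
    ----------
    values
        3-D array, axis order ``(z, y, x)``. Activity concentration in
        kBq/ml or dimensionless SUV depending on ``unit``.
    spacing
        Voxel edge lengths in mm, ``(z, y, x)``.
    origin
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    unit
        Either ``"kBq/ml"`` or ``"SUV"``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = UNIT_KBQ_ML

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3-D array with nonempty axes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive lengths (mm)")
        self.origin = tuple(float(o) for o in self.origin)
        if self.unit not in _VALID_UNITS:
            raise ValueError(f"unit must be one of {_VALID_UNITS}, got {self.unit!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    def voxel_to_world(self, index) -> np.ndarray:
        """World coordinates (mm) of a voxel center."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(
            self.spacing
        )

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Outer bounding box of the grid (voxel faces, not centers)."""
        org = np.asarray(self.origin)
        sp = np.asarray(self.spacing)
        shape = np.asarray(self.shape)
        return org - 0.5 * sp, org + (shape - 0.5) * sp

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "VolumetricImage":
        """New image on the same grid with different values."""
        return VolumetricImage(
            values=values,
            spacing=self.spacing,
            origin=self.origin,
            unit=self.unit if unit is None else unit,
        )

    def same_grid(self, other: "VolumetricImage") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class SubjectContext:
    """Normalisation quantities behind SUV.

    ``injected_activity`` is the administered activity in MBq, decay
    corrected to scan time; ``body_weight`` is in kg.  For phantom data,
    use total phantom activity and phantom volume (in kg-equivalent,
    i.e. litres) instead.
    """

    injected_activity: float
    body_weight: float

    def __post_init__(self) -> None:
        if not (self.injected_activity > 0 and self.body_weight > 0):
            raise ValueError("injected_activity and body_weight must be positive")


@dataclass
class FractionalMask:
    """Per-voxel inclusion weights in [0, 1] on some image's grid."""

    weights: np.ndarray
    voxel_volume: float  # ml

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 3:
            raise ValueError("weights must be a 3-D array")
        if self.weights.size and (self.weights.min() < 0 or self.weights.max() > 1):
            raise ValueError("weights must lie in [0, 1]")
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be positive (ml)")

    @property
    def total_volume_ml(self) -> float:
        return float(self.weights.sum()) * self.voxel_volume

    def is_empty(self) -> bool:
        return not bool(np.any(self.weights > 0))


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a Gaussian full width at half maximum (mm) to sigma (mm)."""
    if fwhm < 0:
        raise ValueError("fwhm must be nonnegative")
    return fwhm / _FWHM_PER_SIGMA


def gaussian_postfilter(img: VolumetricImage, fwhm: float) -> VolumetricImage:
    """Apply an isotropic (in world space) Gaussian post-filter.

    ``fwhm`` is the kernel full width at half maximum in mm; anisotropic
    voxel spacing is handled per axis. The filter is applied in the
    frequency domain with the exact Gaussian transfer function
    ``exp(-2 pi^2 sigma^2 f^2)``, so successive filters compose exactly in
    quadrature (``f1 (x) f2 = sqrt(f1^2 + f2^2)``), total activity is
    conserved, and the effective spatial kernel (the periodised Gaussian)
    is strictly positive. Boundary handling is periodic; images are
    expected to have quiet borders, as reconstructed PET volumes do. A
    zero FWHM returns the values unchanged (on a fresh image object).
    """
    if fwhm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm == 0:
        return img.with_values(img.values.copy())
    sigma_mm = fwhm_to_sigma(fwhm)
    spectrum = sp_fft.rfftn(img.values)
    shape = img.values.shape
    for axis in range(3):
        n = shape[axis]
        if axis == 2:
            freqs = np.fft.rfftfreq(n, d=img.spacing[axis])
        else:
            freqs = np.fft.fftfreq(n, d=img.spacing[axis])
        gain = np.exp(-2.0 * (np.pi * sigma_mm * freqs) ** 2)
        dims = [1, 1, 1]
        dims[axis] = len(freqs)
        spectrum *= gain.reshape(dims)
    filtered = sp_fft.irfftn(spectrum, s=shape)
    return img.with_values(filtered)


def suv_normalize(img: VolumetricImage, ctx: SubjectContext) -> VolumetricImage:
    """Convert an activity-concentration image (kBq/ml) to body-weight SUV.

    SUV(v) = C(v) / (injected_activity / body_weight), reconciling units
    under 1 kg == 1000 ml of tissue: with C in kBq/ml and activity in MBq,
    the whole-body reference concentration is
    ``injected_activity * 1000 kBq / (body_weight * 1000 ml)``, so
    ``SUV = C * body_weight / injected_activity``.
    """
    if img.unit != UNIT_KBQ_ML:
        raise ValueError(f"suv_normalize expects a {UNIT_KBQ_ML} image, got {img.unit}")
    suv = img.values * (ctx.body_weight / ctx.injected_activity)
    return img.with_values(suv, unit=UNIT_SUV)


def _subvoxel_offsets(n: int) -> np.ndarray:
    """Regular sample offsets within one voxel, in voxel units, centered."""
    return (np.arange(n) + 0.5) / n - 0.5


def _sphere_window(
    grid: VolumetricImage, center, diameter: float, subsamples: int
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Fractional sphere weights on the sphere's bounding-box window.

    Returns the window slices into the grid and the weight array for
    those voxels; voxels outside the grid are clipped away.
    """
    center = np.asarray(center, dtype=float)
    radius = diameter / 2.0
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    shape = np.asarray(grid.shape)

    idx_lo = np.maximum(
        np.floor((center - radius - origin) / spacing - 0.5), 0
    ).astype(int)
    idx_hi = np.minimum(
        np.ceil((center + radius - origin) / spacing + 0.5).astype(int) + 1, shape
    )
    window = tuple(slice(int(a), int(b)) for a, b in zip(idx_lo, idx_hi))
    if np.any(idx_lo >= idx_hi):
        return window, np.zeros([max(b - a, 0) for a, b in zip(idx_lo, idx_hi)])

    offs = _subvoxel_offsets(subsamples)
    # per-axis squared sample distances, combined by broadcasting
    p2 = []
    for axis in range(3):
        pos = (
            origin[axis]
            + (np.arange(idx_lo[axis], idx_hi[axis])[:, None] + offs[None, :])
            * spacing[axis]
            - center[axis]
        )
        p2.append(pos * pos)
    d2 = (
        p2[0][:, None, None, :, None, None]
        + p2[1][None, :, None, None, :, None]
        + p2[2][None, None, :, None, None, :]
    )
    counts = np.count_nonzero(d2 <= radius * radius, axis=(3, 4, 5))
    return window, counts / float(subsamples**3)


def make_sphere_mask(
    grid: VolumetricImage,
    center,
    diameter: float,
    subsamples: int = SUBVOXEL_SAMPLES,
) -> FractionalMask:
    """Fractional-voxel mask of a sphere on ``grid``.

    Each voxel's weight is the fraction of its volume inside the sphere,
    estimated by regular ``subsamples^3`` subvoxel sampling. The mask is
    clipped at the image boundary (out-of-grid voxels simply do not
    exist), so a sphere straddling the edge loses the outside portion.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    center = np.asarray(center, dtype=float)
    lo, hi = grid.world_bounds()
    if np.any(center < lo) or np.any(center > hi):
        raise ValueError(f"sphere center {center.tolist()} outside grid bounding box")
    window, frac = _sphere_window(grid, center, diameter, subsamples)
    weights = np.zeros(grid.shape, dtype=float)
    weights[window] = frac
    return FractionalMask(weights=weights, voxel_volume=grid.voxel_volume_ml)


def sphere_mean(
    img: VolumetricImage,
    center,
    diameter: float,
    subsamples: int = SUBVOXEL_SAMPLES,
) -> float:
    """Fractional-weighted mean of ``img`` inside a sphere.

    The mean is the ratio of the weighted sum to the weight sum over the
    sphere's bounding-box window; spheres truncated by the grid boundary
    are thereby renormalised to the in-bounds weights.
    """
    window, weights = _sphere_window(img, center, diameter, subsamples)
    wsum = np.sum(weights)
    if wsum == 0:
        raise ValueError("sphere does not cover any voxel")
    return float(np.sum(weights * img.values[window]) / wsum)


def suv_peak(
    img: VolumetricImage,
    tumor: FractionalMask,
    diameter: float = PEAK_SPHERE_DIAMETER_MM,
) -> float:
    """SUVpeak: highest mean uptake in a 1.2-cm sphere over tumor voxels.

    Candidate sphere centers are the centers of all voxels with tumor
    weight > 0; for each, the fractional-weighted mean inside a sphere of
    ``diameter`` is computed and the maximum returned.  Ties are
    irrelevant to the returned value. Peak spheres clipped by the image
    boundary are renormalised to the in-bounds weights.
    """
    if tumor.weights.shape != img.values.shape:
        raise ValueError("tumor mask must share the image grid")
    candidates = np.argwhere(tumor.weights > 0)
    if candidates.shape[0] == 0:
        raise ValueError("tumor mask is empty")
    best = -math.inf
    for idx in candidates:
        center = img.voxel_to_world(idx)
        mean = sphere_mean(img, center, diameter)
        if mean > best:
            best = mean
    return best
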