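"""Lesion VOI segmentation: SUV4, MAX41 and A50P region growing.

All three methods grow a 26-connected region from a seed voxel; they
differ only in how the threshold is set:

* **SUV4** — fixed absolute threshold, SUV >= 4.0.
* **MAX41** — 41% of the lesion SUVmax, where SUVmax is resolved by
  fixed-point iteration starting from the seed neighbourhood's maximum
  (the reference tooling does not state whether SUVmax is global or
  region-restricted; the region-restricted fixed point is used).
* **A50P** — background-adapted 50% of SUVpeak:
  ``T = BG + 0.5 * (SUVpeak - BG)``, with SUVpeak computed on a
  provisional lesion region and BG the mean uptake in a 2-voxel-thick
  shell starting 2 voxels outside it; iterated to a fixed point.

All thresholds are inclusive (``>=``).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .image import FractionalMask, VolumetricImage, suv_peak

__all__ = [
    "NotQuantifiableError",
    "SegmentationError",
    "segment_suv4",
    "segment_max41",
    "segment_a50p",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)

SUV4_THRESHOLD = 4.0
MAX41_FRACTION = 0.41
MAX_ITERATIONS = 50


class SegmentationError(ValueError):
    """Segmentation failed (no contrast, no convergence, ...)."""


class NotQuantifiableError(SegmentationError):
    """The lesion cannot be quantified by the requested VOI method."""


def _grown_region(values: np.ndarray, start, threshold: float) -> np.ndarray:
    """26-connected component of ``values >= threshold`` containing ``start``."""
    above = values >= threshold
    if not above[tuple(start)]:
        return np.zeros_like(above)
    labels, _ = ndimage.label(above, structure=_CONN26)
    return labels == labels[tuple(start)]


def _neighborhood_argmax(values: np.ndarray, seed) -> tuple[tuple[int, ...], float]:
    """Hottest voxel in the seed's 3x3x3 neighbourhood (clipped at edges)."""
    seed = tuple(int(s) for s in seed)
    lo = [max(s - 1, 0) for s in seed]
    hi = [min(s + 2, n) for s, n in zip(seed, values.shape)]
    sub = values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    rel = np.unravel_index(int(np.argmax(sub)), sub.shape)
    idx = tuple(l + r for l, r in zip(lo, rel))
    return idx, float(values[idx])


def segment_suv4(
    img: VolumetricImage, seed, threshold: float = SUV4_THRESHOLD
) -> np.ndarray:
    """Region grown from ``seed`` over voxels with SUV >= 4.0."""
    seed = tuple(int(s) for s in seed)
    if img.values[seed] < threshold:
        raise NotQuantifiableError(
            f"lesion not quantifiable by SUV4: seed value {img.values[seed]:.2f} "
            f"is below the SUV >= {threshold} threshold"
        )
    return _grown_region(img.values, seed, threshold)


def segment_max41(
    img: VolumetricImage,
    seed,
    fraction: float = MAX41_FRACTION,
    max_iterations: int = MAX_ITERATIONS,
) -> np.ndarray:
    """Region grown at 41% of the lesion SUVmax (fixed-point iteration).

    Starting from the maximum over the seed's 3x3x3 neighbourhood, the
    region at ``fraction * SUVmax`` is grown, SUVmax recomputed over it,
    and the loop repeated until the maximum stabilises. The maximum is
    non-decreasing across iterations, so the loop terminates; a cap
    guards against pathological inputs.
    """
    values = img.values
    hot_idx, current_max = _neighborhood_argmax(values, seed)
    for _ in range(max_iterations):
        region = _grown_region(values, hot_idx, fraction * current_max)
        new_max = float(values[region].max())
        if new_max == current_max:
            return region
        current_max = new_max
        flat = int(np.argmax(np.where(region, values, -np.inf)))
        hot_idx = np.unravel_index(flat, values.shape)
    raise SegmentationError(
        f"MAX41 did not converge within {max_iterations} iterations"
    )


def _background_shell(region: np.ndarray, gap: int = 2, thickness: int = 2) -> np.ndarray:
    inner = ndimage.binary_dilation(region, structure=_CONN26, iterations=gap)
    outer = ndimage.binary_dilation(
        inner, structure=_CONN26, iterations=thickness
    )
    return outer & ~inner


def segment_a50p(
    img: VolumetricImage,
    seed,
    max_iterations: int = MAX_ITERATIONS,
) -> np.ndarray:
    """Background-adapted 50%-of-SUVpeak region growing.

    The threshold ``T = BG + 0.5 * (SUVpeak - BG)`` adapts to local
    tumor-to-background contrast: BG is the mean uptake in a local shell
    around the current region and SUVpeak the highest 1.2-cm-sphere mean
    over the region's voxels. The region/threshold pair is iterated to a
    fixed point.
    """
    values = img.values
    hot_idx, local_max = _neighborhood_argmax(values, seed)
    region = _grown_region(values, hot_idx, 0.5 * local_max)
    for _ in range(max_iterations):
        peak = suv_peak(img, FractionalMask(region.astype(float), img.voxel_volume_ml))
        shell = _background_shell(region)
        if not shell.any():
            # provisional region flooded the grid: no local background exists
            raise NotQuantifiableError(
                "lesion not quantifiable by A50P: no local background "
                "(insufficient tumor-to-background contrast)"
            )
        bg = float(values[shell].mean())
        if peak <= bg:
            raise NotQuantifiableError(
                f"lesion not quantifiable by A50P: SUVpeak {peak:.2f} does not "
                f"exceed local background {bg:.2f}"
            )
        threshold = bg + 0.5 * (peak - bg)
        start = hot_idx if values[hot_idx] >= threshold else None
        if start is None:
            raise NotQuantifiableError(
                "lesion not quantifiable by A50P: threshold above lesion maximum"
            )
        new_region = _grown_region(values, start, threshold)
        if np.array_equal(new_region, region):
            return region
        region = new_region
        flat = int(np.argmax(np.where(region, values, -np.inf)))
        hot_idx = np.unravel_index(flat, values.shape)
    raise SegmentationError(
        f"A50P did not converge within {max_iterations} iterations"
    )
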