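"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's fast paths: sphere weights are
recomputed from the geometric definition with a plain loop over subvoxel
offsets on the full grid, the peak search enumerates every candidate
center, the rank tests enumerate their exact permutation nulls, and the
blurred-sphere profile comes from the closed-form convolution of a
uniform ball with a Gaussian.
"""

import math
from itertools import combinations, product

import numpy as np


def sphere_weights(img, center, diameter, subsamples=5):
    """Full-grid fractional sphere weights by regular subvoxel sampling."""
    org = np.asarray(img.origin)
    sp = np.asarray(img.spacing)
    r2 = (diameter / 2.0) ** 2
    counts = np.zeros(img.shape, dtype=np.int64)
    idx = np.indices(img.shape)
    offsets = (np.arange(subsamples) + 0.5) / subsamples - 0.5
    for oz, oy, ox in product(offsets, repeat=3):
        pz = org[0] + (idx[0] + oz) * sp[0] - center[0]
        py = org[1] + (idx[1] + oy) * sp[1] - center[1]
        px = org[2] + (idx[2] + ox) * sp[2] - center[2]
        counts += (pz * pz + py * py + px * px) <= r2
    return counts / float(subsamples**3)


def brute_force_suv_peak(img, tumor_weights, diameter=12.0):
    """Exhaustive SUVpeak search over every tumor voxel center."""
    best = -math.inf
    for idx in np.argwhere(np.asarray(tumor_weights) > 0):
        center = np.asarray(img.origin) + idx * np.asarray(img.spacing)
        w = sphere_weights(img, center, diameter)
        mean = float(np.sum(w * img.values) / np.sum(w))
        if mean > best:
            best = mean
    return best


def wilcoxon_exact(differences):
    """Exact two-sided signed-rank p by enumerating all sign assignments.

    Pratt convention: zeros are ranked with the rest and dropped from the
    statistic; the null is conditional on the observed magnitudes.
    p = min(1, 2 * min(P(W+ <= w), P(W+ >= w))).
    """
    d = np.asarray(differences, dtype=float)
    order = np.abs(d)
    # midranks, computed by hand
    sorted_idx = np.argsort(order, kind="stable")
    ranks = np.empty(len(d))
    i = 0
    while i < len(d):
        j = i
        while j + 1 < len(d) and order[sorted_idx[j + 1]] == order[sorted_idx[i]]:
            j += 1
        ranks[sorted_idx[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    nz = np.flatnonzero(d)
    if len(nz) == 0:
        return 1.0
    w_obs = float(ranks[d > 0].sum())
    r = ranks[nz]
    le = ge = total = 0
    for signs in product((0, 1), repeat=len(nz)):
        w = float(np.dot(signs, r))
        le += w <= w_obs + 1e-9
        ge += w >= w_obs - 1e-9
        total += 1
    return min(1.0, 2.0 * min(le / total, ge / total))


def mannwhitney_exact(a, b):
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n = len(pooled)
    # midranks by hand
    sorted_idx = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[sorted_idx[j + 1]] == pooled[sorted_idx[i]]:
            j += 1
        ranks[sorted_idx[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    n_a = len(a)
    offset = n_a * (n_a + 1) / 2.0
    u_obs = float(ranks[:n_a].sum()) - offset
    le = ge = total = 0
    for combo in combinations(range(n), n_a):
        u = float(ranks[list(combo)].sum()) - offset
        le += u <= u_obs + 1e-9
        ge += u >= u_obs - 1e-9
        total += 1
    return min(1.0, 2.0 * min(le / total, ge / total))


def blurred_sphere_profile(r, radius, amplitude, sigma, background=0.0):
    """Closed-form value of a Gaussian-blurred uniform ball at radius r.

    Convolution of an indicator ball (value ``amplitude`` above
    ``background``) with an isotropic Gaussian of width ``sigma``:

        f(r) = 1/2 [erf((R-r)/(s*sqrt(2))) + erf((R+r)/(s*sqrt(2)))]
               - s/(r*sqrt(2*pi)) [exp(-(R-r)^2/(2 s^2)) - exp(-(R+r)^2/(2 s^2))]

    with the r -> 0 limit erf(R/(s*sqrt(2))) - sqrt(2/pi)(R/s)exp(-R^2/(2s^2)).
    """
    R, s = radius, sigma
    if r < 1e-12:
        frac = math.erf(R / (s * math.sqrt(2.0))) - math.sqrt(2.0 / math.pi) * (
            R / s
        ) * math.exp(-(R**2) / (2.0 * s**2))
    else:
        frac = 0.5 * (
            math.erf((R - r) / (s * math.sqrt(2.0)))
            + math.erf((R + r) / (s * math.sqrt(2.0)))
        ) - s / (r * math.sqrt(2.0 * math.pi)) * (
            math.exp(-((R - r) ** 2) / (2.0 * s**2))
            - math.exp(-((R + r) ** 2) / (2.0 * s**2))
        )
    return background + (amplitude - background) * frac
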