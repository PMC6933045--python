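"""Paired comparison of lesion metrics across reconstructions.

Per-lesion relative differences are taken against the EARL1 baseline,
summarised as medians with 25th/75th percentiles (type-7 linear
interpolation, numpy's default), stratified by lesion size and contrast,
and tested with nonparametric tests: Wilcoxon signed-rank for paired
reconstruction contrasts and Mann-Whitney U for independent groups.

Small samples use exact enumeration of the permutation null (all sign
assignments, respectively all group assignments) with midranks for ties
and Pratt handling of zero differences; larger samples fall back to the
usual normal approximations from scipy. Two-sided p-values follow the
doubled-tail convention ``p = min(1, 2 * min(P(T <= t), P(T >= t)))``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "relative_difference",
    "paired_test",
    "group_test",
    "summarize",
    "METRICS",
    "EXACT_N_MAX",
]

#: Metric columns summarised by :func:`summarize`.
METRICS = ("matv_ml", "suv_max", "suv_peak", "suv_mean", "tlg")

#: Largest sample size for which the exact permutation null is enumerated.
EXACT_N_MAX = 12

_TIE_EPS = 1e-9


def relative_difference(x: float, baseline: float) -> float:
    """Relative difference in percent: ``100 * (x - baseline) / baseline``."""
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    return 100.0 * (x - baseline) / baseline


def _doubled_tail(null: np.ndarray, observed: float) -> float:
    lo = float(np.mean(null <= observed + _TIE_EPS))
    hi = float(np.mean(null >= observed - _TIE_EPS))
    return min(1.0, 2.0 * min(lo, hi))


def paired_test(differences) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired differences.

    Zeros are handled by the Pratt method (ranked with the rest, then
    dropped from the statistic). With at most ``EXACT_N_MAX`` nonzero
    differences the exact conditional null over all 2^n sign assignments
    is enumerated; above that scipy's normal approximation (Pratt zero
    handling, tie-corrected) is used. All-zero input gives p = 1 with a
    warning; n < 5 nonzero differences also warns (exact p reported).
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("differences must be a nonempty 1-D array")
    nonzero = d != 0
    n = int(nonzero.sum())
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    if n < 5:
        warnings.warn(
            f"only {n} nonzero differences; exact p-value has coarse resolution",
            stacklevel=2,
        )
    ranks = sps.rankdata(np.abs(d))  # zeros included: Pratt
    w_pos = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        r = ranks[nonzero]
        signs = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        null = signs @ r
        return _doubled_tail(null, w_pos)
    res = sps.wilcoxon(d, zero_method="pratt", correction=False, method="approx")
    return float(res.pvalue)


def group_test(values_a, values_b) -> float:
    """Two-sided Mann-Whitney U p-value for two independent groups.

    Exact enumeration over all group assignments of the pooled midranks
    when the combined sample size is at most ``EXACT_N_MAX``; scipy's
    tie-corrected normal approximation with continuity correction above.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = a.size, b.size
    if n_a + n_b <= EXACT_N_MAX:
        from itertools import combinations

        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        observed_u = float(ranks[:n_a].sum()) - n_a * (n_a + 1) / 2.0
        null = np.array(
            [
                ranks[list(combo)].sum() - n_a * (n_a + 1) / 2.0
                for combo in combinations(range(n_a + n_b), n_a)
            ]
        )
        return _doubled_tail(null, observed_u)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


# --- cohort summary -------------------------------------------------------

_STRATA = ("all", "matv_lt_10", "matv_ge_10", "suvmean_le_7", "suvmean_gt_7")
_MATV_CUT_ML = 10.0
_SUVMEAN_CUT = 7.0
_ALPHA = 0.05


def _check_baselines(df: pd.DataFrame, baseline: str) -> None:
    keys = ["subject_id", "lesion_id", "voi_method"]
    has_baseline = df[df["reconstruction"] == baseline].set_index(keys).index
    all_keys = df.set_index(keys).index.unique()
    missing = sorted(set(all_keys) - set(has_baseline))
    if missing:
        raise ValueError(f"lesions without a {baseline} baseline row: {missing}")


def summarize(
    records: pd.DataFrame,
    baseline: str = "EARL1",
    metrics=METRICS,
    alpha: float = _ALPHA,
) -> pd.DataFrame:
    """Median relative differences vs the baseline reconstruction.

    ``records`` is the tidy metrics table (one row per lesion x VOI
    method x reconstruction). Returns one row per VOI method x metric x
    reconstruction x arm x stratum with the median, 25th/75th
    percentiles, Wilcoxon signed-rank p-value, sample size and a
    significance flag at ``alpha``. Strata are defined on the lesion's
    baseline values: MATV < / >= 10 ml and SUVmean <= / > 7.
    """
    required = {"subject_id", "lesion_id", "arm", "voi_method", "reconstruction"}
    if not required.issubset(records.columns):
        raise ValueError(f"records table missing columns {required - set(records.columns)}")
    _check_baselines(records, baseline)

    keys = ["subject_id", "lesion_id", "voi_method"]
    base = (
        records[records["reconstruction"] == baseline]
        .set_index(keys)[list(metrics)]
        .add_suffix("_base")
    )
    rows = []
    others = records[records["reconstruction"] != baseline]
    merged = others.join(base, on=keys)
    merged = merged.assign(
        stratum_size=np.where(
            merged["matv_ml_base"] < _MATV_CUT_ML, "matv_lt_10", "matv_ge_10"
        ),
        stratum_contrast=np.where(
            merged["suv_mean_base"] <= _SUVMEAN_CUT, "suvmean_le_7", "suvmean_gt_7"
        ),
    )

    arms = list(dict.fromkeys(records["arm"])) + ["combined"]
    for voi_method, by_method in merged.groupby("voi_method", sort=False):
        for recon, by_recon in by_method.groupby("reconstruction", sort=False):
            for arm in arms:
                in_arm = by_recon if arm == "combined" else by_recon[by_recon["arm"] == arm]
                for stratum in _STRATA:
                    if stratum == "all":
                        sub = in_arm
                    elif stratum.startswith("matv"):
                        sub = in_arm[in_arm["stratum_size"] == stratum]
                    else:
                        sub = in_arm[in_arm["stratum_contrast"] == stratum]
                    for metric in metrics:
                        pair = sub[[metric, f"{metric}_base"]].dropna()
                        if pair.empty:
                            continue
                        x = pair[metric].to_numpy()
                        b = pair[f"{metric}_base"].to_numpy()
                        rel = 100.0 * (x - b) / b
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            p = paired_test(x - b)
                        rows.append(
                            {
                                "voi_method": voi_method,
                                "metric": metric,
                                "reconstruction": recon,
                                "arm": arm,
                                "stratum": stratum,
                                "n": len(rel),
                                "median_pct": float(np.median(rel)),
                                "p25_pct": float(np.percentile(rel, 25)),
                                "p75_pct": float(np.percentile(rel, 75)),
                                "p_value": p,
                                "significant": bool(p < alpha),
                            }
                        )
    return pd.DataFrame(rows)
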