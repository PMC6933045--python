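#!/usr/bin/env python
"""Summarise how the standard change shifts the lesion metrics.

Reads the tidy metrics written by 04_quantify_lesions.py and prints the
headline comparison (MAX41, both arms combined): median relative
differences of each metric for the sharper (EARL2) and 7-mm-filtered
(EARL2F7) reconstructions against the EARL1 baseline, with quartiles and
Wilcoxon signed-rank significance. Box plots mirroring the per-arm
comparison are written to results/figures/.
"""

from pathlib import Path

import pandas as pd

from petharm.plots import relative_difference_boxplots
from petharm.stats import summarize

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    metrics_path = BASE / "cohort" / "lesion_metrics.csv"
    if not metrics_path.exists():
        raise SystemExit(f"{metrics_path} missing; run 04_quantify_lesions.py first")
    records = pd.read_csv(metrics_path)
    summary = summarize(records)
    summary.to_csv(BASE / "cohort" / "comparison_summary.csv", index=False)

    view = summary[
        (summary.voi_method == "MAX41")
        & (summary.arm == "combined")
        & (summary.stratum == "all")
    ][["metric", "reconstruction", "n", "median_pct", "p25_pct", "p75_pct",
       "p_value", "significant"]]
    print("MAX41, both arms combined, relative differences vs EARL1 (%):")
    print(view.to_string(index=False, float_format=lambda v: f"{v:8.2f}"))

    figures = relative_difference_boxplots(
        records[records.voi_method == "MAX41"], BASE / "figures"
    )
    print(f"wrote {len(figures)} box-plot figures to {BASE / 'figures'}")


if __name__ == "__main__":
    main()
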