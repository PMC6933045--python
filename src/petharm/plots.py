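"""Box-plot figures of relative differences vs the baseline reconstruction."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .stats import METRICS


def relative_difference_boxplots(
    records: pd.DataFrame,
    out_dir: Path,
    baseline: str = "EARL1",
    metrics=METRICS,
) -> list[Path]:
    """One figure per metric: per-arm boxes of relative differences (%)
    for each non-baseline reconstruction. Returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    keys = ["subject_id", "lesion_id", "voi_method"]
    base = (
        records[records["reconstruction"] == baseline]
        .set_index(keys)[list(metrics)]
        .add_suffix("_base")
    )
    merged = records[records["reconstruction"] != baseline].join(base, on=keys)
    written: list[Path] = []
    arms = list(dict.fromkeys(records["arm"].dropna()))
    recons = list(dict.fromkeys(merged["reconstruction"]))
    for metric in metrics:
        fig, ax = plt.subplots(figsize=(7, 4))
        data, labels = [], []
        for recon in recons:
            for arm in arms:
                sub = merged[(merged["reconstruction"] == recon) & (merged["arm"] == arm)]
                pair = sub[[metric, f"{metric}_base"]].dropna()
                rel = 100.0 * (pair[metric] - pair[f"{metric}_base"]) / pair[f"{metric}_base"]
                data.append(rel.to_numpy())
                labels.append(f"{recon}\n{arm}")
        ax.boxplot(data, tick_labels=labels)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_ylabel(f"{metric} relative difference vs {baseline} (%)")
        fig.tight_layout()
        path = out_dir / f"reldiff_{metric}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
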