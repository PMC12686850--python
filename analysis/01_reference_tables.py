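#!/usr/bin/env python
"""Recompute the group-level statistics from the per-dataset reference rows.

The published per-dataset tables (12 olfactory bulbs, three age groups)
are the inputs; everything at the group level — medians of medians,
IQRs, bootstrap CIs of the median, and all pairwise exact Mann-Whitney
comparisons — is recomputed here with the package's statistics layer
and written under results/.
"""

import json
from pathlib import Path

import pandas as pd

from glomquant import tables
from glomquant.pipeline import RunConfig, run_group_comparison
from glomquant.stats import group_summary, quantiles_linear

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    t2 = tables.load_counts_sizes()
    t4 = tables.load_shape()
    merged = t2.merge(t4.drop(columns=["age_group"]), on="dataset")

    group_rows = []
    for metric in ("n_glomeruli", "total_volume_mm3", "median_volume_um3",
                   "median_effective_diameter_um", "median_alr_xz",
                   "median_alr_yz", "median_sphericity"):
        for group, values in tables.group_values(merged, metric).items():
            s = group_summary(values, seed=0)
            group_rows.append({"metric": metric, "age_group": group, **s})
    groups = pd.DataFrame(group_rows)
    groups.to_csv(RESULTS / "group_summaries.csv", index=False)

    comparisons = run_group_comparison(
        merged, RunConfig(),
        metrics=("n_glomeruli", "total_volume_mm3", "median_volume_um3",
                 "median_effective_diameter_um", "median_alr_xz",
                 "median_sphericity"))
    comparisons.to_csv(RESULTS / "group_comparisons.csv", index=False)

    counts = tables.group_values(t2, "n_glomeruli")
    q1, med, q3 = quantiles_linear(counts["PD21"])
    headline = {
        "total_glomeruli_segmented": int(t2["n_glomeruli"].sum()),
        "median_count_per_group": {
            g: quantiles_linear(v)[1] for g, v in counts.items()},
        "pd21_count_quartiles": [q1, q3],
    }
    (RESULTS / "headline_counts.json").write_text(json.dumps(headline, indent=2))

    print(f"{headline['total_glomeruli_segmented']} glomeruli across 12 bulbs; "
          f"group count medians: {headline['median_count_per_group']}")
    sig = comparisons[comparisons.p_exact < 0.05]
    tail = ""
    if len(sig) and ((sig.group_a == "PD56") | (sig.group_b == "PD56")).all():
        tail = " (every significant pair involves PD56)"
    print(f"{len(sig)}/{len(comparisons)} pairwise comparisons significant "
          f"at p < 0.05{tail}")


if __name__ == "__main__":
    main()
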