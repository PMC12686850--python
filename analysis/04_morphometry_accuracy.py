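#!/usr/bin/env python
"""Validate measured morphometry against the analytic ground truth.

Joins the per-object measurements of the synthetic bulb with the
generator's analytic truth and summarizes the recovery errors of
volume, effective diameter and aspect-length ratios. Writes
results/morphometry_accuracy.json.
"""

import json
from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = pd.read_csv(RESULTS / "synthetic_objects.csv")
    truth = pd.read_csv(RESULTS / "synthetic_truth.csv")
    m = table.merge(truth, on="label")

    vol_rel = (m["volume_um3"] / m["analytic_volume_um3"] - 1).abs()
    diam_abs = (m["effective_diameter_um"] - m["analytic_effective_diameter_um"]).abs()
    alr_xz = (m["alr_xz"] - m["expected_alr_xz"]).abs()
    alr_yz = (m["alr_yz"] - m["expected_alr_yz"]).abs()

    out = {
        "n_objects": int(len(m)),
        "volume_rel_error": {"max": float(vol_rel.max()),
                             "mean": float(vol_rel.mean())},
        "effective_diameter_abs_error_um": {"max": float(diam_abs.max()),
                                            "mean": float(diam_abs.mean())},
        "alr_xz_abs_error": {"max": float(alr_xz.max()),
                             "mean": float(alr_xz.mean())},
        "alr_yz_abs_error": {"max": float(alr_yz.max()),
                             "mean": float(alr_yz.mean())},
        "sphericity_range": [float(m["sphericity"].min()),
                             float(m["sphericity"].max())],
    }
    (RESULTS / "morphometry_accuracy.json").write_text(json.dumps(out, indent=2))
    print(f"{out['n_objects']} objects: max |volume error| "
          f"{out['volume_rel_error']['max']:.2%}, "
          f"max |ALR x/z error| {out['alr_xz_abs_error']['max']:.3f}, "
          f"sphericity {out['sphericity_range'][0]:.2f}-"
          f"{out['sphericity_range'][1]:.2f}")


if __name__ == "__main__":
    main()
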