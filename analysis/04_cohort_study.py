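#!/usr/bin/env python
"""The headline in-silico comparison: KIO vs KBI vs BD-DES.

Runs the full pipeline on one synthetic cohort (n = 5 per group, desk CFD
profile): strut layouts, meshing, steady flow, shear endpoints, OCT-style
metrics and the nonparametric group statistics.  Writes per-sample and
group-level tables under results/study_seed0/ and prints the rendered table.
"""

import logging
import os

from bifurcbench.study import RunConfig, cfd_profile_cohort, render_tables, run_study

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "study_seed0")


def main():
    logging.basicConfig(level=logging.INFO)
    cfg = RunConfig(cohort=cfd_profile_cohort(n_per_group=5, seed=0), outdir=OUT)
    report = run_study(cfg)
    print(render_tables(report))
    df = report.per_sample
    med = df.groupby("group")[["A_high_roi_mm2", "shear_max_roi",
                               "pct_floating", "thrombus_top3_mm2"]].median()
    print("\nGroup medians:")
    print(med.to_string())
    a = med["A_high_roi_mm2"]
    print(
        f"\nDirection of the CFD contrast: median ostial high-shear area "
        f"KIO {a['KIO']:.3f} mm^2 vs KBI {a['KBI']:.3f} mm^2 vs "
        f"BD-DES {a['BD-DES']:.3f} mm^2"
    )


if __name__ == "__main__":
    main()
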