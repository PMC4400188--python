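#!/usr/bin/env python
"""Run the full synthetic study end to end and summarize the group pattern.

Simulates every animal's dynamic [1-13C]pyruvate experiment and CINE scan
(published per-week group sizes; banded groups carry 1.3x lactate flux at 9
and 14 weeks, Western-diet groups 0.75x PDH flux throughout), quantifies and
fits each animal, and runs the per-timepoint two-way ANOVA layer.  Prints the
banded:sham flux ratios and surgery-effect p-values per week: the lactate
elevation should emerge at 9 weeks and persist at 14, with the bicarbonate
(PDH) rate unchanged by banding.

Writes the study outputs under results/full_study/.  Takes several minutes.
"""

import argparse
from pathlib import Path

import pandas as pd

from cardiodnp.pipeline import RunConfig, run_study

OUT = Path(__file__).resolve().parents[1] / "results" / "full_study"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    manifest = run_study(RunConfig(seed=args.seed), OUT)
    print(f"wrote {len(manifest['outputs'])} files to {OUT}\n")

    anova = pd.read_csv(OUT / "anova.csv")
    summary = pd.read_csv(OUT / "summary.csv")
    print("banded vs sham group pattern (fitted label-flux rates):")
    for measure in ("k_lactate", "k_bicarbonate"):
        for week in (4, 9, 14):
            sel = summary[(summary["week"] == week) & (summary["measure"] == measure)]
            aab = sel[sel["surgery"] == "aab"]["mean"].mean()
            sham = sel[sel["surgery"] == "sham"]["mean"].mean()
            p = anova[
                (anova["week"] == week)
                & (anova["measure"] == measure)
                & (anova["effect"] == "surgery")
            ]["p"].iloc[0]
            print(
                f"  {measure:<14s} week {week:>2d}: AAB/sham ratio "
                f"{aab / sham:5.2f}, surgery-effect p = {p:.4f}"
            )


if __name__ == "__main__":
    main()
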