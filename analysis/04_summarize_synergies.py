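#!/usr/bin/env python
"""Summarize the extracted synergies: weight table and temporal features.

Reads the per-subject outputs of 03_run_study_pipeline.py and prints the
group-level picture: for each synergy the most heavily weighted muscles per
protocol (the Table-4-style view), the post hoc annotations that survived
correction, and the mean +/- SD temporal activation features (the
Table-5-style view, recomputed here from the per-subject features file).
"""

from pathlib import Path

import pandas as pd

from kicksyn.timing import summarize_features

STUDY = Path("results/study")


def main() -> None:
    weights = pd.read_csv(STUDY / "weights_table.csv")
    for syn, grp in weights.groupby("synergy"):
        print(f"\n{syn}: top muscles by mean weight")
        for proto in ("ESG", "RBG", "SQG"):
            top = grp.nlargest(3, f"{proto}_mean")
            desc = ", ".join(
                f"{r.muscle} {getattr(r, f'{proto}_mean'):.2f}"
                for r in top.itertuples())
            print(f"  {proto}: {desc}")
        flagged = grp[grp["posthoc"].notna() & (grp["posthoc"] != "")]
        for r in flagged.itertuples():
            print(f"  significant protocol difference: {r.muscle}: "
                  f"{r.posthoc}")

    features = pd.read_csv(STUDY / "features.csv")
    table = summarize_features(features)
    print("\ntemporal features (mean +/- SD, % of cycle):")
    for r in table.itertuples():
        print(f"  {r.synergy} {r.protocol}: T={r.T_mean:.1f}+/-{r.T_sd:.1f}"
              f"  T_max={r.T_max_mean:.1f}+/-{r.T_max_sd:.1f}"
              f"  T_start={r.T_start_mean:.1f}+/-{r.T_start_sd:.1f}"
              f"  T_stop={r.T_stop_mean:.1f}+/-{r.T_stop_sd:.1f}")


if __name__ == "__main__":
    main()
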