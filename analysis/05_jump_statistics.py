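#!/usr/bin/env python
"""Jump-height analysis: flight-time conversion, best-of-3, RM-ANOVA.

Recomputes the vertical-jump branch from the raw flight times written by
03_run_study_pipeline.py: h = g t^2 / 8 per jump, best of three per subject,
protocol and time point, then the 3 x 3 fully within-subject ANOVA with
partial eta squared and per-time-point post hocs.  Also reprints the
a priori power analysis of the design.
"""

from pathlib import Path

import numpy as np

from kicksyn import jumpstats as js
from kicksyn.interface import read_jumps_csv
from kicksyn.muscles import PROTOCOLS, TIME_POINTS_MIN

STUDY = Path("results/study")


def main() -> None:
    spec = js.PowerSpec(effect_size_f=0.30)
    n_req = js.rm_anova_sample_size(spec)
    print(f"a priori power (f=0.30, alpha=0.05, power 0.80, m=3, rho=0.5): "
          f"minimum N = {n_req}; power at N=18: "
          f"{js.rm_anova_power(spec, 18):.3f}")

    jumps = read_jumps_csv(STUDY / "jumps.csv")
    jumps["height_cm"] = js.jump_height(jumps["flight_time_s"].to_numpy())
    best = (jumps.groupby(["subject", "protocol", "time_point_min"])
            ["height_cm"].max().unstack(["protocol", "time_point_min"]))
    arr = np.stack([best[p][list(TIME_POINTS_MIN)].to_numpy()
                    for p in PROTOCOLS], axis=1)

    results = js.two_way_rm_anova(arr, ("protocol", "time"))
    print("\ntwo-way RM-ANOVA on best-of-3 jump height:")
    for r in results:
        print(f"  {r.effect_name}: F({r.df_num:.0f}, {r.df_den:.0f}) = "
              f"{r.F:.2f}, p = {r.p:.4f}, eta_p^2 = {r.eta_p_sq:.3f} "
              f"({r.effect_label})")

    print("\nper time point (mean +/- SD cm; Bonferroni post hocs):")
    for ti, minutes in enumerate(TIME_POINTS_MIN):
        values = arr[:, :, ti]
        desc = "  ".join(
            f"{p} {values[:, pi].mean():.1f}+/-{values[:, pi].std(ddof=1):.1f}"
            for pi, p in enumerate(PROTOCOLS))
        omnibus = js.one_way_rm_anova(values)
        notes = []
        if omnibus.p < 0.05:
            for r in js.posthoc_pairwise(values, labels=PROTOCOLS):
                if r.p_adjusted < 0.05:
                    a, b = r.comparison
                    hi, lo = (a, b) if values[:, PROTOCOLS.index(a)].mean() \
                        >= values[:, PROTOCOLS.index(b)].mean() else (b, a)
                    notes.append(f"{hi} > {lo}")
        print(f"  {minutes} min: {desc}   F = {omnibus.F:.2f}, "
              f"p = {omnibus.p:.4f}   {'; '.join(notes)}")


if __name__ == "__main__":
    main()
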