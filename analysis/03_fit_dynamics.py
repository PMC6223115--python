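#!/usr/bin/env python
"""Re-estimate the drift/diffusion laws from the simulated cohorts.

Chain: pair 2-d transitions -> 32-spine volume bins (SD and mean of the
volume change) -> fast-SD law from the 10-min cohorts (30-spine bins,
drift fitted as zero) -> quadrature fast/slow decomposition -> anchored
slow-slope fit per group and pooled drift fit.  Writes results/estimation/.
"""

from pathlib import Path

import pandas as pd

from spinedyn import estimation as est
from spinedyn.model import KO_SPEC, WT_SPEC
from spinedyn.pipeline import anchored_intercept

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "estimation"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = est.read_trajectories(ROOT / "cohorts" / "trajectories.csv")
    fast_table = est.read_trajectories(ROOT / "cohorts" / "fast_trajectories.csv")

    fast_trans, _ = est.pair_transitions(fast_table)
    fast_moments = est.bin_and_moment(fast_trans, 30)
    fast = est.fit_fast(fast_moments)
    fast_moments.table.to_csv(OUT / "moments_fast.csv", index=False)
    print(f"fast SD law: {fast[0]:.3f} V^(2/3) + {fast[1]:.4f} "
          f"(generating: 0.115 V^(2/3) + 0.0051)")

    pooled = []
    for g, spec in (("WT", WT_SPEC), ("KO", KO_SPEC)):
        trans, elim = est.pair_transitions(table[table["group"] == g])
        pooled.append(trans)
        moments = est.bin_and_moment(trans, 32)
        moments.table.to_csv(OUT / f"moments_2d_{g}.csv", index=False)
        slow = est.decompose_slow(moments, fast)
        slope, ci = est.fit_anchored_slope(slow)
        fitted = spec.replace(
            slow_slope=slope,
            slow_intercept=anchored_intercept(slope, anchor_x=0.015 ** (2 / 3)),
            fast_slope=fast[0], fast_intercept=fast[1],
        )
        fitted.to_json(OUT / f"fitted_spec_{g}.json")
        print(f"{g}: slow slope {slope:.3f} (95% CI {ci[0]:.3f}-{ci[1]:.3f}; "
              f"generating {spec.slow_slope}); {len(elim)} eliminations in "
              f"{len(trans) + len(elim)} spine-session pairs")

    drift = est.fit_drift(est.bin_and_moment(pd.concat(pooled, ignore_index=True), 32))
    print(f"pooled drift: {drift[0]:.3f} V^(2/3) + {drift[1]:.4f} "
          f"-> zero crossing {est.drift_zero_crossing(drift):.3f} um^3 "
          f"(generating -0.12 / 0.029 -> 0.119)")
    print("note: recovered slopes sit ~10-20% below the generating values -- "
          "observation noise in the binning covariate and the domain "
          "boundaries attenuate the measured laws (see docs/methods.md)")
    print(f"artifacts -> {OUT}")


if __name__ == "__main__":
    main()
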