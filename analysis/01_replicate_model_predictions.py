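#!/usr/bin/env python
"""Headline model predictions from the published coefficient laws.

No data are needed: the drift and slow-fluctuation laws fully determine the
stationary volume distribution, its mean, the per-2-d elimination rates
(discrete-observation and first-passage functionals), the drift zero
crossing, and the anchored-fit intercepts.  Writes results/preset/.
"""

from pathlib import Path

from spinedyn.pipeline import run_replication_preset

OUT = Path(__file__).resolve().parent.parent / "results" / "preset"


def main() -> None:
    table = run_replication_preset(OUT, make_figures=False)
    print(table.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    print(f"\nWhat to look for: WT and KO share the drift law (zero crossing"
          f" ~0.12 um^3) but the steeper KO fluctuation slope roughly doubles"
          f" the predicted elimination rate while the stationary means stay"
          f" within ~0.003 um^3 of each other.")
    print(f"artifacts -> {OUT}")


if __name__ == "__main__":
    main()
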