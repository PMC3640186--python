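#!/usr/bin/env python
"""Planted-signature recovery across independent simulation seeds.

Repeats the whole study (simulate -> classify -> correlate -> signature
screen) for several seeds and tabulates how often the two planted focal
genera are recovered as cross-site land-use signatures with the correct
signs, and whether any null genus is ever falsely flagged.
"""

from pathlib import Path

import pandas as pd

from landuse16s.pipeline import run_study
from landuse16s.simulate import FOCAL_AOA, FOCAL_BRADY, SimulationConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

SEEDS = range(1, 9)


def main() -> None:
    rows = []
    for seed in SEEDS:
        cfg = SimulationConfig(seed=seed, n_samples_per_group=16, reads_per_sample=400)
        _, res = run_study(cfg)
        sig = res.signatures
        rows.append(
            {
                "seed": seed,
                "aoa_positive": FOCAL_AOA in sig.index
                and sig.loc[FOCAL_AOA, "direction"] == "positive",
                "brady_negative": FOCAL_BRADY in sig.index
                and sig.loc[FOCAL_BRADY, "direction"] == "negative",
                "false_signatures": ", ".join(
                    sorted(set(sig.index) - {FOCAL_AOA, FOCAL_BRADY})
                ),
            }
        )
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "signature_recovery.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    both = (table["aoa_positive"] & table["brady_negative"]).mean()
    clean = (table["false_signatures"] == "").mean()
    print(f"\nboth signatures recovered in {both:.0%} of seeds; "
          f"no false signatures in {clean:.0%} of seeds")


if __name__ == "__main__":
    main()
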