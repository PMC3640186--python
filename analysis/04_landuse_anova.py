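#!/usr/bin/env python
"""Land-use contrasts for the focal genera on the simulated study.

For each site, a one-way ANOVA compares arcsine-square-root-transformed
relative abundance between agricultural and non-agricultural plots for
the two focal genera; a two-way ANOVA tests land use x site effects.
Fold changes of plot-mean abundance are reported alongside.  Reads the
tables produced by 02_run_pipeline.py.
"""

from pathlib import Path

import pandas as pd

from landuse16s.simulate import FOCAL_AOA, FOCAL_BRADY
from landuse16s.stats import arcsine_sqrt, fold_change, one_way_anova, two_way_anova

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SIM_DIR = ROOT / "scratch" / "analysis" / "sim"


def main() -> None:
    relabund = pd.read_csv(RESULTS / "relabund_genus.tsv", sep="\t", index_col=0)
    sheet = pd.read_csv(SIM_DIR / "sample_sheet.tsv", sep="\t", index_col="sample")
    rows = []
    for genus in (FOCAL_AOA, FOCAL_BRADY):
        for site in sorted(sheet["site"].unique()):
            site_samples = sheet.index[sheet["site"] == site]
            groups = {
                lu: arcsine_sqrt(
                    relabund.loc[genus, [s for s in site_samples if sheet.loc[s, "land_use"] == lu]]
                    .to_numpy()
                )
                for lu in (1, 0)
            }
            f, (df1, df2), p = one_way_anova([groups[1], groups[0]])
            means = {
                lu: float(
                    relabund.loc[genus, [s for s in site_samples if sheet.loc[s, "land_use"] == lu]]
                    .mean()
                )
                for lu in (1, 0)
            }
            ratio, fold, direction = fold_change(means[1], means[0])
            rows.append(
                {"genus": genus, "site": site, "F": f, "df1": df1, "df2": df2, "p": p,
                 "mean_ag_pct": 100 * means[1], "mean_nonag_pct": 100 * means[0],
                 "fold": fold, "direction": "ag higher" if direction > 0 else "non-ag higher"}
            )
    oneway = pd.DataFrame(rows)
    oneway.to_csv(RESULTS / "anova_oneway.tsv", sep="\t", index=False)
    print("one-way ANOVA (arcsine-sqrt abundance ~ land use), per site:")
    print(oneway.round(4).to_string(index=False))

    twoway_rows = []
    for genus in (FOCAL_AOA, FOCAL_BRADY):
        vals = arcsine_sqrt(relabund.loc[genus, sheet.index].to_numpy())
        tab = two_way_anova(vals, sheet["land_use"].to_numpy(), sheet["site"].to_numpy())
        for eff in ("A", "B", "A:B"):
            twoway_rows.append(
                {"genus": genus,
                 "effect": {"A": "land_use", "B": "site", "A:B": "land_use:site"}[eff],
                 "F": tab.loc[eff, "F"], "p": tab.loc[eff, "p"]}
            )
    twoway = pd.DataFrame(twoway_rows)
    twoway.to_csv(RESULTS / "anova_twoway.tsv", sep="\t", index=False)
    print("\ntwo-way ANOVA (land use x site):")
    print(twoway.round(6).to_string(index=False))


if __name__ == "__main__":
    main()
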