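#!/usr/bin/env python
"""Shannon alpha diversity, quartile ranks, sector validation and the
TIN-interpolated diversity surface, per realm.

For each realm the samples are ranked by Shannon H (natural log) into
four near-equal quartile groups; the named geographic sectors are then
validated against their quartile-composition rules (e.g. water Central:
100% of samples in quartiles 1-2).  A piecewise-linear surface over the
Delaunay triangulation of the sampling points is exported as a grid.
"""

from pathlib import Path

import pandas as pd

from pelnet.diversity import (SEDIMENT_SECTOR_RULES, WATER_SECTOR_RULES,
                              alpha_diversity, assign_quartiles,
                              tin_interpolate, validate_sectors)
from pelnet.io_formats import read_abundance_table, read_metadata, to_relative
from pelnet.stats import kruskal_wallis

ROOT = Path(__file__).resolve().parent.parent / "results"
RULES = {"water": WATER_SECTOR_RULES, "sediment": SEDIMENT_SECTOR_RULES}


def main() -> None:
    table = read_abundance_table(ROOT / "data" / "abundance.tsv")
    meta = read_metadata(ROOT / "data" / "metadata.tsv")
    for realm in ("water", "sediment"):
        ids = meta.realm_samples(realm)
        rel = to_relative(table.select_samples(ids))
        h = alpha_diversity(rel)
        quart = assign_quartiles(h)
        sectors = meta.df.loc[ids, "sector"]
        pd.DataFrame({"shannon": h, "quartile": quart,
                      "sector": sectors}).to_csv(
            ROOT / f"alpha_{realm}.tsv", sep="\t", index_label="sample_id")

        surface = tin_interpolate(meta.df.loc[ids, "longitude"],
                                  meta.df.loc[ids, "latitude"], h,
                                  grid_res=100)
        surface.to_frame().to_csv(ROOT / f"tin_{realm}.tsv", sep="\t",
                                  index=False)

        report = validate_sectors(quart, sectors, RULES[realm])
        report.to_csv(ROOT / f"sector_rules_{realm}.tsv", sep="\t",
                      index=False)
        kw = kruskal_wallis([h[sectors == s].values
                             for s in sorted(sectors.unique())])
        print(f"{realm}: H in [{h.min():.2f}, {h.max():.2f}], "
              f"sector Kruskal-Wallis H = {kw.statistic:.2f} "
              f"(p = {kw.pvalue:.3g})")
        for _, row in report.iterrows():
            print(f"  {row.sector:>11}: {row.fraction:.0%} of samples in "
                  f"quartiles {{{row.quartiles}}} "
                  f"(rule >= {row.threshold:.0%}: "
                  f"{'pass' if row.passed else 'FAIL'})")


if __name__ == "__main__":
    main()
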