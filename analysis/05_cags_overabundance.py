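#!/usr/bin/env python
"""Co-abundance groups (CAGs), sector over-abundance profiles, and the
Wiggum-plot network export, per realm.

Taxa are clustered into 3 CAGs by Ward linkage on the Spearman
correlation distance between abundance profiles and named after their
most abundant member; per-sector enrichment is the meanArea/meanTot
over-abundance ratio with display tiers (<1 hidden, >=1.3 bold).  The
overall network (nodes sized by mean abundance, edges = significant
Kendall correlations at BH q <= 0.05) is written as GraphML.
"""

from pathlib import Path

import pandas as pd

from pelnet.cags import (build_wiggum, cluster_cags, kendall_matrix,
                         over_abundance)
from pelnet.io_formats import (read_abundance_table, read_metadata,
                               to_relative, write_network)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = read_abundance_table(ROOT / "data" / "abundance.tsv")
    meta = read_metadata(ROOT / "data" / "metadata.tsv")
    truth = pd.read_csv(ROOT / "data" / "ground_truth.tsv", sep="\t")
    blocks = truth[truth.kind == "block"].set_index("taxon")["value"]

    for realm in ("water", "sediment"):
        ids = meta.realm_samples(realm)
        rel = to_relative(table.select_samples(ids))
        sectors = meta.df.loc[ids, "sector"]

        corr = kendall_matrix(rel)
        part = cluster_cags(rel, k=3)
        from sklearn.metrics import adjusted_rand_score
        ari = adjusted_rand_score(blocks.loc[part.membership.index].values,
                                  part.membership.values)
        memb = pd.DataFrame({
            "cag": part.membership,
            "cag_name": [part.name_of(x) for x in part.membership.index]})
        memb.to_csv(ROOT / f"cags_{realm}.tsv", sep="\t", index_label="taxon")

        prof = over_abundance(rel, sectors)
        long = prof.ratios.stack().rename("over_abundance").reset_index()
        long.columns = ["sector", "taxon", "over_abundance"]
        long["tier"] = [prof.tiers.loc[s, x]
                        for s, x in zip(long.sector, long.taxon)]
        long.to_csv(ROOT / f"overabundance_{realm}.tsv", sep="\t",
                    index=False)

        net = build_wiggum(rel, part, corr, edge_q=0.05)
        write_network(net, ROOT / f"wiggum_{realm}.graphml")
        sizes = part.membership.value_counts().sort_index()
        print(f"{realm}: 3 CAGs of sizes {sizes.tolist()} "
              f"named {sorted(part.names.values())}; "
              f"ARI vs planted blocks = {ari:.2f} "
              f"(at survey-scale n the planted co-abundance signal is "
              f"largely below noise; see the recovery benchmark at n=100)")
        print(f"  significant Kendall edges (q <= 0.05): "
              f"{net.number_of_edges()}")
        bold = long[long.tier == "bold"]
        for sec in sorted(sectors.unique()):
            n_bold = (bold.sector == sec).sum()
            print(f"  {sec:>11}: {n_bold} orders over-abundant at >= 1.3")


if __name__ == "__main__":
    main()
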