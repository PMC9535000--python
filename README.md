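# pelnet

Sector-resolved diversity and co-occurrence network analysis for
coupled pelagic/benthic microbiome surveys.

Dense sampling of a small offshore area (here: 19 water-column and 25
surface-sediment samples over ~130 km² in the north-western Adriatic)
can resolve *within-area* microbiome structure: patches ("sectors") of
high and low alpha diversity, sector-specific community composition,
biochemical gradients in the sediment, and sector-specific interaction
networks.  `pelnet` implements that whole analysis chain as a tested
library with a CLI, plus a seeded synthetic-data generator so every
stage can be exercised and benchmarked without any sequencing download.

The chain, and the statistics at its core:

1. **Alpha-diversity sectors** — Shannon H = −Σ pᵢ ln pᵢ per sample;
   rank-based quartiles per realm; named sectors validated against
   quartile-composition rules (e.g. water Central: 100% of samples in
   quartiles 1–2); TIN (Delaunay + barycentric-linear) interpolation of
   H over the sampling area.
2. **Beta diversity** — unweighted UniFrac (unique branch length over
   union branch length), PCoA, one-way PERMANOVA
   (pseudo-F = (SS_A/(a−1))/(SS_W/(N−a)), 999 label permutations),
   and an ordination-vs-environment screen flagging R² > 0.25.
3. **Sediment biochemistry** — carbon equivalents
   BPC = 0.49·PRT + 0.40·CHO + 0.75·LIP (mgC/g), total phytopigments
   PIG = Chl-a + phaeopigments; Mantel tests (Spearman, 9999
   permutations) of UniFrac distances against per-component Euclidean
   distances.
4. **Co-abundance groups (CAGs)** — Kendall tau-b association, Ward
   clustering on the Spearman correlation distance between taxa
   profiles, CAGs named after their most abundant order; per-sector
   over-abundance O = meanArea/meanTot with Wiggum display tiers
   (hidden < 1, bold ≥ 1.3).
5. **Sector networks** — compositional (CLR) association networks with
   a permutation/FDR edge gate and order-1 partial-correlation pruning;
   summarized by hubs (joint degree/betweenness/closeness quantile),
   Louvain modules and modularity, total connectivity (edges/node), and
   Herren–McMahon negative:positive cohesion.

See `docs/methods.md` for the models, defaults and limitations, and the
`analysis/` scripts for the narrative pipeline over the synthetic
survey.

## Worked example

Run the numbered analysis scripts from the repository root (each writes
tables under `results/`):

```bash
python analysis/01_simulate.py
python analysis/02_alpha_sectors.py
python analysis/03_beta_diversity.py
python analysis/04_biochem_mantel.py
```

`01_simulate.py` generates the study-scale dataset (seed 1):

```
wrote 60 taxa x 44 samples to results/data
  reads/sample: mean 12651, sd 3601
  water samples: 19, sediment: 25
```

`02_alpha_sectors.py` ranks samples into Shannon quartiles and checks
the sector rules:

```
water: H in [2.22, 2.97], sector Kruskal-Wallis H = 13.12 (p = 0.00142)
        South: 83% of samples in quartiles {34} (rule >= 70%: pass)
      Central: 100% of samples in quartiles {12} (rule >= 100%: pass)
        North: 67% of samples in quartiles {34} (rule >= 65%: pass)
sediment: H in [0.96, 2.84], sector Kruskal-Wallis H = 9.26 (p = 0.00975)
        South: 89% of samples in quartiles {12} (rule >= 80%: pass)
   North-East: 88% of samples in quartiles {34} (rule >= 90%: FAIL)
   North-West: 88% of samples in quartiles {234} (rule >= 80%: pass)
```

Both realms separate into the planted low-diversity sector (water
Central, sediment South) and high-diversity sectors; the strict 90%
North-East rule misses by one sample at this seed — on generated data
the rules hold only as far as the planted diversity geography beats
sampling noise, whereas the original survey *defined* its sectors from
the observed map.

`03_beta_diversity.py` tests sector segregation and the offshore
gradient:

```
water: sector PERMANOVA pseudo-F = 26.51, R^2 = 0.77, p = 0.001 (999 permutations)
  MDS2 ~ depth_m: R = -0.74, R^2 = 0.54 (p = 0.00032)
sediment: sector PERMANOVA pseudo-F = 50.37, R^2 = 0.82, p = 0.001 (999 permutations)
  MDS1 ~ depth_m: R = -0.76, R^2 = 0.57 (p = 1.2e-05)
```

Sectors segregate at the permutation floor (p = 0.001 at 999
permutations) and the planted inshore–offshore gradient is flagged by
the R² > 0.25 screen.  `04_biochem_mantel.py` links community structure
to the sediment biochemistry:

```
   BPC: 2.84 +/- 0.67 (range 1.70-4.19)
Mantel (Spearman, 9999 permutations) vs UniFrac distances:
   CHO: r = 0.4547, p = 0.0001
   PRT: r = 0.5422, p = 0.0001
   LIP: r = 0.3932, p = 0.0003
   PIG: r = 0.6085, p = 0.0001
```

All four biochemical distance matrices correlate significantly with the
community UniFrac distances, as expected when composition and
biochemistry share the sector structure.  `05_cags_overabundance.py`
and `06_sector_networks.py` complete the chain (CAGs, over-abundance
tiers, per-sector networks with N:P cohesion, modules, connectivity and
hubs); at the survey's per-sector sample sizes the permutation/FDR edge
gate is stringent and sparse or empty sector networks are an expected,
honest outcome.

The same stages are available as a CLI (`pelnet simulate`, `pelnet
alpha`, `pelnet beta`, `pelnet cags`, `pelnet networks`, `pelnet
biochem`, `pelnet compare`, `pelnet run`) and as one orchestrated,
cache-aware pipeline (`pelnet.pipeline.run_pipeline`).

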