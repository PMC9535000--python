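# Methods

`pelnet` analyzes coupled pelagic/benthic microbiome surveys in which a
small offshore area is sampled densely enough to resolve within-area
("sector") structure: alpha-diversity mapping, phylogenetic beta
diversity, biochemical covariates of the sediment, co-abundance groups,
and per-sector co-occurrence networks.  This note records the models,
the numerical choices, and what the synthetic benchmark does and does
not establish.

## Sediment biochemistry

Protein (PRT), carbohydrate (CHO) and lipid (LIP) concentrations (mg/g
dry sediment) are converted to carbon equivalents with 0.49, 0.40 and
0.75 mgC/mg respectively; their sum is biopolymeric carbon (BPC,
mgC/g), a standard proxy for the trophic resources available to benthic
communities.  Total phytopigments (PIG, µg/g) are chlorophyll-a plus
phaeopigments.  Both derived columns are recomputed on every load, so
the identities hold exactly by construction.  BPC is linear in its
inputs; consequently the BPC of mean concentrations equals the mean of
per-sample BPC values, which is what the acceptance computation relies
on.

## Alpha diversity and sectors

Shannon diversity is computed in nats (H = −Σ p_i ln p_i) on per-sample
relative abundances.  Natural log is the convention of the R `vegan`
toolchain; the quartile machinery downstream is invariant to the log
base in any case.  No rarefaction is applied by default — a seeded
`rarefy(depth)` based on multivariate-hypergeometric subsampling is
available to make the choice explicit and switchable.

Within each realm, samples are ranked by H; quartile ranks 1–4 are
assigned by position (`rank·4 // n + 1`), giving group sizes that differ
by at most one (5, 5, 5, 4 at n = 19).  Ties in H are broken by
lexicographic sample id so the assignment is deterministic.  Sectors
are *user input* (polygon assignments in the metadata), validated
against quartile-composition rules such as "water Central: 100% of
samples in quartiles 1–2" — the package deliberately does not
auto-discover sectors, because the sectors of interest were drawn by
inspecting the interpolated diversity map, and automating that would
invent a method with no definition.  The North-West sediment rule
("between the 2nd and 4th quartiles") is ambiguous; the inclusive
reading {2, 3, 4} is the default and the rule set is configurable.

The diversity surface is a Triangulated Irregular Network: Delaunay
triangulation of the sample coordinates with barycentric-linear
interpolation inside each triangle (`scipy.spatial` /
`LinearNDInterpolator`), NaN outside the convex hull.  Linear
interpolation is exact at the vertices, bounded by the data range, and
exact on affine functions of (lon, lat) — all three are tested.
Coordinates are treated as planar: over a ~130 km² extent the
projection error is negligible and a geodesy dependency is avoided.

## Beta diversity

**Unweighted UniFrac.**  Presence is strictly abundance > 0 (no
detection floor).  For each sample pair, the distance is the branch
length subtending exactly one community's taxa divided by the branch
length subtending either (the classical union-normalized definition —
not the whole-tree normalization).  The implementation vectorizes over
a branch × taxon incidence matrix; a naive per-branch enumeration
oracle and scikit-bio's implementation agree with it exactly in tests.
Unweighted UniFrac is treated as a semimetric: symmetry and zero
diagonal are asserted, triangle-inequality violations are possible and
are logged, not raised.

**PCoA.**  Gower double-centering of −D²/2, symmetric
eigendecomposition, axes from positive eigenvalues only; variance
fractions are computed over the positive spectrum and negative
eigenvalues (non-Euclidean input) are reported and logged.  Sign
convention: the largest-magnitude coordinate on each axis is positive,
making runs reproducible.

**PERMANOVA.**  One-way, direct-from-distances: SS_total from all
pairs, SS_within per group, pseudo-F = (SS_A/(a−1))/(SS_W/(N−a)).
Labels are permuted freely (no strata; the design is single-factor),
default 999 permutations, and p-values carry the +1 correction, so the
smallest attainable p at 999 permutations is 0.001.  Note that the
floor is only *reliably* attained when the number of distinct label
splits is large relative to the permutation count; at 2×6 a random
permutation re-draws the observed split with probability 2/924 and p =
0.002–0.003 is common even for perfectly separated clusters.

**Mantel.**  Correlation (Spearman by default) of the vectorized upper
triangles; p by simultaneous row/column permutation of the second
matrix, default 9999 permutations, one-sided (greater) to match the
usual usage for "does community distance increase with environmental
distance".

**Environment screen.**  Each ordination axis is correlated (Pearson
and Spearman, both reported since the field's "R" is often ambiguous)
with each covariate; the simple-regression R² (= squared Pearson r)
is flagged when it exceeds 0.25, the conventional "biologically
relevant" cut used for such screens.  Constant covariates yield flagged
NaNs, never an exception.

## Co-abundance groups and over-abundance

Taxon association for the CAG stage is Kendall's tau-b (tie-corrected)
with asymptotic p-values and Benjamini–Hochberg q-values over the upper
triangle.  Clustering operates on the Spearman correlation distance
d = 1 − ρ between taxa abundance profiles (the plain 1 − ρ reading, not
√(1−ρ) or 1 − |ρ|; configurable), agglomerated by Ward linkage via
scipy.  Two cluster inputs are supported — taxa abundance profiles
(default) or the Kendall matrix rows — because the source protocol can
be read either way.  The cut level k defaults to the best mean
silhouette over k ∈ 2..6, but analyses in this repository fix k = 3 to
mirror the three-CAG structure the study design plants.  Each CAG is
named after its most abundant member; `Unassigned-*` bins (created by
the order-level collapse when a taxon lacks an assignment, pooled per
parent clade) stay in the clustering but never lend their name.

Over-abundance of taxon j in sector s is O_sj = (mean relative
abundance in s) / (mean over all samples).  With sector weights
w_s = n_s/N this satisfies Σ_s w_s·O_sj = 1 exactly, which is asserted
to 1e-12.  Display tiers follow the Wiggum-plot convention: hidden
below 1, normal in [1, 1.3), bold at ≥ 1.3.  Wiggum graphs carry mean
abundance, CAG membership and (for sector views) over-abundance and
tier on the nodes; edges are Kendall correlations at q ≤ 0.05 (the
global FDR level; the source protocol states no explicit edge
threshold), signed positive/negative.

## Sector co-occurrence networks

Per-sector networks are inferred compositionally: relative abundances
are CLR-transformed (pseudocount = half the smallest positive value;
the edge set is thereby exactly invariant to per-sample depth),
pairwise Pearson associations are tested against a permutation null
(each taxon's values shuffled independently, default 1000 seeded
permutations) with BH control at q ≤ 0.05, and an order-1
partial-correlation prune drops edges whose association vanishes
(|partial r| < 0.1) conditioning on any single other taxon.  This is a
deliberately simple, fully owned conditional-independence filter in the
local-to-global spirit; it is not a reimplementation of any published
inference tool, and the graph provenance attributes say exactly what
produced each network.

Summaries: **hubs** are nodes strictly above the 0.9 quantile of
degree, betweenness and closeness simultaneously, computed on the
unsigned largest connected component (betweenness and closeness are
ill-defined across components); when symmetry leaves no strict hub the
best summed-rank node is returned flagged degenerate, ties broken by
node id.  **Modules and modularity** come from seeded Louvain on the
unsigned graph (singletons count as modules; an edgeless graph reports
Q = 0 with a flag).  **Total connectivity** is edges per node — the
table also emits density and mean degree because the bare phrase is
ambiguous.  **Cohesion** follows the Herren–McMahon construction: the
taxon–taxon Pearson correlation matrix is corrected by subtracting its
expectation under a taxon-shuffle null, a taxon's positive (negative)
connectedness is the mean of its positive (negative) corrected
correlations, per-sample cohesion is the abundance-weighted sum of
connectedness, and the sector-level N:P ratio is |mean negative
cohesion| / mean positive cohesion (flagged infinite when the positive
side is exactly zero).  One deliberate refinement: each null dataset is
re-closed (renormalized per sample) after shuffling, so the null
carries the same compositional closure bias (≈ −1/(p−1)) as the
observed correlations; without re-closure the corrected correlations of
a structureless dataset are systematically negative and cohesion is not
centered at zero.  Cohesion is computed from the correlation structure
directly (not from the inferred edge set) by default, with the
alternative available.

At the survey's per-sector sample sizes (6–9), the permutation/FDR gate
has essentially no power with 60 taxa (1770 pairs), and sparse or empty
sector networks are the honest outcome; the network-recovery benchmarks
therefore use larger per-sector n (below).

## Synthetic data

The generator is logistic-normal-multinomial: per sample, a latent
Gaussian log-abundance vector is built from (i) a deterministic
rank-abundance baseline spanning ~9 natural-log units with ranks
assigned at random (order-level communities span several decades, so
many orders are genuinely absent from any given sample at realistic
depths), (ii) block-structured latent noise (shared/block/idiosyncratic
factors giving within-block correlation ρ_within, between-block
ρ_between — the plantable CAG structure), (iii) per-sector log-fold
shifts on designated indicator taxa that are rare at baseline (−8) and
boosted (+7) inside their sector so the shift also flips
presence/absence, which is what unweighted UniFrac can see, (iv) a
continuous inshore–offshore gradient (10 taxa, 10-log-unit span along
latitude, alternating direction) emulating the strong depth/distance
structure of coastal surveys, (iv-b) per-sector dominance scaling (water Central 1.6, sediment South
1.8, sediment North-West 1.2) that multiplies the latent log-abundances
and thereby lowers Shannon diversity, planting the study's
low/high-diversity sector geography, and (v) per-sector hub factors: the hub
taxon's latent is dominated (90% variance share) by a factor its
satellite taxa load on weakly (±0.75, alternating sign so the factor
stays out of the per-sample CLR mean and plants both positive and
negative edges).  Softmax gives the composition; counts are multinomial
at a lognormal depth (mean 12,485, sd 3,235 reads).  Coordinates are
drawn inside axis-aligned sector polygons spanning the survey bounding
box (latitude thirds for water; sediment splits the upper two thirds at
the longitude midline); water depth increases linearly offshore.
Sediment biochemistry is sector means (northern sectors richer in every
component, overall levels near the measured means) plus Gaussian noise.
A single seed feeds per-component substreams (`SeedSequence.spawn`), so
every output is bitwise-reproducible.

What the benchmark does **not** emulate: read-level error, chimeras,
taxonomic mis-assignment, spatial autocorrelation beyond the sector
polygons and the single latitude gradient, non-Gaussian latent tails,
or realistic phylogenetic signal in the abundances (the tree is a
neutral coalescent independent of the planted blocks).  Passing
recovery tests therefore shows the estimators recover their own
generating model at survey scale — not that the field data would yield
the same networks.  Note also that because the survey this emulates
*defined* its sectors from the observed diversity map, its
quartile-composition rules pass by construction on the original data;
on generated data, where sectors are planted a priori, the same rules
pass only to the extent the planted diversity geography dominates
sampling noise, and the sector-validation report states each fraction
honestly.

**Problem sizes for recovery experiments.**  The CAG-recovery and
hub-recovery experiments isolate one planted structure at a time
(gradient/effects/hubs disabled as appropriate), use a shallower 4-log
rank-abundance span and 50,000-read depths so the planted covariance
rather than multinomial noise is what is tested, and use 100 samples
(CAG ARI), 40 samples per sector × 100 replicates (hub recovery), and
the study-scale default design (19 + 25 samples) for the
over-abundance, PERMANOVA and gradient-screen checks.

## Numerical conventions

- Tabular output is serialized with 12 significant digits; round trips
  are value-stable.
- Permutation p-values always use the (1 + hits)/(1 + n_perm)
  correction; seeds are explicit everywhere randomness exists.
- Kendall/Spearman undefined cases (constant taxa) are flagged, carried
  as NaN, and excluded from BH — never silently zeroed.
- Pipeline stages cache on a content hash of their parameters and
  inputs; reruns with an unchanged config are byte-identical and cached
  stages are not rewritten.

## Known limitations

- The conditional-independence filter is order-1 only; higher-order
  redundancy survives pruning.
- Hubs defined by joint centrality quantiles are sensitive to the edge
  set; in near-empty networks the degenerate fallback is reported
  rather than a meaningful hub.
- PERMANOVA assumes exchangeability under the null; with strong
  dispersion differences between groups the test conflates location and
  dispersion, as it does everywhere.
- The BIOM reader supports only the minimal dense JSON variant.
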