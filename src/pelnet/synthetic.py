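"""Seeded synthetic datasets with the statistical structure the pipeline
assumes: block-correlated compositions (plantable co-abundance groups),
spatial sectors with over-abundance shifts, planted network hubs, and
sediment biochemistry tied to the sectors.

The generative model is logistic-normal-multinomial: each sample has a
latent Gaussian log-abundance vector with block covariance (within-block
correlation ``rho_within`` > between-block ``rho_between``), shifted per
sector for the planted effect taxa; softmax gives the composition and a
multinomial draw at a lognormal sequencing depth gives counts.  Hubs are
planted per sector by a shared latent factor loading on the hub and a
set of neighbor taxa, so the hub correlates with every neighbor more
strongly than neighbors do with each other.

The default design mirrors the study layout this pipeline targets: 19
water and 25 sediment samples on a ~130 km^2 offshore grid (latitude
44.0687–44.2524, longitude 12.7229–12.9065), ~12,500 reads per sample,
and three sectors per realm (water North/Central/South by latitude
thirds; sediment South plus North-West/North-East splitting the upper
area by longitude).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import skbio

from .errors import ValidationError
from .io_formats import AbundanceTable, BiochemTable, SampleMetadata

#: study-area bounding box (degrees)
LAT_MIN, LAT_MAX = 44.0686667, 44.2524444
LON_MIN, LON_MAX = 12.72288889, 12.90647222

# allocation order: round-robin over these tuples, so the first-listed
# sector receives the extra sample when counts do not divide evenly
WATER_SECTORS = ("Central", "South", "North")
SEDIMENT_SECTORS = ("South", "North-West", "North-East")

#: per-sector biochemistry means (sediment): the two northern sectors are
#: richer in every component, matching the spatial organic-matter gradient
#: the design emulates; overall levels sit near the measured means
#: (PRT 4.18, CHO 0.66, LIP 0.74 mg/g; CHLA 1.22, PHEO 14.66 ug/g).
BIOCHEM_SECTOR_MEANS = {
    "PRT": {"South": 3.2, "North-West": 4.6, "North-East": 4.8},
    "CHO": {"South": 0.45, "North-West": 0.75, "North-East": 0.78},
    "LIP": {"South": 0.50, "North-West": 0.85, "North-East": 0.90},
    "CHLA": {"South": 0.8, "North-West": 1.4, "North-East": 1.5},
    "PHEO": {"South": 11.0, "North-West": 16.0, "North-East": 17.0},
}
BIOCHEM_NOISE_SD = {"PRT": 0.6, "CHO": 0.12, "LIP": 0.15,
                    "CHLA": 0.3, "PHEO": 2.0}


@dataclass
class SyntheticDesign:
    """Knobs of the generator; the defaults are the study conditions."""

    n_water: int = 19
    n_sediment: int = 25
    n_taxa: int = 60
    n_blocks: int = 3
    rho_within: float = 0.8
    rho_between: float = 0.0
    sector_effect_size: float = 7.0      # log-fold shift of planted taxa
    n_effect_taxa: int = 5               # planted taxa per sector per realm
    effect_taxa_baseline: float = -8.0   # baseline log-abundance of planted
                                         # taxa: rare outside their sector, so
                                         # the shift also flips presence
    n_gradient_taxa: int = 10            # taxa tracking the inshore-offshore
    gradient_strength: float = 10.0      # gradient: log-fold span over the
                                         # full latitude range, alternating sign
    gradient_taxa_baseline: float = -4.5
    n_hub_satellites: int = 12           # a planted hub dominates a shared
    hub_factor_share: float = 0.9        # factor (this share of its variance)
    satellite_loading: float = 0.75      # that its satellites load on weakly,
                                         # so hub edges are detectable while
                                         # satellite-satellite ones are not
    latent_sd: float = 1.0
    rank_log_span: float = 9.0           # span of the baseline rank-abundance
                                         # curve in log units: order abundances
                                         # range over ~4 decades, so many
                                         # orders are absent from any given
                                         # sample at realistic read depths
    depth_mean: float = 12485.0          # reads per sample
    depth_sd: float = 3235.0
    plant_hubs: bool = True
    # the study geography has one clearly low-diversity sector per realm
    # (water Central, sediment South) and a mid-diversity sediment
    # North-West; scaling those samples' latent log-abundances increases
    # dominance and lowers Shannon H
    sector_dominance: tuple = ((("water", "Central"), 1.6),
                               (("sediment", "South"), 1.8),
                               (("sediment", "North-West"), 1.2))

    def __post_init__(self):
        if not (0.0 <= self.rho_between <= self.rho_within < 1.0):
            raise ValidationError("need 0 <= rho_between <= rho_within < 1")
        if self.n_taxa < 2 * self.n_blocks:
            raise ValidationError("too few taxa for the block structure")
        n_hubs = len(WATER_SECTORS) + len(SEDIMENT_SECTORS)
        if self.plant_hubs and n_hubs > self.n_taxa:
            raise ValidationError("more hubs than taxa")
        if self.plant_hubs and self.n_hub_satellites >= self.n_taxa:
            raise ValidationError("more hub satellites than taxa")


@dataclass
class GroundTruth:
    """Planted structure, for recovery tests."""

    blocks: pd.Series                       # taxon -> block id (1..n_blocks)
    sector_effects: pd.DataFrame            # realm, sector, taxon, log_fold
    hubs: dict                              # (realm, sector) -> dict(hub=..., satellites=[...])
    gradient_taxa: list                     # taxa tracking the latitude gradient
    biochem_sector_means: dict
    seed: int


def _water_sector(lat: float) -> str:
    third = (LAT_MAX - LAT_MIN) / 3.0
    if lat < LAT_MIN + third:
        return "South"
    if lat < LAT_MIN + 2 * third:
        return "Central"
    return "North"


def _sediment_sector(lon: float, lat: float) -> str:
    third = (LAT_MAX - LAT_MIN) / 3.0
    if lat < LAT_MIN + third:
        return "South"
    return "North-West" if lon < (LON_MIN + LON_MAX) / 2.0 else "North-East"


def sector_of(realm: str, lon: float, lat: float) -> str:
    """Axis-aligned sector polygons: latitude thirds for water; for
    sediment the upper two thirds split by the longitude midline."""
    return _water_sector(lat) if realm == "water" else _sediment_sector(lon, lat)


def _sample_point_in_sector(realm: str, sector: str, rng) -> tuple:
    for _ in range(10000):
        lon = rng.uniform(LON_MIN, LON_MAX)
        lat = rng.uniform(LAT_MIN, LAT_MAX)
        if sector_of(realm, lon, lat) == sector:
            return lon, lat
    raise ValidationError(f"could not sample a point in sector {sector!r}")


def random_coalescent_tree(taxon_ids, rng) -> skbio.TreeNode:
    """Random coalescent over the taxa: pairs of lineages merge at
    exponential waiting times with rate C(k, 2); branch lengths are the
    inter-coalescence intervals."""
    lineages = []
    for name in taxon_ids:
        node = skbio.TreeNode(name=str(name), length=0.0)
        lineages.append([node, 0.0])      # node, height at its top
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (a, ha), (b, hb) = lineages[i], lineages[j]
        a.length = t - ha
        b.length = t - hb
        parent = skbio.TreeNode(children=[a, b], length=0.0)
        lineages[j:j + 1] = []
        lineages[i] = [parent, t]
    root = lineages[0][0]
    root.length = None
    return root


def _block_latents(n_samples: int, blocks: np.ndarray, design: SyntheticDesign,
                   rng):
    """Latent (taxa x samples) Gaussians with the block correlation
    structure, built from shared/block/idiosyncratic factors.  Also
    returns the block factors so hubs can be planted on them."""
    d = design
    n_taxa = len(blocks)
    g = rng.standard_normal(n_samples)                      # global factor
    bfac = rng.standard_normal((d.n_blocks, n_samples))     # block factors
    eps = rng.standard_normal((n_taxa, n_samples))
    z = (np.sqrt(d.rho_between) * g[None, :]
         + np.sqrt(d.rho_within - d.rho_between) * bfac[blocks - 1, :]
         + np.sqrt(1.0 - d.rho_within) * eps)
    return d.latent_sd * z, bfac


def generate_dataset(design: Optional[SyntheticDesign] = None, seed: int = 0):
    """Generate (AbundanceTable, SampleMetadata, tree, BiochemTable,
    GroundTruth), bitwise-reproducible for a fixed (design, seed)."""
    d = design if design is not None else SyntheticDesign()
    ss = np.random.SeedSequence(seed)
    r_coord, r_latent, r_counts, r_tree, r_biochem, r_struct = (
        np.random.default_rng(c) for c in ss.spawn(6))

    taxa = [f"Order{i + 1:03d}" for i in range(d.n_taxa)]
    blocks = np.asarray([(i % d.n_blocks) + 1 for i in range(d.n_taxa)])
    # deterministic rank-abundance curve, ranks assigned at random
    base = -np.linspace(0.0, d.rank_log_span, d.n_taxa)[
        np.argsort(r_struct.permutation(d.n_taxa))]

    # planted sector shifts: disjoint taxon sets per (realm, sector)
    order = r_struct.permutation(d.n_taxa)
    effect_rows = []
    shift = {}
    cursor = 0
    plant_effects = d.sector_effect_size != 0 and d.n_effect_taxa > 0
    for realm, sectors in (("water", WATER_SECTORS),
                           ("sediment", SEDIMENT_SECTORS)):
        for sec in sectors:
            vec = np.zeros(d.n_taxa)
            if plant_effects:
                chosen = order[cursor:cursor + d.n_effect_taxa]
                cursor = (cursor + d.n_effect_taxa) % d.n_taxa
                vec[chosen] = d.sector_effect_size
                base[chosen] = d.effect_taxa_baseline
            shift[(realm, sec)] = vec
            if plant_effects:
                for c in chosen:
                    effect_rows.append((realm, sec, taxa[c],
                                        d.sector_effect_size))
    sector_effects = pd.DataFrame(effect_rows, columns=["realm", "sector",
                                                        "taxon", "log_fold"])

    # continuous latitude gradient: distinct taxa turn over along the
    # inshore-offshore axis, alternating direction
    grad_idx = order[::-1][:d.n_gradient_taxa]
    grad_dir = np.zeros(d.n_taxa)
    grad_dir[grad_idx] = [(-1.0) ** i for i in range(len(grad_idx))]
    base[grad_idx] = d.gradient_taxa_baseline
    gradient_taxa = [taxa[i] for i in grad_idx]

    # planted hubs: one per (realm, sector), disjoint from each other and
    # from the planted effect/gradient taxa; satellites are any other taxa
    hubs = {}
    if d.plant_hubs:
        used = set(order[:cursor]) | set(order[::-1][:d.n_gradient_taxa])
        pool = [i for i in r_struct.permutation(d.n_taxa) if i not in used]
        for realm, sectors in (("water", WATER_SECTORS),
                               ("sediment", SEDIMENT_SECTORS)):
            for sec in sectors:
                hub = pool.pop()
                sats = [i for i in r_struct.permutation(d.n_taxa)
                        if i != hub][:d.n_hub_satellites]
                hubs[(realm, sec)] = {"hub": taxa[hub],
                                      "satellites": [taxa[i] for i in sats],
                                      "_idx": (hub, sats)}
                base[hub] = max(base[hub], -1.0)  # hubs are prevalent taxa

    # samples: round-robin sector allocation, coordinates inside polygons
    sample_ids, realms, lons, lats, sectors = [], [], [], [], []
    for realm, n_total, secs, prefix in (("water", d.n_water, WATER_SECTORS, "W"),
                                         ("sediment", d.n_sediment,
                                          SEDIMENT_SECTORS, "S")):
        for i in range(n_total):
            sec = secs[i % len(secs)]
            lon, lat = _sample_point_in_sector(realm, sec, r_coord)
            sample_ids.append(f"{prefix}{i + 1:02d}")
            realms.append(realm)
            lons.append(lon)
            lats.append(lat)
            sectors.append(sec)
    n_samples = len(sample_ids)

    # depth increases offshore (northwards) — the planted environmental
    # gradient the ordination screen should recover
    lat_frac = (np.asarray(lats) - LAT_MIN) / (LAT_MAX - LAT_MIN)
    depth_m = 10.0 + 30.0 * lat_frac + r_coord.normal(0, 1.5, n_samples)
    depth_m = np.clip(depth_m, 2.0, None)
    dist_km = 13.5 + 12.0 * lat_frac + r_coord.normal(0, 0.5, n_samples)

    # latent compositions
    Z, bfac = _block_latents(n_samples, blocks, d, r_latent)
    if d.plant_hubs:
        # within its sector: the hub taxon's latent is mostly a shared
        # factor h that every satellite also (weakly) loads on, so the
        # hub correlates detectably with each satellite while
        # satellite-satellite correlations stay sub-threshold
        for (realm, sec), info in hubs.items():
            hub, sats = info["_idx"]
            cols = [j for j in range(n_samples)
                    if realms[j] == realm and sectors[j] == sec]
            h = r_latent.standard_normal(len(cols))
            e = r_latent.standard_normal(len(cols))
            Z[hub, cols] = d.latent_sd * (
                np.sqrt(d.hub_factor_share) * h
                + np.sqrt(1.0 - d.hub_factor_share) * e)
            for si, s in enumerate(sats):
                # alternating signs keep the factor out of the sample mean
                # (CLR-safe) and plant both positive and negative edges
                Z[s, cols] += (d.latent_sd * d.satellite_loading
                               * ((-1.0) ** si) * h)
    Z += base[:, None]
    for j in range(n_samples):
        Z[:, j] += shift[(realms[j], sectors[j])]
        Z[:, j] += d.gradient_strength * (lat_frac[j] - 0.5) * grad_dir
        scale = dict(d.sector_dominance).get((realms[j], sectors[j]))
        if scale:
            Z[:, j] *= scale
    P = np.exp(Z - Z.max(axis=0, keepdims=True))
    P /= P.sum(axis=0, keepdims=True)

    # sequencing depths (lognormal with the target mean/sd) and counts
    cv2 = (d.depth_sd / d.depth_mean) ** 2
    sigma2 = np.log1p(cv2)
    mu = np.log(d.depth_mean) - sigma2 / 2.0
    depths = np.maximum(
        r_counts.lognormal(mu, np.sqrt(sigma2), n_samples).astype(int), 100)
    counts = np.zeros((d.n_taxa, n_samples))
    for j in range(n_samples):
        counts[:, j] = r_counts.multinomial(depths[j], P[:, j])

    table = AbundanceTable(taxa, sample_ids, counts, is_relative=False,
                           realm=dict(zip(sample_ids, realms)))
    meta = SampleMetadata(pd.DataFrame({
        "realm": realms, "longitude": lons, "latitude": lats,
        "depth_m": depth_m, "distance_from_coast_km": dist_km,
        "sector": sectors}, index=pd.Index(sample_ids, name="sample_id")))

    tree = random_coalescent_tree(taxa, r_tree)

    sed_ids = [s for s, r in zip(sample_ids, realms) if r == "sediment"]
    sed_secs = [sec for sec, r in zip(sectors, realms) if r == "sediment"]
    bio = {}
    for comp, means in BIOCHEM_SECTOR_MEANS.items():
        vals = np.array([means[sec] for sec in sed_secs])
        vals = vals + r_biochem.normal(0, BIOCHEM_NOISE_SD[comp], len(sed_ids))
        bio[comp] = np.clip(vals, 0.01, None)
    biochem_table = BiochemTable(pd.DataFrame(
        bio, index=pd.Index(sed_ids, name="sample_id")))

    truth = GroundTruth(
        blocks=pd.Series(blocks, index=taxa, name="block"),
        sector_effects=sector_effects,
        hubs={k: {"hub": v["hub"], "satellites": v["satellites"]}
              for k, v in hubs.items()},
        gradient_taxa=gradient_taxa,
        biochem_sector_means=BIOCHEM_SECTOR_MEANS,
        seed=seed)
    return table, meta, tree, biochem_table, truth


def planted_truth_report(truth: GroundTruth) -> pd.DataFrame:
    """Machine-readable table of every planted feature (block
    memberships, sector shifts, hubs), consumed by recovery tests."""
    rows = [("block", "", "", taxon, str(block))
            for taxon, block in truth.blocks.items()]
    for _, r in truth.sector_effects.iterrows():
        rows.append(("sector_effect", r["realm"], r["sector"], r["taxon"],
                     f"{r['log_fold']:g}"))
    for (realm, sec), info in truth.hubs.items():
        rows.append(("hub", realm, sec, info["hub"], "hub"))
        for v in info["satellites"]:
            rows.append(("hub", realm, sec, v, "satellite"))
    for taxon in truth.gradient_taxa:
        rows.append(("gradient", "", "", taxon, "gradient"))
    return pd.DataFrame(rows, columns=["kind", "realm", "sector", "taxon",
                                       "value"])
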