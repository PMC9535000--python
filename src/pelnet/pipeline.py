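"""End-to-end orchestration: simulate (or load) -> alpha/sectors ->
beta diversity -> biochemistry/Mantel -> CAGs/over-abundance -> sector
networks, with a provenance manifest and content-hash stage caching.

Water and sediment are processed as independent branches sharing code;
a small cross-realm report classifies orders as shared or
realm-exclusive (mean relative-abundance ratio above 10:1).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beta import axis_environment_screen, mantel, pcoa, permanova, unweighted_unifrac
from .cags import build_wiggum, cluster_cags, kendall_matrix, over_abundance
from .cooccurrence import infer_network, summarize_sector
from .diversity import (SEDIMENT_SECTOR_RULES, WATER_SECTOR_RULES,
                        alpha_diversity, assign_quartiles, tin_interpolate,
                        validate_sectors)
from .errors import ValidationError
from .io_formats import (AbundanceTable, read_abundance_table, read_biochem,
                         read_metadata, read_newick, to_relative,
                         write_abundance_table, write_biochem, write_metadata,
                         write_network, write_newick)
from .synthetic import SyntheticDesign, generate_dataset, planted_truth_report

log = logging.getLogger(__name__)

EXCLUSIVITY_RATIO = 10.0


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults are the study conditions."""

    seed: int = 0
    simulate: bool = True
    design: SyntheticDesign = field(default_factory=SyntheticDesign)
    table_path: Optional[str] = None
    metadata_path: Optional[str] = None
    tree_path: Optional[str] = None
    biochem_path: Optional[str] = None
    cag_k: Optional[int] = 3
    edge_q: float = 0.05
    hub_quantile: float = 0.90
    r2_threshold: float = 0.25
    n_perm_permanova: int = 999
    n_perm_mantel: int = 9999
    n_perm_network: int = 1000
    n_null_cohesion: int = 200
    grid_res: int = 50

    def __post_init__(self):
        for name, lo, hi in (("edge_q", 0, 1), ("hub_quantile", 0, 1),
                             ("r2_threshold", 0, 1)):
            v = getattr(self, name)
            if not (lo < v < hi):
                raise ValidationError(f"{name}={v} outside ({lo}, {hi})")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        design = SyntheticDesign(**doc.pop("design", {}))
        return cls(design=design, **doc)


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    """Stage cache: a stage is skipped when its key (parameters + input
    file hashes) is unchanged and all of its outputs still exist."""

    def __init__(self, outdir: Path):
        self.path = outdir / "manifest.json"
        self.doc = {"version": __version__, "stages": {}}
        if self.path.exists():
            try:
                self.doc = json.loads(self.path.read_text())
            except json.JSONDecodeError:
                pass
        self.doc["version"] = __version__

    def fresh(self, stage: str, key: str, outputs) -> bool:
        rec = self.doc["stages"].get(stage)
        return (rec is not None and rec.get("key") == key
                and all(Path(o).exists() for o in rec.get("outputs", []))
                and sorted(rec.get("outputs", [])) == sorted(map(str, outputs)))

    def record(self, stage: str, key: str, outputs, **params):
        self.doc["stages"][stage] = {"key": key,
                                     "outputs": sorted(map(str, outputs)),
                                     "params": params}
        self.path.write_text(json.dumps(self.doc, indent=2, default=str))


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run every stage into ``outdir``; reruns with an unchanged config
    reuse cached stage outputs byte-for-byte."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)
    cfg_dict = asdict(config)

    # --- inputs -----------------------------------------------------------
    paths = {"table": outdir / "abundance.tsv",
             "meta": outdir / "metadata.tsv",
             "tree": outdir / "tree.nwk",
             "biochem": outdir / "biochem.tsv",
             "truth": outdir / "ground_truth.tsv"}
    if config.simulate:
        key = _hash_obj(["simulate", asdict(config.design), config.seed])
        if not manifest.fresh("simulate", key, paths.values()):
            table, meta, tree, biochem_tab, truth = generate_dataset(
                config.design, seed=config.seed)
            write_abundance_table(table, paths["table"])
            write_metadata(meta, paths["meta"])
            write_newick(tree, paths["tree"])
            write_biochem(biochem_tab, paths["biochem"])
            planted_truth_report(truth).to_csv(paths["truth"], sep="\t",
                                               index=False)
            manifest.record("simulate", key, paths.values(),
                            seed=config.seed)
        table = read_abundance_table(paths["table"])
        meta = read_metadata(paths["meta"])
        tree = read_newick(paths["tree"])
        biochem_tab = read_biochem(paths["biochem"])
    else:
        for name in ("table_path", "metadata_path", "tree_path"):
            if getattr(config, name) is None:
                raise ValidationError(f"{name} required when simulate=false")
        table = read_abundance_table(config.table_path)
        meta = read_metadata(config.metadata_path)
        tree = read_newick(config.tree_path)
        biochem_tab = (read_biochem(config.biochem_path)
                       if config.biochem_path else None)

    realms = sorted(set(meta.df["realm"]))
    rules = {"water": WATER_SECTOR_RULES, "sediment": SEDIMENT_SECTOR_RULES}

    alpha_by_realm = {}
    for realm in realms:
        samples = meta.realm_samples(realm)
        sub = table.select_samples(samples)
        rel = to_relative(sub)
        sectors = meta.df.loc[samples, "sector"] if "sector" in meta.df else None

        # --- alpha diversity, quartiles, sectors, TIN ---------------------
        stage = f"alpha-{realm}"
        outs = [outdir / f"{stage}-{s}.tsv"
                for s in ("shannon", "grid", "sector_report")]
        key = _hash_obj([stage, _hash_file(paths["table"]) if config.simulate
                         else config.table_path, config.grid_res])
        h = alpha_diversity(rel)
        quart = assign_quartiles(h)
        alpha_by_realm[realm] = h
        if not manifest.fresh(stage, key, outs):
            pd.DataFrame({"shannon": h, "quartile": quart}).to_csv(
                outs[0], sep="\t", index_label="sample_id")
            surface = tin_interpolate(meta.df.loc[samples, "longitude"],
                                      meta.df.loc[samples, "latitude"], h,
                                      grid_res=config.grid_res)
            surface.to_frame().to_csv(outs[1], sep="\t", index=False)
            if sectors is not None:
                report = validate_sectors(quart, sectors, rules[realm])
                report.to_csv(outs[2], sep="\t", index=False)
            else:
                outs[2].write_text("sector validation skipped: no sectors\n")
            manifest.record(stage, key, outs)

        # --- beta diversity -----------------------------------------------
        stage = f"beta-{realm}"
        outs = [outdir / f"{stage}-{s}.tsv"
                for s in ("unifrac", "pcoa", "permanova", "env_screen")]
        key = _hash_obj([stage, config.seed, config.n_perm_permanova,
                         config.r2_threshold])
        dm = unweighted_unifrac(rel, tree)
        ordn = pcoa(dm)
        if not manifest.fresh(stage, key, outs):
            dm.to_data_frame().to_csv(outs[0], sep="\t")
            ordn.coordinates.to_csv(outs[1], sep="\t", index_label="sample_id")
            if sectors is not None:
                pr = permanova(dm, sectors.loc[list(dm.ids)],
                               n_perm=config.n_perm_permanova,
                               seed=config.seed)
                pd.DataFrame([asdict(pr)]).to_csv(outs[2], sep="\t",
                                                  index=False)
            else:
                outs[2].write_text("permanova skipped: no sectors\n")
            covs = meta.df.loc[samples, ["depth_m", "distance_from_coast_km"]]
            covs = covs.assign(shannon=h)
            screen = axis_environment_screen(ordn, covs,
                                             r2_threshold=config.r2_threshold)
            screen.to_csv(outs[3], sep="\t", index=False)
            manifest.record(stage, key, outs)

        # --- CAGs and over-abundance ---------------------------------------
        stage = f"cags-{realm}"
        outs = [outdir / f"{stage}-{s}" for s in
                ("membership.tsv", "overabundance.tsv", "network.graphml")]
        key = _hash_obj([stage, config.cag_k, config.edge_q])
        if not manifest.fresh(stage, key, outs):
            corr = kendall_matrix(rel)
            part = cluster_cags(rel, k=config.cag_k)
            memb = pd.DataFrame({
                "cag": part.membership,
                "cag_name": [part.name_of(x) for x in part.membership.index]})
            memb.to_csv(outs[0], sep="\t", index_label="taxon")
            if sectors is not None:
                prof = over_abundance(rel, sectors)
                long = prof.ratios.stack().rename("over_abundance").reset_index()
                long.columns = ["sector", "taxon", "over_abundance"]
                long["tier"] = [prof.tiers.loc[s, x]
                                for s, x in zip(long["sector"], long["taxon"])]
                long.to_csv(outs[1], sep="\t", index=False)
            else:
                prof = None
                outs[1].write_text("over-abundance skipped: no sectors\n")
            net = build_wiggum(rel, part, corr, edge_q=config.edge_q)
            write_network(net, outs[2], format="graphml")
            manifest.record(stage, key, outs)

        # --- sector networks ------------------------------------------------
        if sectors is not None:
            stage = f"networks-{realm}"
            summary_out = outdir / f"{stage}-summary.tsv"
            sector_levels = sorted(sectors.unique())
            net_outs = [outdir / f"{stage}-{s}.graphml" for s in sector_levels]
            outs = [summary_out, *net_outs]
            key = _hash_obj([stage, config.seed, config.n_perm_network,
                             config.n_null_cohesion, config.hub_quantile])
            if not manifest.fresh(stage, key, outs):
                rows = []
                for sec, out_path in zip(sector_levels, net_outs):
                    t_sec = rel.select_samples(
                        list(sectors.index[sectors == sec]))
                    summary = summarize_sector(
                        sec, t_sec, seed=config.seed,
                        n_perm=config.n_perm_network,
                        n_null=config.n_null_cohesion,
                        hub_quantile=config.hub_quantile)
                    net = infer_network(t_sec, n_perm=config.n_perm_network,
                                        seed=config.seed)
                    write_network(net, out_path, format="graphml")
                    row = asdict(summary)
                    row["hubs"] = ";".join(row["hubs"])
                    rows.append(row)
                pd.DataFrame(rows).to_csv(summary_out, sep="\t", index=False)
                manifest.record(stage, key, outs)

    # --- sediment biochemistry + Mantel ------------------------------------
    if biochem_tab is not None and "sediment" in realms:
        stage = "mantel-sediment"
        out = outdir / "mantel-sediment.tsv"
        key = _hash_obj([stage, config.seed, config.n_perm_mantel])
        if not manifest.fresh(stage, key, [out]):
            sed = meta.realm_samples("sediment")
            common = [s for s in sed if s in biochem_tab.df.index]
            dm = unweighted_unifrac(
                to_relative(table.select_samples(common)), tree)
            rows = []
            from scipy.spatial.distance import pdist, squareform
            from skbio.stats.distance import DistanceMatrix
            for comp in ("CHO", "PRT", "LIP", "PIG"):
                env = squareform(pdist(
                    biochem_tab.df.loc[common, [comp]].values))
                res = mantel(dm, DistanceMatrix(env, ids=common),
                             method="spearman", n_perm=config.n_perm_mantel,
                             seed=config.seed)
                rows.append({"component": comp, "mantel_r": res.r,
                             "pvalue": res.pvalue,
                             "n_permutations": res.n_permutations})
            pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
            manifest.record(stage, key, [out])

    # --- cross-realm sharing report -----------------------------------------
    if set(realms) == {"water", "sediment"}:
        stage = "realm-exclusivity"
        out = outdir / "realm_exclusivity.tsv"
        key = _hash_obj([stage, EXCLUSIVITY_RATIO])
        if not manifest.fresh(stage, key, [out]):
            realm_exclusivity(table, meta).to_csv(out, sep="\t", index=False)
            manifest.record(stage, key, [out])

    return outdir


def realm_exclusivity(table: AbundanceTable, meta,
                      ratio: float = EXCLUSIVITY_RATIO) -> pd.DataFrame:
    """Classify each order as water-exclusive, sediment-exclusive or
    shared by the ratio of its mean relative abundances in the two
    realms (exclusive above ``ratio``:1)."""
    rel = to_relative(table)
    means = {}
    for realm in ("water", "sediment"):
        ids = meta.realm_samples(realm)
        idx = [rel.sample_ids.index(s) for s in ids]
        means[realm] = rel.values[:, idx].mean(axis=1)
    w, s = means["water"], means["sediment"]
    status = []
    for wi, si in zip(w, s):
        if si == 0 or (si > 0 and wi / si > ratio):
            status.append("water-exclusive" if wi > 0 else "absent")
        elif wi == 0 or si / wi > ratio:
            status.append("sediment-exclusive")
        else:
            status.append("shared")
    return pd.DataFrame({"taxon": rel.taxon_ids, "mean_water": w,
                         "mean_sediment": s, "status": status})
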