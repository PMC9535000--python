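"""Co-abundance groups (CAGs), sector over-abundance, and Wiggum-plot
network assembly.

Taxon-taxon association is Kendall's tau-b across samples; CAGs are cut
from a Ward dendrogram built on the Spearman correlation distance
(1 - rho) between taxa abundance profiles and named after their most
abundant member order.  Sector enrichment is the over-abundance ratio
meanArea/meanTot, displayed in three tiers: hidden (< 1), normal
([1, 1.3)) and bold (>= 1.3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .errors import ValidationError
from .io_formats import AbundanceTable, to_relative
from .stats import benjamini_hochberg

log = logging.getLogger(__name__)

#: over-abundance display tiers (Wiggum-plot convention)
TIER_HIDDEN_BELOW = 1.0
TIER_BOLD_AT = 1.3


def collapse_to_level(t: AbundanceTable, taxonomy: Mapping[str, Mapping[str, str]],
                      level: str = "order") -> AbundanceTable:
    """Sum abundances within each taxon's assignment at ``level``.

    ``taxonomy`` maps taxon id -> lineage dict (e.g. ``{"order":
    "Vibrionales", "class": "Gammaproteobacteria"}``).  Taxa unassigned
    at the level are pooled into ``Unassigned-<parent>`` bins (parent =
    next-higher assigned rank) and kept, since dropping ~half the
    community silently would distort every downstream composition.
    """
    parents = {"order": ("class", "phylum", "domain"),
               "family": ("order", "class", "phylum", "domain"),
               "genus": ("family", "order", "class", "phylum", "domain")}
    groups: dict = {}
    for taxon in t.taxon_ids:
        if taxon not in taxonomy:
            raise ValidationError(f"no taxonomy for taxon {taxon!r}")
        lineage = taxonomy[taxon]
        name = lineage.get(level)
        if not name:
            parent = next((lineage[p] for p in parents.get(level, ())
                           if lineage.get(p)), "root")
            name = f"Unassigned-{parent}"
        groups.setdefault(name, []).append(taxon)
    names = list(groups)
    mat = np.zeros((len(names), len(t.sample_ids)))
    tix = {x: i for i, x in enumerate(t.taxon_ids)}
    for gi, name in enumerate(names):
        rows = [tix[x] for x in groups[name]]
        mat[gi] = t.values[rows].sum(axis=0)
    return AbundanceTable(names, t.sample_ids, mat, t.is_relative, t.realm)


@dataclass
class CorrelationMatrix:
    """Kendall tau-b association between taxa with BH-adjusted q-values
    over the upper triangle."""

    taxon_ids: list
    tau: np.ndarray
    pvalues: np.ndarray
    qvalues: np.ndarray
    undefined: np.ndarray  # boolean mask of pairs with undefined tau


def kendall_matrix(t: AbundanceTable) -> CorrelationMatrix:
    """Pairwise tie-corrected Kendall tau-b across samples, with
    asymptotic p-values and BH q-values.  Constant taxa yield undefined
    (NaN) tau for their pairs, flagged rather than raised."""
    if len(t.sample_ids) < 5:
        raise ValidationError("need at least 5 samples for correlations")
    X = t.values
    p_tax = len(t.taxon_ids)
    tau = np.eye(p_tax)
    pv = np.zeros((p_tax, p_tax))
    undef = np.zeros((p_tax, p_tax), dtype=bool)
    for i in range(p_tax):
        for j in range(i + 1, p_tax):
            if np.ptp(X[i]) == 0 or np.ptp(X[j]) == 0:
                tau[i, j] = tau[j, i] = np.nan
                pv[i, j] = pv[j, i] = np.nan
                undef[i, j] = undef[j, i] = True
                continue
            res = sps.kendalltau(X[i], X[j], variant="b")
            tau[i, j] = tau[j, i] = res.statistic
            pv[i, j] = pv[j, i] = res.pvalue
    iu = np.triu_indices(p_tax, k=1)
    q = np.full((p_tax, p_tax), np.nan)
    pvec = pv[iu]
    ok = np.isfinite(pvec)
    qvec = np.full_like(pvec, np.nan)
    if ok.any():
        qvec[ok] = benjamini_hochberg(pvec[ok])
    q[iu] = qvec
    q.T[iu] = qvec
    np.fill_diagonal(q, 0.0)
    if undef.any():
        log.warning("kendall_matrix: %d taxon pairs undefined (constant taxa)",
                    int(undef[iu].sum()))
    return CorrelationMatrix(list(t.taxon_ids), tau, pv, q, undef)


@dataclass
class CAGPartition:
    """Taxon -> CAG membership with the linkage tree it was cut from."""

    membership: pd.Series        # taxon id -> CAG integer label (1..k)
    names: dict                  # CAG label -> display name (dominant order)
    linkage_matrix: np.ndarray
    k: int

    def name_of(self, taxon: str) -> str:
        return self.names[self.membership[taxon]]


def _spearman_distance(t: AbundanceTable) -> np.ndarray:
    rho = sps.spearmanr(t.values.T).statistic
    rho = np.atleast_2d(rho)
    # constant taxa have undefined rho: treat as uncorrelated (d = 1)
    rho = np.nan_to_num(rho, nan=0.0)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, None)


def cluster_cags(t: AbundanceTable, k: Optional[int] = None,
                 cluster_input: str = "profiles",
                 corr: Optional[CorrelationMatrix] = None) -> CAGPartition:
    """Ward clustering of taxa into co-abundance groups.

    ``cluster_input="profiles"`` (default) builds the Spearman
    correlation distance 1 - rho between taxa abundance profiles;
    ``"kendall"`` converts a supplied Kendall matrix to 1 - tau.  The
    dendrogram is cut at ``k``; if ``k`` is None the mean silhouette over
    k = 2..6 decides.  CAGs are named by their most abundant member,
    skipping ``Unassigned-*`` bins.
    """
    rel = t if t.is_relative else to_relative(t)
    n_tax = len(rel.taxon_ids)
    if k is not None and (k < 1 or k > n_tax):
        raise ValidationError(f"k={k} outside 1..{n_tax}")
    if cluster_input == "profiles":
        dist = _spearman_distance(rel)
    elif cluster_input == "kendall":
        if corr is None:
            raise ValidationError("kendall mode needs a CorrelationMatrix")
        dist = 1.0 - np.nan_to_num(corr.tau, nan=0.0)
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    else:
        raise ValidationError(f"unknown cluster_input {cluster_input!r}")
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="ward")
    if k is None:
        best_k, best_s = 2, -np.inf
        for kk in range(2, min(6, n_tax - 1) + 1):
            lab = fcluster(Z, kk, criterion="maxclust")
            if len(np.unique(lab)) < 2:
                continue
            s = silhouette_score(dist, lab, metric="precomputed")
            if s > best_s:
                best_k, best_s = kk, s
        k = best_k
    labels = (np.ones(n_tax, dtype=int) if k == 1
              else fcluster(Z, k, criterion="maxclust"))
    membership = pd.Series(labels, index=rel.taxon_ids, name="cag")
    mean_ab = pd.Series(rel.values.mean(axis=1), index=rel.taxon_ids)
    names = {}
    for lab in sorted(np.unique(labels)):
        members = membership.index[membership == lab]
        named = [m for m in members if not str(m).startswith("Unassigned")]
        pool = named or list(members)
        top = mean_ab.loc[pool].idxmax()
        name = str(top)
        if name in names.values():
            name = f"{name}-{lab}"
        names[int(lab)] = name
    return CAGPartition(membership, names, Z, int(k))


@dataclass
class OverAbundanceProfile:
    """Sector-by-taxon enrichment ratios meanArea/meanTot with display
    tiers; sector weights n_s/N make sum_s w_s * O_sj = 1 per taxon."""

    ratios: pd.DataFrame        # sectors x taxa
    tiers: pd.DataFrame         # sectors x taxa, {"hidden","normal","bold"}
    sector_weights: pd.Series   # sector -> n_s / N


def over_abundance(t: AbundanceTable, sectors: pd.Series) -> OverAbundanceProfile:
    """Per-sector over-abundance O_sj = (mean relative abundance of taxon
    j in sector s) / (mean over all samples)."""
    rel = t if t.is_relative else to_relative(t)
    sectors = sectors.loc[rel.sample_ids]
    levels = sorted(sectors.unique())
    for s in levels:
        if (sectors == s).sum() == 0:
            raise ValidationError(f"sector {s!r} is empty")
    overall = rel.values.mean(axis=1)
    zero = overall == 0
    if zero.any():
        log.warning("over_abundance: %d taxa have zero overall mean "
                    "(undefined ratios)", int(zero.sum()))
    rows = []
    weights = []
    for s in levels:
        mask = np.asarray(sectors == s)
        weights.append(mask.sum() / len(rel.sample_ids))
        means = rel.values[:, mask].mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rows.append(np.where(zero, np.nan, means / np.where(zero, 1, overall)))
    ratios = pd.DataFrame(rows, index=levels, columns=rel.taxon_ids)
    tiers = ratios.map(_tier)
    return OverAbundanceProfile(ratios, tiers,
                                pd.Series(weights, index=levels, name="weight"))


def _tier(o: float) -> str:
    if not np.isfinite(o):
        return "undefined"
    if o < TIER_HIDDEN_BELOW:
        return "hidden"
    if o >= TIER_BOLD_AT:
        return "bold"
    return "normal"


def build_wiggum(t: AbundanceTable, partition: CAGPartition,
                 corr: CorrelationMatrix,
                 profile: Optional[OverAbundanceProfile] = None,
                 sector: Optional[str] = None,
                 edge_q: float = 0.05) -> nx.Graph:
    """Assemble the Wiggum-plot graph: nodes carry mean abundance, CAG
    membership and (for sector views) over-abundance + display tier;
    edges are the significant Kendall correlations (BH q <= ``edge_q``),
    signed by tau."""
    rel = t if t.is_relative else to_relative(t)
    if list(rel.taxon_ids) != list(corr.taxon_ids):
        raise ValidationError("correlation matrix taxa do not match table")
    g = nx.Graph()
    g.graph["provenance"] = "kendall-CAG"
    if sector is not None:
        g.graph["sector"] = sector
    mean_ab = rel.values.mean(axis=1)
    for i, taxon in enumerate(rel.taxon_ids):
        attrs = {"mean_abundance": float(mean_ab[i]),
                 "cag": int(partition.membership[taxon]),
                 "cag_name": partition.name_of(taxon)}
        if profile is not None and sector is not None:
            o = float(profile.ratios.loc[sector, taxon])
            tier = profile.tiers.loc[sector, taxon]
            attrs.update(over_abundance=o, tier=tier,
                         excluded=bool(tier == "hidden"))
        g.add_node(taxon, **attrs)
    p_tax = len(rel.taxon_ids)
    for i in range(p_tax):
        for j in range(i + 1, p_tax):
            q = corr.qvalues[i, j]
            if np.isfinite(q) and q <= edge_q:
                tau = float(corr.tau[i, j])
                g.add_edge(rel.taxon_ids[i], rel.taxon_ids[j], weight=tau,
                           qvalue=float(q),
                           sign="negative" if tau < 0 else "positive")
    return g
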