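"""Sector-specific co-occurrence networks and their summary statistics.

Network inference is compositional: relative abundances are
centered-log-ratio transformed (pseudocount = half the smallest positive
value), pairwise Pearson associations are tested by a seeded permutation
null with BH control at q <= 0.05, and an optional order-1
partial-correlation prune removes edges explainable by any single third
taxon.  This conditional-independence filter is this package's own
construction in the spirit of local-to-global network learning; it is
not a reimplementation of any published tool, and network provenance
fields record it.

Summaries follow common practice for microbial networks: hubs are nodes
jointly extreme in degree, betweenness and closeness; modules and
modularity come from seeded Louvain on the unsigned graph; total
connectivity is edges per node; and community cohesion (Herren &
McMahon-style) is the abundance-weighted average of each taxon's
null-corrected positive/negative connectedness, summarized per sector
as the negative:positive (N:P) cohesion ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import AbundanceTable, to_relative
from .stats import benjamini_hochberg

log = logging.getLogger(__name__)


def clr_transform(t: AbundanceTable, pseudocount: Optional[float] = None) -> np.ndarray:
    """Centered log-ratio transform of relative abundances (taxa x samples).

    The pseudocount defaults to half the smallest positive relative
    abundance in the table.  Because proportions are used, the result is
    invariant to per-sample sequencing depth.
    """
    rel = t if t.is_relative else to_relative(t)
    X = rel.values
    if pseudocount is None:
        pos = X[X > 0]
        if pos.size == 0:
            raise ValidationError("table has no positive entries")
        pseudocount = pos.min() / 2.0
    L = np.log(X + pseudocount)
    return L - L.mean(axis=0, keepdims=True)


def _pairwise_pearson(X: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    r = np.nan_to_num(r, nan=0.0)   # constant rows: no association
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def infer_network(t: AbundanceTable, n_perm: int = 1000, seed: int = 0,
                  edge_q: float = 0.05, prune_order1: bool = True,
                  partial_r_threshold: float = 0.1,
                  pseudocount: Optional[float] = None) -> nx.Graph:
    """Infer a signed co-occurrence network for one sector's samples.

    Pearson correlations of CLR-transformed abundances are tested
    against a permutation null (each taxon's values shuffled
    independently across samples, ``n_perm`` times, seeded); edges keep
    pairs with BH q <= ``edge_q``.  With ``prune_order1``, an edge is
    dropped when conditioning on any single other taxon sends its
    partial correlation below ``partial_r_threshold`` in magnitude.
    """
    if len(t.sample_ids) < 5:
        raise ValidationError("need at least 5 samples to infer a network")
    if len(t.taxon_ids) < 3:
        raise ValidationError("need at least 3 taxa to infer a network")
    X = clr_transform(t, pseudocount)
    p_tax, n = X.shape
    const = np.ptp(X, axis=1) == 0
    r = _pairwise_pearson(X)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(p_tax, k=1)
    exceed = np.zeros(len(iu[0]), dtype=np.int64)
    obs = np.abs(r[iu])
    for _ in range(n_perm):
        Xp = np.array([row[rng.permutation(n)] for row in X])
        rp = np.abs(_pairwise_pearson(Xp)[iu])
        exceed += rp >= obs
    pvec = (1.0 + exceed) / (1.0 + n_perm)
    valid = ~(const[iu[0]] | const[iu[1]])
    qvec = np.full_like(pvec, np.nan)
    if valid.any():
        qvec[valid] = benjamini_hochberg(pvec[valid])
    g = nx.Graph()
    g.add_nodes_from(t.taxon_ids)
    g.graph.update(provenance="sector-inference",
                   method="clr-pearson-permutation+order1-prune",
                   n_permutations=n_perm, seed=seed, edge_q=edge_q)
    keep = []
    for idx in range(len(iu[0])):
        i, j = iu[0][idx], iu[1][idx]
        if valid[idx] and np.isfinite(qvec[idx]) and qvec[idx] <= edge_q:
            keep.append((i, j, qvec[idx]))
    if prune_order1:
        kept = []
        for i, j, q in keep:
            rij = r[i, j]
            pruned = False
            for k in range(p_tax):
                if k in (i, j) or const[k]:
                    continue
                denom = (1 - r[i, k] ** 2) * (1 - r[j, k] ** 2)
                if denom <= 1e-12:
                    continue
                partial = (rij - r[i, k] * r[j, k]) / np.sqrt(denom)
                if abs(partial) < partial_r_threshold:
                    pruned = True
                    break
            if not pruned:
                kept.append((i, j, q))
        keep = kept
    for i, j, q in keep:
        w = float(r[i, j])
        g.add_edge(t.taxon_ids[i], t.taxon_ids[j], weight=w, qvalue=float(q),
                   sign="negative" if w < 0 else "positive")
    return g


@dataclass
class HubResult:
    hubs: list
    degenerate: bool = False


def find_hubs(net: nx.Graph, quantile: float = 0.90) -> HubResult:
    """Hub taxa: nodes strictly above the ``quantile`` of degree,
    betweenness and closeness simultaneously (computed on the unsigned
    largest connected component).

    If no node dominates all three, the single best node by summed
    centrality ranks is returned, flagged degenerate; ties break by node
    id.  An edgeless network yields an empty list with a warning.
    """
    if net.number_of_edges() == 0:
        log.warning("find_hubs: edgeless network")
        return HubResult([], degenerate=True)
    comp = max(nx.connected_components(net), key=lambda c: (len(c), sorted(c)))
    sub = net.subgraph(comp)
    nodes = sorted(sub.nodes)
    deg = dict(sub.degree())
    btw = nx.betweenness_centrality(sub)
    clo = nx.closeness_centrality(sub)
    metrics = {m: np.array([vals[v] for v in nodes])
               for m, vals in (("degree", deg), ("betweenness", btw),
                               ("closeness", clo))}
    thresholds = {m: np.quantile(v, quantile) for m, v in metrics.items()}
    hubs = [v for i, v in enumerate(nodes)
            if all(metrics[m][i] > thresholds[m] for m in metrics)]
    if hubs:
        return HubResult(sorted(hubs))
    # symmetric/degenerate: best summed rank, ties by id
    ranks = np.zeros(len(nodes))
    for m in metrics:
        order = np.argsort(np.argsort(-metrics[m], kind="stable"))
        ranks += order
    best = min(zip(ranks, nodes))
    return HubResult([best[1]], degenerate=True)


def modularity_and_modules(net: nx.Graph, seed: int = 0):
    """Louvain community detection (seeded) on the unsigned graph.

    Returns (Q, n_modules, membership dict).  Singletons count as
    modules; an edgeless network reports Q = 0 with one module per node.
    """
    if net.number_of_edges() == 0:
        membership = {v: i for i, v in enumerate(sorted(net.nodes))}
        log.warning("modularity on edgeless network: Q reported as 0")
        return 0.0, net.number_of_nodes(), membership
    unsigned = nx.Graph()
    unsigned.add_nodes_from(net.nodes)
    for u, v, d in net.edges(data=True):
        unsigned.add_edge(u, v, weight=abs(d.get("weight", 1.0)))
    comms = nx.community.louvain_communities(unsigned, weight="weight",
                                             seed=seed)
    q = nx.community.modularity(unsigned, comms, weight="weight")
    membership = {}
    for i, comm in enumerate(sorted(comms, key=lambda c: sorted(c)[0])):
        for v in comm:
            membership[v] = i
    return float(q), len(comms), membership


def total_connectivity(net: nx.Graph) -> dict:
    """Edge count per node (the headline value), plus density and mean
    degree for disambiguation."""
    n, m = net.number_of_nodes(), net.number_of_edges()
    return {"edges_per_node": m / n if n else 0.0,
            "density": nx.density(net) if n > 1 else 0.0,
            "mean_degree": 2.0 * m / n if n else 0.0,
            "n_nodes": n, "n_edges": m}


@dataclass
class CohesionResult:
    """Null-corrected connectedness and cohesion for one sector."""

    connectedness_pos: pd.Series   # per taxon, >= 0
    connectedness_neg: pd.Series   # per taxon, <= 0
    cohesion_pos: pd.Series        # per sample
    cohesion_neg: pd.Series        # per sample
    np_ratio: float                # |mean cohesion-| / mean cohesion+
    np_infinite: bool = False


def cohesion(t: AbundanceTable, n_null: int = 200, seed: int = 0) -> CohesionResult:
    """Community cohesion from abundance correlations with a taxon-shuffle
    null.

    Pearson correlations between taxa (on relative abundances) are
    corrected by subtracting the mean correlation over ``n_null`` seeded
    datasets in which each taxon's values are independently shuffled
    across samples and samples are re-closed to sum to one (so the null
    carries the same compositional closure bias as the observed
    matrix).  A taxon's positive (negative) connectedness is the
    mean of its positive (negative) corrected correlations; sample
    cohesion is the abundance-weighted sum of connectedness, and the
    sector N:P ratio compares mean negative to mean positive cohesion.
    """
    if len(t.sample_ids) < 5:
        raise ValidationError("need at least 5 samples for cohesion")
    rel = t if t.is_relative else to_relative(t)
    X = rel.values
    p_tax, n = X.shape
    keep = np.ptp(X, axis=1) > 0
    corr = np.zeros((p_tax, p_tax))
    sub = np.corrcoef(X[keep])
    corr[np.ix_(keep, keep)] = np.atleast_2d(sub)
    rng = np.random.default_rng(seed)
    null_sum = np.zeros_like(corr)
    for _ in range(n_null):
        Xp = np.array([row[rng.permutation(n)] for row in X])
        sums = Xp.sum(axis=0)
        Xp = Xp / np.where(sums > 0, sums, 1.0)
        null_sum[np.ix_(keep, keep)] += np.atleast_2d(np.corrcoef(Xp[keep]))
    corrected = corr - null_sum / n_null
    np.fill_diagonal(corrected, 0.0)
    conn_pos = np.zeros(p_tax)
    conn_neg = np.zeros(p_tax)
    for j in range(p_tax):
        row = np.delete(corrected[j], j)
        pos = row[row > 0]
        neg = row[row < 0]
        conn_pos[j] = pos.mean() if pos.size else 0.0
        conn_neg[j] = neg.mean() if neg.size else 0.0
    coh_pos = X.T @ conn_pos
    coh_neg = X.T @ conn_neg
    mean_pos = float(coh_pos.mean())
    mean_neg = float(coh_neg.mean())
    if mean_pos <= 0:
        ratio, infinite = (0.0, False) if mean_neg == 0 else (np.inf, True)
        if infinite:
            log.warning("cohesion: no positive cohesion, N:P flagged infinite")
    else:
        ratio, infinite = abs(mean_neg) / mean_pos, False
    taxa = rel.taxon_ids
    return CohesionResult(
        pd.Series(conn_pos, index=taxa), pd.Series(conn_neg, index=taxa),
        pd.Series(coh_pos, index=rel.sample_ids),
        pd.Series(coh_neg, index=rel.sample_ids),
        float(ratio), infinite)


@dataclass
class NetworkSummary:
    """One row of the per-sector network parameter table."""

    sector: str
    np_cohesion_ratio: float
    n_modules: int
    modularity: float
    total_connectivity: float
    hubs: list
    n_nodes: int
    n_edges: int
    seed: int


def summarize_sector(sector: str, t_sector: AbundanceTable, seed: int = 0,
                     n_perm: int = 1000, n_null: int = 200,
                     hub_quantile: float = 0.90,
                     net: Optional[nx.Graph] = None) -> NetworkSummary:
    """Infer (or accept) the sector network and compute the full summary:
    N:P cohesion, modules, modularity, total connectivity and hubs."""
    if net is None:
        net = infer_network(t_sector, n_perm=n_perm, seed=seed)
    q, n_modules, _ = modularity_and_modules(net, seed=seed)
    conn = total_connectivity(net)
    hubs = find_hubs(net, quantile=hub_quantile)
    coh = cohesion(t_sector, n_null=n_null, seed=seed)
    return NetworkSummary(sector, coh.np_ratio, n_modules, q,
                          conn["edges_per_node"], hubs.hubs,
                          conn["n_nodes"], conn["n_edges"], seed)
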