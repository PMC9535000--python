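"""Beta diversity: unweighted UniFrac, principal coordinates, PERMANOVA,
Mantel matrix correlation, and ordination-vs-environment screens.

Unweighted UniFrac follows the classical presence/absence definition:
the branch length unique to either community divided by the branch
length of the union of both communities' lineages.  PERMANOVA uses the
direct-from-distances pseudo-F with free label permutation; permutation
p-values carry the +1 correction, so the smallest attainable p at 999
permutations is 0.001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import skbio
from scipy import stats as sps
from skbio.stats.distance import DistanceMatrix

from .errors import ValidationError
from .io_formats import AbundanceTable, to_relative

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------

def _branch_incidence(tree: skbio.TreeNode, taxon_ids):
    """Per-branch leaf incidence: boolean (branches x taxa) matrix plus
    branch lengths, over all non-root branches with positive length."""
    idx = {t: i for i, t in enumerate(taxon_ids)}
    missing = [lf.name for lf in tree.tips() if lf.name is None]
    if missing:
        raise ValidationError("tree has unnamed leaves")
    below = {}
    rows, lengths = [], []
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            vec = np.zeros(len(taxon_ids), dtype=bool)
            if node.name in idx:
                vec[idx[node.name]] = True
            below[id(node)] = vec
        else:
            vec = np.zeros(len(taxon_ids), dtype=bool)
            for child in node.children:
                vec |= below[id(child)]
            below[id(node)] = vec
        if not node.is_root() and node.length and vec.any():
            rows.append(vec)
            lengths.append(node.length)
    if not rows:
        raise ValidationError("tree has no positive-length branches over the taxa")
    return np.array(rows), np.asarray(lengths, dtype=float)


def unweighted_unifrac(t: AbundanceTable, tree: skbio.TreeNode,
                       prune_missing: bool = False) -> DistanceMatrix:
    """Pairwise unweighted UniFrac distances between all samples.

    A taxon is present in a sample iff its abundance is strictly
    positive.  Taxa absent from the tree are an error unless
    ``prune_missing`` drops them (with a warning).
    """
    leaves = {lf.name for lf in tree.tips()}
    missing = [x for x in t.taxon_ids if x not in leaves]
    if missing:
        if not prune_missing:
            raise ValidationError(
                f"taxa missing from tree: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        log.warning("pruning %d taxa absent from the tree", len(missing))
        t = t.select_taxa([x for x in t.taxon_ids if x in leaves])
    B, L = _branch_incidence(tree, t.taxon_ids)
    presence = t.values > 0
    # branch "observed" in a sample iff any descendant taxon is present
    A = (B.astype(float) @ presence.astype(float) > 0).astype(float)
    s = L @ A                            # per-sample observed branch length
    both = (L[:, None] * A).T @ A        # pairwise shared branch length
    union = s[:, None] + s[None, :] - both
    unique = s[:, None] + s[None, :] - 2.0 * both
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, unique / np.where(union > 0, union, 1.0), 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=t.sample_ids)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class Ordination:
    """Principal-coordinates embedding: centered sample coordinates on
    axes MDS1, MDS2, ... ordered by decreasing (positive) eigenvalue."""

    coordinates: pd.DataFrame       # samples x axes
    eigenvalues: np.ndarray         # positive eigenvalues, descending
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray


def pcoa(d: DistanceMatrix) -> Ordination:
    """Classical PCoA: Gower double-centering of -d^2/2, eigendecomposition,
    axes from positive eigenvalues only.

    Negative eigenvalues (non-Euclidean inputs) are excluded from the
    axes and variance fractions, and logged.  Sign convention: on each
    axis the largest-magnitude coordinate is positive.
    """
    dm = np.asarray(d.data, dtype=float)
    n = dm.shape[0]
    if np.allclose(dm, 0):
        raise ValidationError("all-zero distance matrix is degenerate")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dm ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10 * max(evals.max(), 1.0), 1e-12)
    pos = evals > tol
    neg = evals[evals < -tol]
    if neg.size:
        log.info("PCoA: %d negative eigenvalues (non-Euclidean input) "
                 "excluded, most negative %.3g", neg.size, neg.min())
    lam = evals[pos]
    coords = evecs[:, pos] * np.sqrt(lam)
    for k in range(coords.shape[1]):
        if coords[np.argmax(np.abs(coords[:, k])), k] < 0:
            coords[:, k] *= -1.0
    axes = [f"MDS{k + 1}" for k in range(coords.shape[1])]
    frame = pd.DataFrame(coords, index=list(d.ids), columns=axes)
    return Ordination(frame, lam, lam / lam.sum(), neg)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    pvalue: float
    n_permutations: int
    seed: int


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """Within-group sum of squared distances (Anderson's formulation)."""
    ss_w = 0.0
    for g in range(n_groups):
        mask = codes == g
        ng = int(mask.sum())
        ss_w += d2[np.ix_(mask, mask)].sum() / (2.0 * ng)
    return ss_w


def permanova(d: DistanceMatrix, groups, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA (adonis): pseudo-F from sums of squared
    distances, p by free permutation of group labels with the +1
    correction."""
    groups = pd.Series(groups)
    if set(map(str, groups.index)) == set(d.ids):
        groups = groups.loc[[*d.ids]]
    labels = np.asarray(groups.values)
    codes, uniq = pd.factorize(labels)
    a = len(uniq)
    if a < 2:
        raise ValidationError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValidationError("every group needs at least 2 samples")
    dm = np.asarray(d.data, dtype=float)
    n = dm.shape[0]
    if len(codes) != n:
        raise ValidationError("group labels do not match distance matrix")
    d2 = dm ** 2
    ss_t = d2.sum() / (2.0 * n)
    ss_w = _permanova_ss(d2, codes, a)
    ss_a = ss_t - ss_w
    f_obs = (ss_a / (a - 1)) / (ss_w / (n - a))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        ss_wp = _permanova_ss(d2, perm, a)
        f_p = ((ss_t - ss_wp) / (a - 1)) / (ss_wp / (n - a))
        if f_p >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(ss_a / ss_t), float(p),
                           n_perm, seed)


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    pvalue: float
    n_permutations: int
    method: str
    alternative: str
    seed: int


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, method: str = "spearman",
           n_perm: int = 9999, seed: int = 0,
           alternative: str = "greater") -> MantelResult:
    """Mantel correlation between two distance matrices over the same
    samples; p by simultaneous row/column permutation of the second
    matrix (9999 permutations by default)."""
    if list(d1.ids) != list(d2.ids):
        if set(d1.ids) == set(d2.ids):
            d2 = d2.filter(d1.ids)
        else:
            raise ValidationError("distance matrices cover different samples")
    n = len(d1.ids)
    if n < 4:
        raise ValidationError("need at least 4 samples for a Mantel test")
    iu = np.triu_indices(n, k=1)
    v1 = np.asarray(d1.data)[iu]
    m2 = np.asarray(d2.data, dtype=float)
    if method == "spearman":
        v1 = sps.rankdata(v1)
        rank_fn = sps.rankdata
    elif method == "pearson":
        rank_fn = lambda x: x
    else:
        raise ValidationError(f"unknown method {method!r}")
    v1c = v1 - v1.mean()

    def corr_with(mat):
        v2 = rank_fn(mat[iu])
        v2c = v2 - v2.mean()
        denom = np.sqrt((v1c ** 2).sum() * (v2c ** 2).sum())
        if denom == 0:
            raise ValidationError("constant distance matrix")
        return float((v1c * v2c).sum() / denom)

    r_obs = corr_with(m2)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr_with(m2[np.ix_(perm, perm)])
        if alternative == "greater":
            hits += r_p >= r_obs
        elif alternative == "two-sided":
            hits += abs(r_p) >= abs(r_obs)
        else:
            hits += r_p <= r_obs
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(r_obs, float(p), n_perm, method, alternative, seed)


# ---------------------------------------------------------------------------
# ordination vs environment
# ---------------------------------------------------------------------------

def axis_environment_screen(ordination: Ordination, covariates: pd.DataFrame,
                            r2_threshold: float = 0.25,
                            n_axes: int = 2) -> pd.DataFrame:
    """Correlation/regression screen of ordination axes against
    environmental covariates.

    Emits Pearson and Spearman correlations with p-values plus the
    simple-linear-regression R^2 per (axis, covariate), flagging pairs
    that exceed the relevance threshold (default R^2 > 0.25).  Constant
    covariates are flagged undefined rather than raising.
    """
    coords = ordination.coordinates
    covariates = covariates.loc[coords.index]
    rows = []
    for axis in coords.columns[:n_axes]:
        x = coords[axis].values
        for cov in covariates.columns:
            y = covariates[cov].astype(float).values
            ok = np.isfinite(y)
            if ok.sum() < 3 or np.std(y[ok]) == 0 or np.std(x[ok]) == 0:
                rows.append((axis, cov, np.nan, np.nan, np.nan, np.nan,
                             np.nan, False, True))
                continue
            pr, pp = sps.pearsonr(x[ok], y[ok])
            sr, sp = sps.spearmanr(x[ok], y[ok])
            r2 = pr ** 2
            rows.append((axis, cov, pr, pp, sr, sp, r2,
                         bool(r2 > r2_threshold), False))
    return pd.DataFrame(rows, columns=[
        "axis", "covariate", "pearson_r", "pearson_p", "spearman_r",
        "spearman_p", "r_squared", "relevant", "undefined"])
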