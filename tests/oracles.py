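"""Independent brute-force oracles used by the test suite.

These deliberately use the most naive formulation of each quantity
(per-branch loops, pair counting, full enumeration) so that agreement
with the vectorized implementations is a meaningful check.
"""

import itertools

import numpy as np


def unifrac_bruteforce(tree, presence_a: set, presence_b: set) -> float:
    """Unweighted UniFrac by looping over every branch and testing which
    community has a descendant leaf below it."""
    unique = 0.0
    union = 0.0
    for node in tree.traverse(include_self=False):
        if not node.length:
            continue
        leaves = {lf.name for lf in ([node] if node.is_tip() else node.tips())}
        in_a = bool(leaves & presence_a)
        in_b = bool(leaves & presence_b)
        if in_a or in_b:
            union += node.length
            if in_a != in_b:
                unique += node.length
    return unique / union if union > 0 else 0.0


def kendall_tau_pairs(x, y) -> float:
    """Kendall tau-b by explicit concordant/discordant pair counting."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / denom if denom > 0 else np.nan


def wilcoxon_exact_enumeration(x, y) -> float:
    """Two-sided rank-sum p by enumerating every assignment of the
    pooled ranks to the first group (tie-free inputs only)."""
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == len(pooled), "tie-free inputs only"
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    nx = len(x)
    w_obs = ranks[:nx].sum()
    mu = nx * (len(pooled) + 1) / 2.0
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), nx):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


def permanova_f(dmat: np.ndarray, codes: np.ndarray) -> float:
    """Pseudo-F directly from the definition (per-group double loop)."""
    n = len(codes)
    groups = np.unique(codes)
    a = len(groups)
    ss_t = sum(dmat[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_w = 0.0
    for g in groups:
        idx = np.flatnonzero(codes == g)
        ss_w += sum(dmat[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    ss_a = ss_t - ss_w
    return (ss_a / (a - 1)) / (ss_w / (n - a))


def permanova_exhaustive_p(dmat: np.ndarray, codes: np.ndarray) -> float:
    """Exact PERMANOVA p over every distinct relabelling."""
    f_obs = permanova_f(dmat, codes)
    count = total = 0
    for perm in set(itertools.permutations(codes)):
        total += 1
        if permanova_f(dmat, np.asarray(perm)) >= f_obs - 1e-12:
            count += 1
    return count / total


def pearson_upper_triangles(m1: np.ndarray, m2: np.ndarray) -> float:
    """Pearson correlation of the vectorized strict upper triangles."""
    iu = np.triu_indices(m1.shape[0], k=1)
    return float(np.corrcoef(m1[iu], m2[iu])[0, 1])
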