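"""Between-sample (beta) diversity.

Generalized UniFrac distances from a phylogenetic tree and a normalized
OTU table, ordination of the resulting distance matrix (classical PCoA and
non-metric MDS), PERMANOVA significance testing of group separation
(overall and pairwise), and Ward hierarchical clustering.

The generalized UniFrac family (Chen-style) is

    d^(a)(A, B) = sum_i b_i (p_Ai + p_Bi)^a * |p_Ai - p_Bi| / (p_Ai + p_Bi)
                  -----------------------------------------------------------
                  sum_i b_i (p_Ai + p_Bi)^a

where b_i is the length of branch i and p_Ai the total proportion of
sample A's community descending from that branch; branches with
p_Ai + p_Bi = 0 are skipped in both sums (the limit convention).  The
exponent a in [0, 1] interpolates between sensitivity to rare lineages
(a = 0) and to dominant ones (a = 1); the default a = 0.5 is the balanced
compromise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io import NormalizedTable, ValidationError
from .stats import bh_adjust

DEFAULT_ALPHA = 0.5


def _branch_profile(table: NormalizedTable, tree) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths b_i and per-branch sample proportions p_i.

    Returns (lengths, props) with props shaped (n_branches, n_samples):
    props[i, j] is the summed proportion of sample j's community carried by
    the leaves descending from branch i.
    """
    values = table.values.to_numpy(dtype=float)
    sums = values.sum(axis=0)
    if (sums <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, sums) if t <= 0]
        raise ValidationError(f"samples with zero total: {bad}")
    props = values / sums
    row_of = {otu: i for i, otu in enumerate(table.otu_ids)}

    tip_names = {t.name for t in tree.tips()}
    missing = set(table.otu_ids) - tip_names
    if missing:
        raise ValidationError(f"OTUs absent from tree: {sorted(missing)}")

    lengths, branch_props = [], []
    subtree: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            if node.name in row_of:
                vec = props[row_of[node.name]]
            else:
                vec = np.zeros(props.shape[1])
        else:
            vec = np.zeros(props.shape[1])
            for child in node.children:
                vec = vec + subtree[id(child)]
        subtree[id(node)] = vec
        if node.parent is not None:  # every edge except the (nonexistent) root edge
            lengths.append(node.length if node.length is not None else 0.0)
            branch_props.append(vec)
    return np.asarray(lengths, dtype=float), np.asarray(branch_props, dtype=float)


def generalized_unifrac(
    table: NormalizedTable, tree, alpha: float = DEFAULT_ALPHA
) -> DistanceMatrix:
    """All-against-all generalized UniFrac distance matrix."""
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError(f"alpha must be in [0, 1], got {alpha}")
    lengths, props = _branch_profile(table, tree)
    n = props.shape[1]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pa, pb = props[:, i], props[:, j]
            tot = pa + pb
            mask = tot > 0
            w = lengths[mask] * tot[mask] ** alpha
            ratio = np.abs(pa[mask] - pb[mask]) / tot[mask]
            denom = w.sum()
            d = (w * ratio).sum() / denom if denom > 0 else 0.0
            dm[i, j] = dm[j, i] = d
    return DistanceMatrix(dm, ids=[str(s) for s in table.sample_ids])


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x k
    method: str  # "PCoA" | "NMDS"
    eigenvalues: np.ndarray | None = None  # PCoA, descending, incl. negatives
    stress: float | None = None  # NMDS Kruskal stress-1
    converged: bool = True


def pcoa(dm: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical (metric) scaling of a distance matrix.

    Double-centres -D^2/2, eigendecomposes, and scales eigenvectors by the
    square roots of the positive eigenvalues.  Negative eigenvalues (from
    non-Euclidean distances) are reported but their axes dropped; no
    Cailliez/Lingoes correction is applied.
    """
    d = dm.data
    n = d.shape[0]
    if n < 3:
        raise ValidationError("PCoA needs at least 3 samples")
    a = -0.5 * d**2
    centre = np.eye(n) - np.ones((n, n)) / n
    g = centre @ a @ centre
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10 * max(eigvals.max(), 1.0)
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    k_eff = min(k, coords.shape[1])
    cols = [f"PCo{i + 1}" for i in range(k_eff)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords[:, :k_eff], index=list(dm.ids), columns=cols),
        method="PCoA",
        eigenvalues=eigvals,
    )


def _stress1(dist: np.ndarray, dhat: np.ndarray) -> float:
    denom = (dist**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dist - dhat) ** 2).sum() / denom))


def _smacof_nonmetric(d, x0, max_iter, tol):
    """One non-metric SMACOF run: isotonic disparities + Guttman updates."""
    n = x0.shape[0]
    order = np.argsort(d, kind="stable")  # ties averaged by adjacent pooling
    x = x0 - x0.mean(axis=0)
    best_x, best_stress = x, np.inf
    converged = False
    for _ in range(max_iter):
        dist = pdist(x)
        dhat_sorted = isotonic_regression(dist[order]).x
        dhat = np.empty_like(dist)
        dhat[order] = dhat_sorted
        stress = _stress1(dist, dhat)
        if stress >= best_stress - 1e-15:
            if best_stress - stress < tol:
                converged = True
            if stress > best_stress:
                break  # reject an increasing step, keep the best config
        best_x, best_stress = x, min(stress, best_stress)
        if converged or stress < 1e-12:
            converged = True
            break
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat / dist, 0.0)
        b = -squareform(ratio)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = (b @ x) / n
        x = x - x.mean(axis=0)
    return best_x, best_stress, converged


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    seed: int = 0,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Iterative majorization (SMACOF) with isotonic regression of the
    configuration distances on the rank order of the input dissimilarities.
    The first start is the PCoA configuration; the remaining ``n_starts - 1``
    are random.  The lowest-stress configuration wins; the result carries a
    ``converged`` flag that is False when no start converged.
    """
    n = dm.shape[0]
    if n <= k + 1:
        raise ValidationError(f"NMDS in {k} dimensions needs more than {k + 1} samples")
    d = dm.condensed_form()
    rng = np.random.default_rng(seed)
    try:
        x0 = pcoa(dm, k=k).coordinates.to_numpy()
        if x0.shape[1] < k:  # degenerate metric start: pad with tiny noise
            pad = 1e-6 * rng.standard_normal((n, k - x0.shape[1]))
            x0 = np.hstack([x0, pad])
        starts = [x0]
    except ValidationError:
        starts = []
    while len(starts) < n_starts:
        starts.append(rng.standard_normal((n, k)))

    best = (None, np.inf, False)
    for x0 in starts:
        x, stress, conv = _smacof_nonmetric(d, x0, max_iter, tol)
        if stress < best[1]:
            best = (x, stress, conv)
    x, stress, conv = best
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return OrdinationResult(
        coordinates=pd.DataFrame(x, index=list(dm.ids), columns=cols),
        method="NMDS",
        stress=stress,
        converged=conv,
    )


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int
    pairwise: pd.DataFrame | None = None


def _permanova_f(d2: np.ndarray, idx_groups: list[np.ndarray], n: int) -> tuple[float, float]:
    """Pseudo-F and R2 from squared distances and per-group index arrays."""
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for idx in idx_groups:
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2 * len(idx))
    ss_among = ss_total - ss_within
    a = len(idx_groups)
    if ss_within == 0:  # perfectly separated groups
        f = np.inf
    else:
        f = (ss_among / (a - 1)) / (ss_within / (n - a))
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA (Anderson's pseudo-F) on a distance matrix.

    The pseudo-F partitions the total sum of squared inter-point distances
    into among- and within-group components; significance comes from
    uniformly permuting the sample labels, with
    p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    """
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    if (counts < 2).any():
        small = [str(g) for g, c in zip(labels, counts) if c < 2]
        raise ValidationError(f"groups with fewer than 2 samples: {small}")
    n = dm.shape[0]
    if n != len(groups):
        raise ValidationError("group labels must match distance-matrix samples")
    d2 = dm.data**2
    idx_groups = [np.flatnonzero(groups == g) for g in labels]
    f_obs, r2 = _permanova_f(d2, idx_groups, n)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        perm_groups = [perm[idx] for idx in idx_groups]
        f_perm, _ = _permanova_f(d2, perm_groups, n)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return PermanovaResult(pseudo_F=float(f_obs), R2=float(r2), p=float(p), n_permutations=n_perm)


def pairwise_permanova(
    dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0
) -> PermanovaResult:
    """Overall PERMANOVA plus every group-pair tested on its sub-matrix.

    Pairwise p-values are Benjamini-Hochberg adjusted across pairs.
    """
    groups = np.asarray(groups)
    overall = permanova(dm, groups, n_perm=n_perm, seed=seed)
    labels = np.unique(groups)
    rng = np.random.default_rng(seed)
    rows = []
    ids = np.asarray(dm.ids)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            mask = (groups == labels[i]) | (groups == labels[j])
            sub = dm.filter(ids[mask])
            res = permanova(sub, groups[mask], n_perm=n_perm,
                            seed=int(rng.integers(2**31)))
            rows.append(
                dict(group_a=labels[i], group_b=labels[j],
                     pseudo_F=res.pseudo_F, p=res.p)
            )
    pw = pd.DataFrame(rows)
    pw["p_adj"] = bh_adjust(pw["p"].to_numpy())
    overall.pairwise = pw
    return overall


@dataclass
class WardResult:
    linkage: np.ndarray  # scipy merge table
    ids: list
    newick: str


def _linkage_to_newick(node, ids) -> str:
    if node.is_leaf():
        return str(ids[node.id])
    left, right = node.get_left(), node.get_right()
    parts = []
    for child in (left, right):
        length = max(node.dist - child.dist, 0.0) / 2 if not child.is_leaf() else node.dist / 2
        parts.append(f"{_linkage_to_newick(child, ids)}:{length:.10g}")
    return f"({parts[0]},{parts[1]})"


def ward_dendrogram(dm: DistanceMatrix) -> WardResult:
    """Agglomerative clustering with the Ward criterion (ward.D2 semantics).

    scipy's 'ward' linkage on raw dissimilarities minimizes the increase in
    within-cluster sum of squared distances, i.e. the criterion applied to
    squared dissimilarities; ties break deterministically by index order.
    """
    if dm.shape[0] < 2:
        raise ValidationError("dendrogram needs at least 2 samples")
    z = sch.linkage(dm.condensed_form(), method="ward")
    root = sch.to_tree(z)
    newick = _linkage_to_newick(root, list(dm.ids)) + ";"
    return WardResult(linkage=z, ids=list(dm.ids), newick=newick)
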