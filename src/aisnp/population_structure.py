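"""Between-population structure: Nei DA, pairwise Fst, NJ trees and PCA.

Multi-locus pairwise Fst combines loci as a ratio of sums, sum(Ht - Hs) /
sum(Ht), not a mean of per-locus ratios. Neighbor-joining follows the
Saitou-Nei agglomeration with the standard Q criterion, deterministic
lowest-index tie-breaking, and negative branch-length estimates clamped
to 0. PCA is covariance PCA on column-centred matrices; individual-level
PCA mean-imputes missing genotypes (optionally scales by sqrt(p(1-p))).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from aisnp.genotype_io import MISSING, AlleleFrequencyTable, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def get(self, a: str, b: str) -> float:
        return float(
            self.values[self.labels.index(a), self.labels.index(b)]
        )


@dataclass
class PhyloTree:
    """Unrooted tree as an edge list over integer nodes.

    Nodes 0..n_leaves-1 are leaves (in ``leaf_labels`` order); higher ids
    are internal. Edge lengths are non-negative.
    """

    leaf_labels: list[str]
    edges: list[tuple[int, int, float]]
    n_nodes: int

    def adjacency(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {
            i: [] for i in range(self.n_nodes)
        }
        for u, v, w in self.edges:
            adj[u].append((v, w))
            adj[v].append((u, w))
        return adj

    def leaf_distance_matrix(self) -> DistanceMatrix:
        """Pairwise path lengths between leaves along the tree."""
        adj = self.adjacency()
        n_leaves = len(self.leaf_labels)
        out = np.zeros((n_leaves, n_leaves))
        for src in range(n_leaves):
            dist = {src: 0.0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for dst in range(n_leaves):
                out[src, dst] = dist[dst]
        return DistanceMatrix(list(self.leaf_labels), out)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def nei_da(aft: AlleleFrequencyTable) -> DistanceMatrix:
    """Nei's DA distance between all group pairs.

    DA(X, Y) = 1 - (1/L) * sum_l [sqrt(x_l y_l) + sqrt((1-x_l)(1-y_l))].
    Loci where either group has an undefined frequency are dropped from
    that pair with L adjusted.
    """
    k = len(aft.groups)
    out = np.zeros((k, k))
    f = aft.alt_freq
    for i, j in itertools.combinations(range(k), 2):
        ok = ~np.isnan(f[i]) & ~np.isnan(f[j])
        if not ok.all():
            log.warning(
                "nei_da: dropping %d loci with undefined frequencies for %s/%s",
                int((~ok).sum()), aft.groups[i], aft.groups[j],
            )
        if not ok.any():
            raise ValueError(
                f"no loci usable between {aft.groups[i]} and {aft.groups[j]}"
            )
        x, y = f[i][ok], f[j][ok]
        share = np.sqrt(x * y) + np.sqrt((1 - x) * (1 - y))
        d = 1.0 - share.mean()
        out[i, j] = out[j, i] = max(d, 0.0)
    return DistanceMatrix(list(aft.groups), out)


def pairwise_fst_matrix(aft: AlleleFrequencyTable) -> DistanceMatrix:
    """Multi-locus pairwise Gst matrix (ratio of sums over loci)."""
    k = len(aft.groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    out = np.zeros((k, k))
    f = aft.alt_freq
    for i, j in itertools.combinations(range(k), 2):
        ok = ~np.isnan(f[i]) & ~np.isnan(f[j])
        x, y = f[i][ok], f[j][ok]
        pbar = (x + y) / 2.0
        ht = 2.0 * pbar * (1.0 - pbar)
        hs = x * (1.0 - x) + y * (1.0 - y)  # mean of 2p(1-p) over the pair
        denom = ht.sum()
        fst = (ht - hs).sum() / denom if denom > 0 else 0.0
        out[i, j] = out[j, i] = max(float(fst), 0.0)
    return DistanceMatrix(list(aft.groups), out)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Negative branch-length estimates are clamped to 0. Requires >= 3
    taxa; the result is an unrooted binary tree.
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")

    # working state: active node ids and their mutual distances
    next_id = n
    active = list(range(n))
    dist: dict[tuple[int, int], float] = {}
    for i, j in itertools.combinations(range(n), 2):
        dist[(i, j)] = dist[(j, i)] = float(dm.values[i, j])
    edges: list[tuple[int, int, float]] = []

    def d(a: int, b: int) -> float:
        return 0.0 if a == b else dist[(a, b)]

    while len(active) > 3:
        r = len(active)
        row_sums = {a: sum(d(a, b) for b in active) for a in active}
        best = None
        best_q = np.inf
        for ii in range(r):
            for jj in range(ii + 1, r):
                a, b = active[ii], active[jj]
                q = (r - 2) * d(a, b) - row_sums[a] - row_sums[b]
                if q < best_q - 1e-12:  # strict improvement; else keep lowest pair
                    best_q = q
                    best = (a, b)
        a, b = best  # type: ignore[misc]
        la = 0.5 * d(a, b) + (row_sums[a] - row_sums[b]) / (2 * (r - 2))
        lb = d(a, b) - la
        u = next_id
        next_id += 1
        edges.append((u, a, max(la, 0.0)))
        edges.append((u, b, max(lb, 0.0)))
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
            dist[(u, c)] = dist[(c, u)] = duc
        active = [c for c in active if c not in (a, b)] + [u]

    a, b, c = active
    u = next_id
    next_id += 1
    edges.append((u, a, max(0.5 * (d(a, b) + d(a, c) - d(b, c)), 0.0)))
    edges.append((u, b, max(0.5 * (d(a, b) + d(b, c) - d(a, c)), 0.0)))
    edges.append((u, c, max(0.5 * (d(a, c) + d(b, c) - d(a, b)), 0.0)))
    return PhyloTree(labels, edges, next_id)


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: PhyloTree) -> str:
    """Serialize an unrooted tree, rooted for syntax at the last internal node."""
    adj = tree.adjacency()
    root = tree.n_nodes - 1
    if root < len(tree.leaf_labels):  # degenerate: no internal nodes
        root = 0

    def render(node: int, parent: int) -> str:
        children = [(v, w) for v, w in adj[node] if v != parent]
        if not children and node < len(tree.leaf_labels):
            return _quote_label(tree.leaf_labels[node])
        inner = ",".join(
            f"{render(v, node)}:{w:.10g}" for v, w in children
        )
        name = (
            _quote_label(tree.leaf_labels[node])
            if node < len(tree.leaf_labels)
            else ""
        )
        return f"({inner}){name}"

    return render(root, -1) + ";"


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    entity_labels: list[str]
    scores: np.ndarray  # entities x components
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # loci x components

    def to_frame(self, n_components: int = 2) -> pd.DataFrame:
        k = min(n_components, self.scores.shape[1])
        df = pd.DataFrame(
            self.scores[:, :k], columns=[f"PC{i + 1}" for i in range(k)]
        )
        df.insert(0, "label", self.entity_labels)
        return df


def _pca(matrix: np.ndarray, labels: list[str]) -> PCAResult:
    centered = matrix - matrix.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive per component
    for k in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u * s
    var = s**2
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    return PCAResult(labels, scores, ratio, vt.T)


def pca_populations(aft: AlleleFrequencyTable) -> PCAResult:
    """Covariance PCA of group frequency vectors (one point per group)."""
    if len(aft.groups) < 2 or len(aft.loci) < 2:
        raise ValueError("need >= 2 groups and >= 2 loci")
    f = aft.alt_freq
    if np.isnan(f).any():
        raise ValueError("undefined frequency cells; filter loci first")
    return _pca(f, list(aft.groups))


def pca_individuals(gm: GenotypeMatrix, scale: bool = False) -> PCAResult:
    """Covariance PCA of genotype dosages (one point per individual).

    Missing codes are imputed with the locus mean before centring; loci
    with no calls at all are dropped with a warning. ``scale=True``
    divides each locus by sqrt(p(1-p)) after centring.
    """
    if gm.n_samples < 2:
        raise ValueError("need >= 2 individuals")
    codes = gm.codes.astype(float)
    codes[gm.codes == MISSING] = np.nan
    all_missing = np.all(np.isnan(codes), axis=0)
    if all_missing.any():
        log.warning("dropping %d loci with no calls", int(all_missing.sum()))
        codes = codes[:, ~all_missing]
    col_mean = np.nanmean(codes, axis=0)
    inds = np.where(np.isnan(codes))
    codes[inds] = np.take(col_mean, inds[1])
    if scale:
        p = col_mean / 2.0
        sd = np.sqrt(np.clip(p * (1.0 - p), 1e-12, None))
        codes = codes / sd
    return _pca(codes, list(gm.samples))
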