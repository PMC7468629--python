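"""Ordination and tree building: genotype PCA, classical MDS, neighbor joining.

PCA operates on the individuals x loci dosage matrix (missing values
mean-imputed per locus); MDS is Torgerson's classical scaling of a distance
matrix; neighbor joining is the Saitou-Nei agglomeration with deterministic
lowest-index tie-breaking, returning a Bio.Phylo tree whose root trifurcates
(the unrooted-tree convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Phylo.BaseTree import Clade, Tree

from .io_formats import MISSING, GenotypeTable


@dataclass
class PcaResult:
    scores: np.ndarray              # (n, C)
    loadings: np.ndarray            # (L, C)
    explained: np.ndarray           # variance fractions, non-increasing
    mode: str                       # "center" | "patterson"


@dataclass
class MdsResult:
    coordinates: pd.DataFrame       # populations x dims
    eigenvalues: np.ndarray         # all eigenvalues of the doubly-centered matrix
    stress: float                   # fraction of |eigenvalue| mass not in the
                                    # retained positive components


def impute_dosage(table: GenotypeTable) -> np.ndarray:
    """Dosage matrix with missing entries replaced by the locus mean."""
    d = table.dosage.astype(float)
    miss = table.dosage == MISSING
    col_mean = np.where(miss, 0, d).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1)
    return np.where(miss, col_mean[None, :], d)


def genotype_pca(table: GenotypeTable, mode: str = "center",
                 n_components: int | None = None) -> PcaResult:
    """PCA of the (imputed) dosage matrix.

    ``mode="center"`` subtracts locus means; ``mode="patterson"``
    additionally divides each locus by ``sqrt(p(1-p))`` with p the mean
    dosage / 2.  Sign convention: the largest-magnitude loading of each
    component is positive.
    """
    if table.n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    if mode not in ("center", "patterson"):
        raise ValueError(f"unknown PCA mode {mode!r}")
    X = impute_dosage(table)
    X = X - X.mean(axis=0, keepdims=True)
    if mode == "patterson":
        p = np.clip(impute_dosage(table).mean(axis=0) / 2, 1e-9, 1 - 1e-9)
        X = X / np.sqrt(p * (1 - p))[None, :]
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    if n_components is None:
        n_components = min(X.shape)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    # deterministic sign: largest-|loading| entry positive
    for c in range(len(s)):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            vt[c] *= -1
            u[:, c] *= -1
    scores = u * s
    var = s ** 2
    total = (X ** 2).sum()
    explained = var / total if total > 0 else np.zeros_like(var)
    return PcaResult(scores, vt.T, explained, mode)


def classical_mds(distance_matrix: pd.DataFrame | np.ndarray, dims: int = 2) -> MdsResult:
    """Torgerson classical scaling.

    Coordinates are the top-``dims`` eigenvectors of the doubly-centered
    squared-distance matrix scaled by root-eigenvalues (components with
    non-positive eigenvalues get zero coordinates); the centroid sits at the
    origin by construction.
    """
    if isinstance(distance_matrix, pd.DataFrame):
        labels = list(distance_matrix.index)
        D = distance_matrix.to_numpy(dtype=float)
    else:
        D = np.asarray(distance_matrix, dtype=float)
        labels = [str(i) for i in range(D.shape[0])]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, dims))
    for c in range(min(dims, n)):
        if evals[c] > 0:
            coords[:, c] = evecs[:, c] * np.sqrt(evals[c])
    total = np.abs(evals).sum()
    kept = evals[:dims][evals[:dims] > 0].sum()
    stress = float(1 - kept / total) if total > 0 else 0.0
    return MdsResult(pd.DataFrame(coords, index=labels,
                                  columns=[f"dim{c+1}" for c in range(dims)]),
                     evals, stress)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(distance_matrix: pd.DataFrame | np.ndarray,
                     labels=None, clamp_negative: bool = False) -> Tree:
    """Saitou-Nei neighbor joining.

    Tie-breaks on the Q criterion go to the lexicographically smallest index
    pair, making the topology deterministic.  Branch lengths may be negative
    unless ``clamp_negative``.  With two leaves the tree is a single edge.
    """
    if isinstance(distance_matrix, pd.DataFrame):
        labels = list(distance_matrix.index)
        D = distance_matrix.to_numpy(dtype=float)
    else:
        D = np.asarray(distance_matrix, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(D.shape[0])]
        labels = list(labels)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 leaves")
    nodes: list[Clade] = [Clade(name=lab) for lab in labels]
    D = D.copy()

    def _clamp(x: float) -> float:
        return max(x, 0.0) if clamp_negative else x

    while len(nodes) > 3:
        m = len(nodes)
        row_sums = D.sum(axis=1)
        q = (m - 2) * D - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic argmin: smallest (i, j) among minima
        flat = np.argmin(q)
        best = np.unravel_index(flat, q.shape)
        i, j = sorted(best)
        d_ij = D[i, j]
        li = _clamp(0.5 * d_ij + (row_sums[i] - row_sums[j]) / (2 * (m - 2)))
        lj = _clamp(d_ij - li)
        ci, cj = nodes[i], nodes[j]
        ci.branch_length = li
        cj.branch_length = lj
        new = Clade(clades=[ci, cj])
        d_new = 0.5 * (D[i] + D[j] - d_ij)
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new]

    if len(nodes) == 2:
        a, b = nodes
        b.branch_length = D[0, 1]
        root = Clade(clades=[a, b])
        a.branch_length = 0.0
        return Tree(root=root, rooted=False)

    # final three nodes: closed-form three-point lengths, trifurcating root
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = _clamp(0.5 * (d01 + d02 - d12))
    l1 = _clamp(0.5 * (d01 + d12 - d02))
    l2 = _clamp(0.5 * (d02 + d12 - d01))
    for node, length in zip(nodes, (l0, l1, l2)):
        node.branch_length = length
    return Tree(root=Clade(clades=list(nodes)), rooted=False)


def tree_distance_matrix(tree: Tree) -> pd.DataFrame:
    """Leaf-to-leaf path-length (cophenetic) matrix of a Bio.Phylo tree."""
    leaves = tree.get_terminals()
    names = [t.name for t in leaves]
    depths = {}
    for a in leaves:
        depths[a.name] = {b.name: (0.0 if a is b else tree.distance(a, b)) for b in leaves}
    return pd.DataFrame([[depths[x][y] for y in names] for x in names],
                        index=names, columns=names)
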