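"""Neighbor-joining trees from codon-usage distances, with bootstrap.

Species relatedness is assessed without an alignment: pairwise Euclidean
distances between RSCU profiles feed a Saitou-Nei neighbor-joining
agglomeration, and branch support comes from resampling the codon columns of
the RSCU matrix with replacement. Trees are scikit-bio ``TreeNode`` objects,
so newick round-trips come for free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    provenance: str = "rscu_euclidean"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if (v < 0).any() or not np.allclose(np.diag(v), 0):
            raise ValueError("distances must be non-negative with zero diagonal")
        object.__setattr__(self, "values", v)

    def __len__(self):
        return len(self.labels)


def usage_distance_matrix(
    matrix: pd.DataFrame, provenance: str = "rscu_euclidean"
) -> DistanceMatrix:
    """Euclidean distances between species rows of a usage matrix."""
    if len(matrix) < 3:
        raise ValueError("need at least 3 species for a tree")
    x = matrix.to_numpy(dtype=float)
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # kill float asymmetry
    return DistanceMatrix(
        labels=tuple(matrix.index), values=d, provenance=provenance
    )


def p_distance_matrix(sequences: dict[str, str]) -> DistanceMatrix:
    """Proportion of mismatching positions between equal-length sequences."""
    labels = tuple(sequences)
    lens = {len(s) for s in sequences.values()}
    if len(lens) != 1:
        raise ValueError("p-distance requires equal-length (pre-aligned) sequences")
    arr = np.array([list(sequences[l]) for l in labels])
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = np.mean(arr[i] != arr[j])
    return DistanceMatrix(labels=labels, values=d, provenance="p_distance")


def _clamped(length: float, context: str) -> float:
    if length < 0:
        warnings.warn(f"negative NJ branch length {length:.6g} at {context}; clamped to 0")
        return 0.0
    return float(length)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    At every step the pair minimizing Q = (m-2) d_ij - r_i - r_j is joined;
    exact Q ties are broken by the lexicographically smallest (label_i,
    label_j) pair, where a cluster is labelled by its smallest leaf name.
    Negative branch lengths are clamped to zero with a warning. Returns an
    unrooted tree (trifurcating root) for n >= 4, a star for n = 3.
    """
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.values.copy()
    nodes = [TreeNode(name=str(l)) for l in dm.labels]
    reps = [str(l) for l in dm.labels]  # smallest leaf label per cluster

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((reps[i], reps[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        ctx = f"({reps[i]},{reps[j]})"
        nodes[i].length = _clamped(li, ctx)
        nodes[j].length = _clamped(lj, ctx)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_d = (d[i, :] + d[j, :] - d[i, j]) / 2
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_d[keep]])
        d = np.hstack([d, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]

    # final three clusters join at an unrooted (trifurcating) root
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = _clamped((dab + dac - dbc) / 2, "root")
    b.length = _clamped((dab + dbc - dac) / 2, "root")
    c.length = _clamped((dac + dbc - dab) / 2, "root")
    root = TreeNode(children=[a, b, c])
    root.length = None
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Informative bipartitions of an unrooted tree.

    Each internal edge splits the leaves in two; the side not containing the
    alphabetically first leaf names the bipartition, so the representation
    is rooting-invariant.
    """
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def bootstrap_support(
    matrix: pd.DataFrame,
    b_replicates: int = 1000,
    seed: int = 0,
    provenance: str = "rscu_euclidean",
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree with column-resampling bootstrap supports.

    The point-estimate tree is built from the full species x codon matrix;
    each replicate resamples the codon columns with replacement, rebuilds
    the tree, and every internal bipartition of the point tree is scored by
    the percentage of replicates containing it. Supports are written onto
    the internal node names (integer percent).
    """
    if b_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    tree = nj_tree(usage_distance_matrix(matrix, provenance))
    target = bipartitions(tree)
    hits = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    p = matrix.shape[1]
    for _ in range(b_replicates):
        cols = rng.integers(0, p, size=p)
        rep = matrix.iloc[:, cols]
        rep_bps = bipartitions(nj_tree(usage_distance_matrix(rep, provenance)))
        for bp in target:
            if bp in rep_bps:
                hits[bp] += 1
    support = {bp: 100.0 * k / b_replicates for bp, k in hits.items()}

    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = leaves - side
        if side in support:
            node.name = str(int(round(support[side])))
    return tree, support


def write_newick(tree: TreeNode, path: str | Path) -> Path:
    path = Path(path)
    tree.write(str(path), format="newick")
    return path


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(Path(path)), format="newick")
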