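"""p-distances, neighbor joining, and nonparametric bootstrap supports.

NJ serves as a desk-scale stand-in for minimum-evolution searches: ME
uses an NJ starting tree and rarely differs at these sizes; externally
inferred trees remain first-class inputs via the newick reader.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ProteinAlignment, RadsigError
from .substitution import N_STATES, encode_alignment
from .tree import Node, Tree


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if D.shape != (n, n):
            raise RadsigError("distance matrix shape does not match ids")
        if not np.all(np.isfinite(D)):
            raise RadsigError("distance matrix has non-finite entries")
        if np.any(D < 0) or not np.allclose(D, D.T):
            raise RadsigError("distance matrix must be symmetric and non-negative")
        self.matrix = D


def _p_distance_from_codes(codes: np.ndarray) -> np.ndarray:
    """Pairwise p-distance with pairwise deletion of gap/X positions."""
    valid = codes < N_STATES
    both = valid[:, None, :] & valid[None, :, :]
    compared = both.sum(axis=2)
    diff = (codes[:, None, :] != codes[None, :, :]) & both
    if np.any(compared[~np.eye(len(codes), dtype=bool)] == 0):
        raise RadsigError("a sequence pair has no comparable positions")
    D = diff.sum(axis=2) / np.maximum(compared, 1)
    np.fill_diagonal(D, 0.0)
    return D


def p_distance(aln: ProteinAlignment) -> DistanceMatrix:
    """Proportion of differing sites per pair, pairwise deletion."""
    if aln.n_sequences < 2:
        raise RadsigError("need at least two sequences")
    codes, ids = encode_alignment(aln)
    return DistanceMatrix(ids, _p_distance_from_codes(codes))


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Negative intermediate branch lengths are clamped to zero with the
    deficit moved to the sibling branch. Ties in the Q criterion are
    broken by the lexicographically smallest pair of subtree keys (the
    smallest leaf label in each subtree), so the result is independent
    of input order. The returned tree is unrooted in style: degree-3
    root, no supports.
    """
    n = len(dm.ids)
    if n < 3:
        raise RadsigError("neighbor joining needs at least 3 taxa")
    D = dm.matrix.copy()
    nodes = [Node(label=lb) for lb in dm.ids]
    keys = list(dm.ids)  # smallest leaf label in each active subtree

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        candidates = np.argwhere(Q <= qmin + 0.0)
        i, j = min(
            (tuple(sorted((int(a), int(b)), key=lambda t: keys[t])) for a, b in candidates),
            key=lambda ij: (keys[ij[0]], keys[ij[1]]),
        )
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = D[i, j] - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        parent = Node()
        nodes[i].length = vi
        nodes[j].length = vj
        parent.add(nodes[i])
        parent.add(nodes[j])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = dnew[keep]
        D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[x] for x in keep] + [parent]
        keys = [keys[x] for x in keep] + [min(keys[i], keys[j])]

    root = Node()
    if len(nodes) == 3:
        (a, b, c) = nodes
        la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
        lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
        lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
        for node, length in zip((a, b, c), (la, lb, lc)):
            node.length = max(length, 0.0)
            root.add(node)
    return Tree(root)


def nj_from_alignment(aln: ProteinAlignment) -> Tree:
    return neighbor_joining(p_distance(aln))


def bootstrap_supports(
    aln: ProteinAlignment,
    n_replicates: int,
    seed: int,
    builder=None,
) -> Tree:
    """NJ tree of the full alignment with bootstrap supports in percent.

    Columns are resampled with replacement per replicate; the support of
    each internal bipartition of the full-data tree is the percentage of
    replicate trees containing that bipartition.
    """
    if n_replicates < 1:
        raise RadsigError("need at least one bootstrap replicate")
    tree = (builder or nj_from_alignment)(aln)
    codes, ids = encode_alignment(aln)
    L = codes.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {s: 0 for s in tree.bipartitions()}
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep_codes = codes[:, cols]
        if builder is None:
            rep_tree = neighbor_joining(DistanceMatrix(ids, _p_distance_from_codes(rep_codes)))
        else:
            rows = ["".join(aln.rows[i][c] for c in cols) for i in range(len(ids))]
            rep_tree = builder(ProteinAlignment(list(ids), rows))
        for split in rep_tree.bipartitions():
            if split in counts:
                counts[split] += 1

    # attach supports onto the full-data tree
    all_leaves = set(tree.leaf_labels())
    anchor = min(all_leaves)
    below: dict[int, set[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = {node.label}
        else:
            s = set().union(*(below[id(c)] for c in node.children))
            below[id(node)] = s
            if node is tree.root:
                continue
            side = s if anchor not in s else all_leaves - s
            key = frozenset(side)
            if key in counts:
                node.support = 100.0 * counts[key] / n_replicates
    return tree
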