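"""Distance-based phylogenetics: K2P, neighbor joining, bootstrap, parsimony.

The Kimura 2-parameter distance corrects separately for transitions (P) and
transversions (Q): d = -1/2 ln((1-2P-Q) sqrt(1-2Q)).  Neighbor joining uses
the canonical Q-criterion with deterministic tie-breaking (lexicographically
smallest label pair) and clamps negative branch lengths to zero.  Bootstrap
resamples supermatrix columns with replacement and reports, on the
point-estimate tree, the percentage of replicates containing each internal
bipartition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .coresnp import CharacterMatrix
from .records import CladepanError, LabeledMatrix
from .tree import TreeNode, bipartitions


class SaturationError(CladepanError):
    """Raised when the K2P correction is undefined (1-2P-Q <= 0 or 1-2Q <= 0)."""


@dataclass
class SiteCounts:
    """Usable-site count and transition/transversion proportions of a pair."""

    n_sites: int
    P: float
    Q: float

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise CladepanError("no usable sites")
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise CladepanError("invalid transition/transversion proportions")


_PURINES = frozenset("AG")


def site_counts(row_a: str, row_b: str) -> SiteCounts:
    """Count usable sites (both symbols in ACGT) and classify differences."""
    if len(row_a) != len(row_b):
        raise CladepanError("rows have different lengths")
    n = ts = tv = 0
    for x, y in zip(row_a, row_b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise CladepanError("zero usable sites between rows")
    return SiteCounts(n_sites=n, P=ts / n, Q=tv / n)


def k2p_from_counts(counts: SiteCounts, pair: str = "") -> float:
    """Closed-form K2P distance from transition/transversion proportions."""
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P saturation for pair {pair or '(unnamed)'}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def k2p_distance(row_a: str, row_b: str) -> float:
    """K2P distance between two aligned rows with pairwise deletion of
    non-ACGT sites (gaps and N excluded)."""
    return k2p_from_counts(site_counts(row_a, row_b))


_K2P_CODE = np.full(128, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _K2P_CODE[ord(_c)] = _i


def k2p_matrix(chars: CharacterMatrix) -> LabeledMatrix:
    """All-pairs K2P distances over a character matrix (vectorized)."""
    genomes = chars.genomes
    n = len(genomes)
    if chars.n_columns == 0:
        raise CladepanError("cannot compute distances on an empty matrix")
    codes = np.empty(chars.columns.shape, dtype=np.int8)
    for i in range(n):
        for j, ch in enumerate(chars.columns[i]):
            codes[i, j] = _K2P_CODE[ord(ch)] if ord(ch) < 128 else -1
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[i], codes[j]
            usable = (a >= 0) & (b >= 0)
            m = int(usable.sum())
            if m == 0:
                raise CladepanError(
                    f"zero usable sites between {genomes[i]} and {genomes[j]}"
                )
            aa, bb = a[usable], b[usable]
            diff = aa != bb
            # with codes A=0,C=1,G=2,T=3 transitions (A<->G, C<->T) preserve parity
            ts = int((diff & ((aa & 1) == (bb & 1))).sum())
            tv = int(diff.sum()) - ts
            out[i, j] = out[j, i] = k2p_from_counts(
                SiteCounts(n_sites=m, P=ts / m, Q=tv / m),
                pair=f"({genomes[i]}, {genomes[j]})",
            )
    return LabeledMatrix(df=pd.DataFrame(out, index=genomes, columns=genomes),
                         symmetric=True)


def nj_tree(dist: LabeledMatrix) -> TreeNode:
    """Canonical neighbor joining; returns an unrooted tree (trifurcating root).

    Join ties are broken by the lexicographically smallest pair of cluster
    labels (a cluster is labeled by its smallest descendant leaf); negative
    branch lengths are clamped to zero.
    """
    if not dist.symmetric:
        raise CladepanError("NJ needs a symmetric distance matrix")
    labels = dist.row_labels
    if len(labels) < 3:
        raise CladepanError("NJ needs at least 3 taxa")
    d = dist.df.to_numpy(dtype=float).copy()
    if np.isnan(d).any():
        raise CladepanError("distance matrix has missing cells")
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    tags: list[str] = list(labels)  # smallest descendant leaf per cluster
    active = list(range(len(labels)))

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        total = sub.sum(axis=1)
        best = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                q = (r - 2) * sub[ii, jj] - total[ii] - total[jj]
                pair_tag = tuple(sorted((tags[active[ii]], tags[active[jj]])))
                key = (q, pair_tag)
                if best is None or key < best[0]:
                    best = (key, ii, jj)
        _, ii, jj = best
        i, j = active[ii], active[jj]
        dij = d[i, j]
        li = 0.5 * dij + (total[ii] - total[jj]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = max(0.0, li), max(0.0, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        new_node = TreeNode(children=[child_i, child_j])
        # distances from the new node
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_row])
        new_col = np.append(new_row, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(new_node)
        tags.append(min(tags[i], tags[j]))
        active = [x for x in active if x not in (i, j)] + [len(nodes) - 1]

    # resolve the final three clusters on a star
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, length in zip((a, b, c), (la, lb, lc)):
        nodes[idx].length = max(0.0, length)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    root.sort()
    return root


def root_tree(tree: TreeNode, outgroup_label: str) -> TreeNode:
    """Root on the midpoint of the outgroup's pendant edge."""
    tree = tree.copy()
    target = tree.find_leaf(outgroup_label)

    # find parent of target
    parent = None
    for node in tree.walk():
        if target in node.children:
            parent = node
            break
    if parent is None:  # tree of one leaf
        raise CladepanError("cannot root a single-leaf tree")
    parent.children.remove(target)
    rest = _rehang(tree, parent)
    # collapse degenerate unary chains at the new apex, accumulating their
    # edge lengths into the outgroup's pendant edge
    extra = 0.0
    while len(rest.children) == 1 and rest.name is None:
        inner = rest.children[0]
        extra += inner.length
        rest = inner
    pendant = target.length + extra
    rest.length = pendant / 2.0
    target.length = pendant / 2.0
    root = TreeNode(children=[target, rest])
    root.sort()
    return root


def _rehang(root: TreeNode, new_root: TreeNode) -> TreeNode:
    """Re-orient the tree so ``new_root`` becomes the root (lengths follow edges)."""
    parent_of: dict[int, TreeNode] = {}
    for node in root.walk():
        for child in node.children:
            parent_of[id(child)] = node

    path = [new_root]
    while id(path[-1]) in parent_of:
        path.append(parent_of[id(path[-1])])
    # reverse parent-child relation along the path
    for child, parent in zip(path, path[1:]):
        parent.children.remove(child)
        child.children.append(parent)
        parent.length = child.length
        parent.support = child.support
    new_root.length = 0.0
    # collapse a now-degenerate old root with a single child
    _suppress_unary(new_root)
    return new_root


def _suppress_unary(node: TreeNode) -> None:
    for child in list(node.children):
        _suppress_unary(child)
    for child in list(node.children):
        if len(child.children) == 1 and child.name is None:
            grand = child.children[0]
            grand.length += child.length
            node.children[node.children.index(child)] = grand


def unrooted_bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    return bipartitions(tree)


def bootstrap_support(
    chars: CharacterMatrix,
    n_reps: int = 100,
    rng: np.random.Generator | None = None,
) -> TreeNode:
    """NJ tree from K2P distances with bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; replicates whose
    distance computation saturates are skipped with a warning, and more than
    20% skipped replicates is a hard error.  Supports (percent of replicates
    containing each internal bipartition) are attached to the point-estimate
    tree built from the full matrix.
    """
    if len(chars.genomes) < 4:
        raise CladepanError("bootstrap needs at least 4 genomes")
    if chars.n_columns < 1:
        raise CladepanError("bootstrap needs at least one column")
    rng = rng if rng is not None else np.random.default_rng(0)
    point_tree = nj_tree(k2p_matrix(chars))
    splits = {s: 0 for s in bipartitions(point_tree)}
    # resample over a canonical (lexicographic) column order so supports are
    # exactly invariant to the input column order under a fixed seed
    canon = sorted(range(chars.n_columns),
                   key=lambda j: "".join(chars.columns[:, j]))
    columns = chars.columns[:, canon]
    provenance = [chars.provenance[j] for j in canon]
    skipped = 0
    for _ in range(n_reps):
        pick = rng.integers(0, chars.n_columns, size=chars.n_columns)
        rep = CharacterMatrix(
            genomes=chars.genomes,
            columns=columns[:, pick],
            provenance=[provenance[p] for p in pick],
        )
        try:
            rep_tree = nj_tree(k2p_matrix(rep))
        except (SaturationError, CladepanError) as exc:
            skipped += 1
            warnings.warn(f"bootstrap replicate skipped: {exc}", stacklevel=2)
            continue
        rep_splits = bipartitions(rep_tree)
        for s in splits:
            if s in rep_splits:
                splits[s] += 1
    if skipped * 5 >= n_reps:
        raise CladepanError(f"{skipped}/{n_reps} bootstrap replicates skipped")
    effective = n_reps - skipped
    support_of = {s: round(100.0 * c / effective) for s, c in splits.items()}
    all_leaves = frozenset(point_tree.leaf_names())
    anchor = min(all_leaves)

    def annotate(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        clade = frozenset().union(*(annotate(c) for c in node.children))
        side = clade if anchor not in clade else all_leaves - clade
        if side in support_of:
            node.support = support_of[side]
        return clade

    annotate(point_tree)
    return point_tree


def fitch_score(tree: TreeNode, chars: CharacterMatrix) -> int:
    """Fitch parsimony score: minimal state changes summed over columns."""
    leaf_names = sorted(tree.leaf_names())
    if leaf_names != sorted(chars.genomes):
        raise CladepanError("tree leaves do not match character-matrix rows")
    row_of = {g: i for i, g in enumerate(chars.genomes)}
    total = 0
    for j in range(chars.n_columns):
        column = chars.columns[:, j]

        def fitch(node: TreeNode) -> frozenset[str]:
            nonlocal total
            if node.is_leaf:
                return frozenset([column[row_of[node.name]]])
            sets = [fitch(c) for c in node.children]
            acc = sets[0]
            for s in sets[1:]:
                inter = acc & s
                if inter:
                    acc = inter
                else:
                    acc = acc | s
                    total += 1
            return acc

        fitch(tree)
    return int(total)


@dataclass
class Dendrogram:
    """Complete-linkage clustering result in scipy linkage form."""

    labels: list[str]
    linkage: np.ndarray  # scipy (n-1, 4) linkage matrix
    leaf_order: list[str]

    def merge_heights(self) -> list[float]:
        return [float(h) for h in self.linkage[:, 2]]

    def as_tree(self) -> TreeNode:
        nodes = [TreeNode(name=lab) for lab in self.labels]
        for row in self.linkage:
            left, right, height, _ = row
            child_a, child_b = nodes[int(left)], nodes[int(right)]
            nodes.append(TreeNode(children=[child_a, child_b], length=float(height)))
        return nodes[-1]


def complete_linkage_dendrogram(matrix: pd.DataFrame) -> Dendrogram:
    """Agglomerative complete-linkage clustering of matrix rows (euclidean).

    Ternary states are treated as numeric 0/1/2.  Returns the scipy linkage
    (merge order and heights) plus the leaf ordering used for matrix export.
    """
    if matrix.shape[0] < 2:
        raise CladepanError("need at least 2 rows to cluster")
    data = matrix.to_numpy(dtype=float)
    linkage = hierarchy.linkage(pdist(data, metric="euclidean"), method="complete")
    order = hierarchy.leaves_list(linkage)
    labels = [str(x) for x in matrix.index]
    return Dendrogram(
        labels=labels,
        linkage=linkage,
        leaf_order=[labels[i] for i in order],
    )
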