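"""Neighbor-joining trees, bootstrap clade support, Newick IO and tree queries.

The NJ implementation follows the canonical agglomerative scheme: at each
step join the pair (i, j) minimizing

    Q(i, j) = (r - 2) d(i, j) - R(i) - R(j)

where r is the number of active nodes and R the row sum of the current
distance matrix.  Pendant branch lengths are

    v_i = d(i, j) / 2 + (R(i) - R(j)) / (2 (r - 2))

and the reduced distances d(u, k) = (d(i,k) + d(j,k) - d(i,j)) / 2.  Ties in
Q are broken by the lexicographically smallest (i, j) pair in current label
order, so the tree is reproducible across runs and platforms.  On an additive
matrix this recovers the generating topology and branch lengths exactly.

Trees are held as dendropy objects wrapped in :class:`PhyloTree`; the final
join leaves a trifurcating seed node ("last-join" display root) and the tree
is otherwise unrooted.  Bootstrap support for an internal edge is the
percentage of column-resampled replicate trees containing the same
bipartition of the leaf set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np

from .errors import InputError, NewickParseError
from .distances import DistanceMatrix, distance_matrix
from .taxdata import Alignment

Bipartition = frozenset  # frozenset of leaf labels on one side of an edge


@dataclass
class PhyloTree:
    """An (un)rooted tree with branch lengths and optional bootstrap supports.

    ``supports`` maps canonical bipartitions (the side not containing the
    reference leaf, as a frozenset of labels) to percentages in [0, 100].
    """

    tree: dendropy.Tree
    supports: Optional[dict[Bipartition, float]] = None
    rooting: str = "last-join"

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(
            lf.taxon.label for lf in self.tree.leaf_node_iter()
        )

    def _reference_leaf(self) -> str:
        return min(self.leaf_labels)

    def bipartitions(self) -> set[Bipartition]:
        """Non-trivial bipartitions, each canonicalized to the side not
        containing the lexicographically smallest leaf label."""
        all_labels = set(self.leaf_labels)
        ref = self._reference_leaf()
        n = len(all_labels)
        out: set[Bipartition] = set()
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            below = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
            side = below if ref not in below else frozenset(all_labels - below)
            if 2 <= len(side) <= n - 2:
                out.add(side)
        return out

    def clone(self) -> "PhyloTree":
        return PhyloTree(
            tree=self.tree.clone(depth=1),
            supports=dict(self.supports) if self.supports else None,
            rooting=self.rooting,
        )


def nj_build(
    matrix: DistanceMatrix, negative_branch_policy: str = "clamp-to-zero"
) -> PhyloTree:
    """Build a neighbor-joining tree from a distance matrix.

    Negative branch lengths (possible on non-additive input) are clamped to
    zero under the default policy; ``"keep"`` preserves raw values.
    """
    if negative_branch_policy not in ("clamp-to-zero", "keep"):
        raise InputError(f"unknown branch policy: {negative_branch_policy!r}")
    clamp = negative_branch_policy == "clamp-to-zero"
    n = len(matrix)
    if n < 2:
        raise InputError("neighbor joining requires at least 2 taxa")

    taxa = dendropy.TaxonNamespace([str(lab) for lab in matrix.labels])
    tree = dendropy.Tree(taxon_namespace=taxa)

    def leaf(i: int) -> dendropy.Node:
        node = dendropy.Node(taxon=taxa.get_taxon(str(matrix.labels[i])))
        return node

    def fix(x: float) -> float:
        return max(0.0, x) if clamp else x

    if n == 2:
        d = float(matrix.d[0, 1])
        root = tree.seed_node
        for i in (0, 1):
            child = leaf(i)
            root.add_child(child)
            child.edge.length = fix(d / 2.0)
        tree.is_rooted = False
        return PhyloTree(tree=tree)

    D = matrix.d.astype(float).copy()
    active = [leaf(i) for i in range(n)]

    while len(active) > 3:
        r = len(active)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        iu = np.triu_indices(r, k=1)
        qvals = Q[iu]
        # argmin over row-major upper triangle = lexicographically smallest tie
        k = int(np.argmin(qvals))
        i, j = int(iu[0][k]), int(iu[1][k])

        dij = D[i, j]
        vi = dij / 2.0 + (R[i] - R[j]) / (2.0 * (r - 2))
        vj = dij - vi
        u = dendropy.Node()
        u.add_child(active[i])
        active[i].edge.length = fix(vi)
        u.add_child(active[j])
        active[j].edge.length = fix(vj)

        du = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [t for t in range(r) if t not in (i, j)]
        newD = np.empty((r - 1, r - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = du[keep]
        newD[:-1, -1] = du[keep]
        newD[-1, -1] = 0.0
        D = newD
        active = [active[t] for t in keep] + [u]

    root = tree.seed_node
    if len(active) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        v = [
            (d01 + d02 - d12) / 2.0,
            (d01 + d12 - d02) / 2.0,
            (d02 + d12 - d01) / 2.0,
        ]
        for node, length in zip(active, v):
            root.add_child(node)
            node.edge.length = fix(length)
    tree.is_rooted = False
    return PhyloTree(tree=tree)


def bootstrap_support(
    alignment: Alignment,
    policy: str = "pairwise",
    n_reps: int = 1000,
    seed: int = 0,
    negative_branch_policy: str = "clamp-to-zero",
) -> PhyloTree:
    """NJ point-estimate tree with bootstrap supports on internal edges.

    Each replicate resamples alignment columns with replacement, recomputes
    the distance matrix and NJ tree, and contributes its bipartitions.
    Replicate r draws from a stream seeded by (seed, r), so partial re-runs
    agree.  Supports are percentages of ``n_reps``.
    """
    if n_reps < 1:
        raise InputError("bootstrap requires n_reps >= 1")
    point = nj_build(
        distance_matrix(alignment, policy=policy),
        negative_branch_policy=negative_branch_policy,
    )
    target = point.bipartitions()
    counts = {bp: 0 for bp in target}
    L = alignment.n_columns
    records = list(alignment)
    for rep in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence((seed, rep)))
        cols = rng.integers(0, L, size=L)
        resampled = Alignment(
            records=tuple(
                rec.__class__(
                    accession=rec.accession,
                    residues="".join(rec.residues[c] for c in cols),
                    is_fragment=rec.is_fragment,
                    lineage=rec.lineage,
                )
                for rec in records
            )
        )
        rep_tree = nj_build(
            distance_matrix(resampled, policy=policy, mode="permissive"),
            negative_branch_policy=negative_branch_policy,
        )
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    point.supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    _annotate_supports(point)
    return point


def _annotate_supports(ptree: PhyloTree) -> None:
    """Copy supports onto internal node labels for Newick serialization."""
    if ptree.supports is None:
        return
    all_labels = set(ptree.leaf_labels)
    ref = min(all_labels)
    n = len(all_labels)
    for node in ptree.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if ref not in below else frozenset(all_labels - below)
        if 2 <= len(side) <= n - 2 and side in ptree.supports:
            sup = ptree.supports[side]
            node.label = f"{sup:g}"


def write_newick(ptree: PhyloTree, path) -> None:
    """Write Newick with 6-decimal branch lengths and supports as labels."""
    _annotate_supports(ptree)
    s = ptree.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6f",
        unquoted_underscores=True,
    )
    with open(path, "w") as fh:
        fh.write(s)


def read_newick(path) -> PhyloTree:
    """Read a Newick file; internal node labels are interpreted as supports."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise NewickParseError(f"failed to parse Newick file {path}: {exc}") from exc
    ptree = PhyloTree(tree=tree)
    supports: dict[Bipartition, float] = {}
    all_labels = set(ptree.leaf_labels)
    ref = min(all_labels)
    n = len(all_labels)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None or node.label is None:
            continue
        try:
            sup = float(node.label)
        except ValueError:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = below if ref not in below else frozenset(all_labels - below)
        if 2 <= len(side) <= n - 2:
            supports[side] = sup
    ptree.supports = supports or None
    return ptree


def _path_between(u: dendropy.Node, v: dendropy.Node) -> list[dendropy.Node]:
    """Node path from leaf u to leaf v through their MRCA (seed-node rooted)."""
    up = []
    node = u
    while node is not None:
        up.append(node)
        node = node.parent_node
    seen = {id(n): i for i, n in enumerate(up)}
    down = []
    node = v
    while id(node) not in seen:
        down.append(node)
        node = node.parent_node
    return up[: seen[id(node)] + 1] + list(reversed(down))


def _midpoint_rooted(ptree: PhyloTree) -> dendropy.Tree:
    """Root a clone of the tree at the midpoint of its longest leaf-leaf path.

    When the midpoint falls (within tolerance) on an existing internal node
    the tree is rerooted at that node, so no spurious degree-2 root is
    introduced; otherwise a new root node is created inside the edge.
    """
    t = ptree.tree.clone(depth=1)
    leaves = sorted(t.leaf_node_iter(), key=lambda lf: lf.taxon.label)
    # longest leaf-leaf path (deterministic tie-break by label order)
    best = None
    pdm = t.phylogenetic_distance_matrix()
    for i, u in enumerate(leaves):
        for v in leaves[i + 1 :]:
            dist = pdm.distance(u.taxon, v.taxon)
            if best is None or dist > best[0] + 1e-15:
                best = (dist, u, v)
    total, u, v = best
    path = _path_between(u, v)
    # cumulative distance from u at each path node
    cum = [0.0]
    for a, b in zip(path, path[1:]):
        # consecutive path nodes are parent/child of each other
        child = b if b.parent_node is a else a
        cum.append(cum[-1] + (child.edge.length or 0.0))
    half = total / 2.0
    tol = 1e-9 * max(total, 1.0)
    for idx in range(len(path) - 1):
        if cum[idx + 1] >= half - tol:
            a, b = path[idx], path[idx + 1]
            for node, c in ((a, cum[idx]), (b, cum[idx + 1])):
                if abs(c - half) <= tol and not node.is_leaf():
                    t.reroot_at_node(node, suppress_unifurcations=True)
                    return t
            child = b if b.parent_node is a else a
            into_edge = half - cum[idx]  # distance from a along the edge
            elen = child.edge.length or 0.0
            if child is b:
                l_child, l_parent = elen - into_edge, into_edge
            else:
                l_child, l_parent = into_edge, elen - into_edge
            t.reroot_at_edge(
                child.edge,
                length1=l_parent,
                length2=l_child,
                suppress_unifurcations=True,
            )
            return t
    t.reroot_at_node(path[len(path) // 2], suppress_unifurcations=True)
    return t


def count_bifurcations(
    ptree: PhyloTree, leaf: str, rooting: str = "midpoint"
) -> int:
    """Number of internal nodes on the display-root-to-leaf path.

    The display root counts; the leaf does not.  ``rooting`` selects the
    display convention: ``"midpoint"`` or ``"last-join"`` (the seed node left
    by the final NJ join).
    """
    if len(ptree.leaf_labels) < 3:
        raise InputError("bifurcation counts need at least 3 leaves")
    if rooting == "midpoint":
        tree = _midpoint_rooted(ptree)
    elif rooting == "last-join":
        tree = ptree.tree
    else:
        raise InputError(f"unknown rooting policy: {rooting!r}")
    node = None
    for lf in tree.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == leaf:
            node = lf
            break
    if node is None:
        raise InputError(f"leaf {leaf!r} not present in tree")
    count = 0
    node = node.parent_node
    while node is not None:
        if len(node.child_nodes()) >= 2:
            count += 1
        node = node.parent_node
    return count
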