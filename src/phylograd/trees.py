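"""Rooted bifurcating phylogenies, Newick I/O, and traversal schedules.

Node-index convention
---------------------
Internally nodes are numbered 0-based: tips ``0 .. N-1`` in order of first
appearance in the Newick string, internal non-root nodes ``N .. 2N-3`` in
post-order, and the root ``2N-2``.  Branches are indexed by their child
node, so there are exactly ``2N-2`` branch lengths and the root carries
none.  Reports aimed at humans use the equivalent 1-based labelling (tips
``1..N``, root ``2N-1``) via :meth:`Phylogeny.paper_label`.

Newick parsing is delegated to dendropy; this module enforces the strict
bifurcation contract (polytomies are rejected, with the offending node
reported) and mandatory branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .exceptions import (
    InvalidParameterError,
    ParseError,
    UnsupportedTopologyError,
)

__all__ = [
    "Phylogeny",
    "TraversalSchedule",
    "parse_newick",
    "write_newick",
    "traversal_schedule",
    "reroot",
    "tip_distance_matrix",
]


@dataclass
class Phylogeny:
    """Rooted strictly bifurcating tree with branch lengths indexed by child."""

    taxon_names: list[str]
    parent: np.ndarray  # (2N-1,) int; -1 at the root
    children: np.ndarray  # (2N-1, 2) int; -1 at tips
    branch_lengths: np.ndarray  # (2N-1,) float; entry at the root unused (0.0)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_taxa - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def is_tip(self, i: int) -> bool:
        return i < self.n_taxa

    def paper_label(self, i: int) -> int:
        """1-based node label (tips 1..N, internals N+1..2N-2, root 2N-1)."""
        return i + 1

    def sibling(self, i: int) -> int:
        k = self.parent[i]
        a, b = self.children[k]
        return b if a == i else a

    def validate(self) -> None:
        N = self.n_taxa
        if N < 2:
            raise InvalidParameterError("a phylogeny needs at least two taxa")
        if len(set(self.taxon_names)) != N:
            raise InvalidParameterError("duplicate taxon names")
        M = self.n_nodes
        if self.parent.shape != (M,) or self.children.shape != (M, 2):
            raise InvalidParameterError("parent/children arrays have wrong shape")
        if self.parent[self.root] != -1:
            raise InvalidParameterError("root must have no parent")
        seen = np.zeros(M, dtype=bool)
        for i in range(M - 1):
            k = self.parent[i]
            if not (0 <= k < M) or self.is_tip(k):
                raise InvalidParameterError(f"node {i} has invalid parent {k}")
            if i not in self.children[k]:
                raise InvalidParameterError(f"parent/children maps disagree at node {i}")
            seen[i] = True
        for k in range(N, M):
            a, b = self.children[k]
            if a < 0 or b < 0 or a == b:
                raise UnsupportedTopologyError(
                    f"internal node {k} does not have two children", node=k
                )
        # connectivity / acyclicity: every non-root node must reach the root
        for i in range(M - 1):
            j, steps = i, 0
            while j != self.root:
                j = self.parent[j]
                steps += 1
                if steps > M:
                    raise InvalidParameterError("cycle detected in parent map")
        b = self.branch_lengths[: M - 1]
        if not np.all(np.isfinite(b)) or np.any(b < 0):
            raise InvalidParameterError("branch lengths must be finite and >= 0")


@dataclass
class TraversalSchedule:
    """Dependency-respecting visit orders for the two passes.

    ``postorder``: (parent k, child i, child j) triples, children before
    parents, one per internal node.  ``preorder``: (node i, parent k,
    sibling j) triples, parents before children, tips included and root
    excluded (2N-2 entries).
    """

    postorder: list[tuple[int, int, int]]
    preorder: list[tuple[int, int, int]]


def parse_newick(text: str) -> Phylogeny:
    """Parse a rooted bifurcating Newick string with mandatory branch lengths.

    Taxon order is the order of first appearance.  Quoted labels and
    bracketed comments are accepted; internal-node labels are ignored.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"malformed Newick: {exc}") from exc

    leaves = list(dtree.leaf_node_iter())
    names = [lf.taxon.label if lf.taxon else None for lf in leaves]
    if any(n is None for n in names):
        raise ParseError("tip without a taxon label")
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ParseError(f"duplicate taxon name(s): {dup}")
    N = len(names)
    if N < 2:
        raise ParseError("need at least two taxa")

    index: dict[int, int] = {}
    for i, lf in enumerate(leaves):
        index[id(lf)] = i
    nxt = N
    for nd in dtree.postorder_node_iter():
        if nd.is_leaf():
            continue
        kids = nd.child_nodes()
        if len(kids) != 2:
            raise UnsupportedTopologyError(
                f"node with {len(kids)} children (polytomy or unifurcation) "
                f"near taxa {[t.taxon.label for t in nd.leaf_iter()][:3]}",
                node=nxt,
            )
        index[id(nd)] = nxt
        nxt += 1

    M = 2 * N - 1
    parent = np.full(M, -1, dtype=np.int64)
    children = np.full((M, 2), -1, dtype=np.int64)
    lengths = np.zeros(M)
    for nd in dtree.postorder_node_iter():
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise ParseError(f"missing branch length above node {i + 1}")
            lengths[i] = float(nd.edge.length)
        if not nd.is_leaf():
            a, b = nd.child_nodes()
            children[i] = (index[id(a)], index[id(b)])
    tree = Phylogeny(
        taxon_names=list(names), parent=parent, children=children, branch_lengths=lengths
    )
    tree.validate()
    return tree


def _subtree_newick(tree: Phylogeny, i: int) -> str:
    if tree.is_tip(i):
        label = tree.taxon_names[i]
        if any(ch in label for ch in " (),:;[]'"):
            label = "'" + label.replace("'", "''") + "'"
        body = label
    else:
        a, b = tree.children[i]
        body = f"({_subtree_newick(tree, a)},{_subtree_newick(tree, b)})"
    if i == tree.root:
        return body
    return f"{body}:{tree.branch_lengths[i]:.17g}"


def write_newick(tree: Phylogeny) -> str:
    """Newick string with full-precision branch lengths."""
    return _subtree_newick(tree, tree.root) + ";"


def traversal_schedule(tree: Phylogeny) -> TraversalSchedule:
    """Compute post- and pre-order visit schedules by explicit DFS."""
    post: list[tuple[int, int, int]] = []
    pre: list[tuple[int, int, int]] = []
    # iterative DFS from the root
    stack = [(tree.root, False)]
    order: list[int] = []  # preorder node sequence
    while stack:
        node, processed = stack.pop()
        if processed:
            a, b = tree.children[node]
            post.append((node, a, b))
            continue
        order.append(node)
        if not tree.is_tip(node):
            stack.append((node, True))
            a, b = tree.children[node]
            stack.append((b, False))
            stack.append((a, False))
    for node in order:
        if node == tree.root:
            continue
        pre.append((node, int(tree.parent[node]), tree.sibling(node)))
    return TraversalSchedule(postorder=post, preorder=pre)


def tip_distance_matrix(tree: Phylogeny) -> np.ndarray:
    """Pairwise path lengths between tips (invariant under rerooting)."""
    N, M = tree.n_taxa, tree.n_nodes
    # distance from every node up to each ancestor via accumulated depths
    depth = np.zeros(M)
    sched = traversal_schedule(tree)
    for i, k, _ in sched.preorder:
        depth[i] = depth[k] + tree.branch_lengths[i]
    # ancestor sets per tip
    anc: list[dict[int, float]] = []
    for t in range(N):
        d: dict[int, float] = {}
        j = t
        while j != -1:
            d[j] = depth[j]
            j = int(tree.parent[j])
        anc.append(d)
    D = np.zeros((N, N))
    for a in range(N):
        for b in range(a + 1, N):
            common = anc[a].keys() & anc[b].keys()
            mrca_depth = max(anc[a][c] for c in common)
            D[a, b] = D[b, a] = depth[a] + depth[b] - 2 * mrca_depth
    return D


def _build_from_adjacency(
    adj: dict[int, list[tuple[int, float]]],
    new_root: int,
    tip_ids: dict[int, int],
    taxon_names: list[str],
) -> Phylogeny:
    """Orient an undirected tree away from ``new_root`` and renumber nodes.

    Tips keep their original indices; internal nodes are renumbered in
    post-order with the root last.
    """
    N = len(taxon_names)
    M = 2 * N - 1
    parent_of: dict[int, tuple[int, float]] = {}
    children_of: dict[int, list[int]] = {k: [] for k in adj}
    stack = [new_root]
    seen = {new_root}
    dfs_post: list[int] = []
    order = []
    while stack:
        u = stack.pop()
        order.append(u)
        for v, w in adj[u]:
            if v in seen:
                continue
            seen.add(v)
            parent_of[v] = (u, w)
            children_of[u].append(v)
            stack.append(v)
    # post-order via reversed preorder (children recorded before parents pop)
    visited = []
    stack = [(new_root, False)]
    while stack:
        u, done = stack.pop()
        if done:
            dfs_post.append(u)
            continue
        stack.append((u, True))
        for v in children_of[u]:
            stack.append((v, False))

    new_index: dict[int, int] = {}
    nxt = N
    for u in dfs_post:
        if u in tip_ids:
            new_index[u] = tip_ids[u]
        elif u == new_root:
            new_index[u] = M - 1
        else:
            new_index[u] = nxt
            nxt += 1

    parent = np.full(M, -1, dtype=np.int64)
    children = np.full((M, 2), -1, dtype=np.int64)
    lengths = np.zeros(M)
    for u, (p, w) in parent_of.items():
        iu, ip = new_index[u], new_index[p]
        parent[iu] = ip
        lengths[iu] = w
        slot = 0 if children[ip, 0] == -1 else 1
        children[ip, slot] = iu
    tree = Phylogeny(
        taxon_names=list(taxon_names), parent=parent, children=children, branch_lengths=lengths
    )
    tree.validate()
    return tree


def reroot(tree: Phylogeny, new_root_branch: int, split: float = 0.5) -> Phylogeny:
    """Re-root on the branch above node ``new_root_branch``.

    The old root (a degree-2 vertex of the unrooted topology) is suppressed,
    its two child branches merged, and a new root inserted on the chosen
    branch at fraction ``split`` from the child end.  Pairwise tip path
    lengths are preserved exactly; for a reversible model with stationary
    root prior the likelihood is invariant (pulley principle).
    """
    if not (0 <= new_root_branch < tree.n_nodes - 1):
        raise InvalidParameterError(f"invalid branch id {new_root_branch}")
    if not (0.0 <= split <= 1.0):
        raise InvalidParameterError("split must lie in [0, 1]")

    root = tree.root
    c1, c2 = (int(c) for c in tree.children[root])
    merged_len = tree.branch_lengths[c1] + tree.branch_lengths[c2]

    # undirected adjacency over original node ids, old root suppressed
    adj: dict[int, list[tuple[int, float]]] = {
        i: [] for i in range(tree.n_nodes) if i != root
    }
    for i in range(tree.n_nodes - 1):
        k = int(tree.parent[i])
        if k == root:
            continue
        adj[i].append((k, float(tree.branch_lengths[i])))
        adj[k].append((i, float(tree.branch_lengths[i])))

    new_root_id = tree.n_nodes  # temporary id for the inserted root
    adj[new_root_id] = []

    def connect(u: int, v: int, w: float) -> None:
        adj[u].append((v, w))
        adj[v].append((u, w))

    if new_root_branch in (c1, c2):
        # target is the merged edge between the old root's children
        x = new_root_branch
        y = c2 if x == c1 else c1
        d = split * merged_len
        connect(new_root_id, x, d)
        connect(new_root_id, y, merged_len - d)
    else:
        connect(c1, c2, merged_len)
        x = new_root_branch
        p = int(tree.parent[x])
        b = float(tree.branch_lengths[x])
        adj[x] = [(v, w) for v, w in adj[x] if v != p]
        adj[p] = [(v, w) for v, w in adj[p] if v != x]
        connect(new_root_id, x, split * b)
        connect(new_root_id, p, (1.0 - split) * b)

    tip_ids = {t: t for t in range(tree.n_taxa)}
    return _build_from_adjacency(adj, new_root_id, tip_ids, tree.taxon_names)
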