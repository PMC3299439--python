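"""Unrooted binary phylogenetic trees with per-edge JC substitution probabilities.

Trees are stored unrooted (every internal node has degree 3); likelihood code
roots them arbitrarily, which is harmless because the Jukes-Cantor process is
time-reversible with a uniform stationary distribution.  Edges are identified
by their leaf-label bipartition, canonicalised as the side that does NOT
contain the lexicographically smallest taxon, so edge parameters survive any
re-traversal or re-parse of the same topology.

Branch "lengths" in Newick carry the per-edge substitution probability
p(e) ∈ [0, 3/4], not expected numbers of substitutions.
"""

from __future__ import annotations

import io
import itertools
from typing import Dict, FrozenSet, Iterator, List, Optional, Sequence, Tuple

import dendropy

__all__ = [
    "PhyloTree",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "enumerate_unrooted_topologies",
    "rf_distance",
    "n_unrooted_topologies",
    "compose_jc",
]

Split = FrozenSet[str]

P_MAX = 0.75


class NewickParseError(ValueError):
    """Raised for malformed Newick input (with a hint at the offending part)."""


def compose_jc(p: float, q: float) -> float:
    """Probability of net change across two JC edges in series.

    M(p) @ M(q) = M(p + q - 4pq/3); used when suppressing a degree-2 root.
    """
    return p + q - 4.0 * p * q / 3.0


def _check_p(p: float, context: str = "") -> float:
    p = float(p)
    if not (0.0 <= p <= P_MAX):
        raise ValueError(
            f"edge substitution probability must lie in [0, 3/4], got {p}"
            + (f" ({context})" if context else "")
        )
    return p


class PhyloTree:
    """A leaf-labelled unrooted binary tree topology with edge parameters.

    Parameters
    ----------
    adjacency:
        Mapping node id -> iterable of neighbour node ids (symmetric).
    leaf_labels:
        Mapping node id -> taxon label for the leaves (degree-1 nodes).
    edge_params:
        Optional mapping from canonical split (frozenset of labels) to
        p(e) in [0, 3/4].  Missing edges default to 0.
    """

    __slots__ = ("_adj", "_leaf_label", "_label_node", "edge_params", "_splits_cache")

    def __init__(
        self,
        adjacency: Dict[int, Sequence[int]],
        leaf_labels: Dict[int, str],
        edge_params: Optional[Dict[Split, float]] = None,
    ):
        self._adj: Dict[int, Tuple[int, ...]] = {
            u: tuple(sorted(vs)) for u, vs in adjacency.items()
        }
        self._leaf_label = dict(leaf_labels)
        if len(set(self._leaf_label.values())) != len(self._leaf_label):
            raise ValueError("duplicate leaf labels")
        self._label_node = {lab: n for n, lab in self._leaf_label.items()}
        self._splits_cache: Optional[Dict[Tuple[int, int], Split]] = None
        self._validate_shape()
        all_splits = set(self.edge_splits().values())
        self.edge_params: Dict[Split, float] = {s: 0.0 for s in all_splits}
        if edge_params:
            for s, p in edge_params.items():
                s = frozenset(s)
                if s not in self.edge_params:
                    raise ValueError(f"unknown edge split {sorted(s)}")
                self.edge_params[s] = _check_p(p, f"edge {sorted(s)}")

    # -- structure -----------------------------------------------------

    def _validate_shape(self) -> None:
        degs = {u: len(vs) for u, vs in self._adj.items()}
        for u, vs in self._adj.items():
            for v in vs:
                if u not in self._adj.get(v, ()):
                    raise ValueError("adjacency is not symmetric")
        n_leaves = sum(1 for d in degs.values() if d == 1)
        if set(self._leaf_label) != {u for u, d in degs.items() if d == 1}:
            raise ValueError("leaf_labels must cover exactly the degree-1 nodes")
        if n_leaves < 2:
            raise ValueError("a tree needs at least 2 leaves")
        for u, d in degs.items():
            if d not in (1, 3) and not (n_leaves == 2 and d == 1):
                raise ValueError(
                    f"node {u} has degree {d}; unrooted binary trees need degree 1 or 3"
                )
        # connectivity
        seen = set()
        stack = [next(iter(self._adj))]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(self._adj[u])
        if seen != set(self._adj):
            raise ValueError("tree is not connected")

    @property
    def taxa(self) -> Tuple[str, ...]:
        return tuple(sorted(self._label_node))

    @property
    def n_leaves(self) -> int:
        return len(self._label_node)

    def neighbors(self, u: int) -> Tuple[int, ...]:
        return self._adj[u]

    def is_leaf(self, u: int) -> bool:
        return u in self._leaf_label

    def leaf_label(self, u: int) -> str:
        return self._leaf_label[u]

    def nodes(self) -> Tuple[int, ...]:
        return tuple(self._adj)

    def edges(self) -> List[Tuple[int, int]]:
        """All edges as (u, v) node pairs with u < v, sorted."""
        return sorted(
            (min(u, v), max(u, v)) for u in self._adj for v in self._adj[u] if u < v
        )

    def edge_splits(self) -> Dict[Tuple[int, int], Split]:
        """Map each edge (u, v) to its canonical leaf-label split.

        Canonical side = the side not containing the smallest taxon label.
        """
        if self._splits_cache is not None:
            return self._splits_cache
        anchor = min(self._label_node)
        out: Dict[Tuple[int, int], Split] = {}
        for (u, v) in self.edges():
            side = frozenset(self._leaves_beyond(v, u))
            if anchor in side:
                side = frozenset(self._label_node) - side
            out[(u, v)] = side
        self._splits_cache = out
        return out

    def _leaves_beyond(self, start: int, blocked: int) -> Iterator[str]:
        """Labels of leaves reachable from `start` without crossing `blocked`."""
        stack = [(start, blocked)]
        while stack:
            u, parent = stack.pop()
            if self.is_leaf(u):
                yield self._leaf_label[u]
            for w in self._adj[u]:
                if w != parent:
                    stack.append((w, u))

    def nontrivial_splits(self) -> FrozenSet[Split]:
        """Bipartitions induced by internal edges (both sides of size ≥ 2)."""
        n = self.n_leaves
        return frozenset(
            s for s in self.edge_splits().values() if 1 < len(s) < n - 1
        )

    def same_topology(self, other: "PhyloTree") -> bool:
        if set(self.taxa) != set(other.taxa):
            return False
        return self.nontrivial_splits() == other.nontrivial_splits()

    def postorder_edges(
        self, root: Optional[int] = None
    ) -> Tuple[int, List[Tuple[int, int, Split]]]:
        """(root, [(child, parent, split), ...]) with children before parents."""
        if root is None:
            root = self._default_root()
        splits = self.edge_splits()
        order: List[Tuple[int, int, Split]] = []
        stack = [(root, -1)]
        visit: List[Tuple[int, int]] = []
        while stack:
            u, parent = stack.pop()
            visit.append((u, parent))
            for w in self._adj[u]:
                if w != parent:
                    stack.append((w, u))
        for u, parent in reversed(visit):
            if parent != -1:
                key = (min(u, parent), max(u, parent))
                order.append((u, parent, splits[key]))
        return root, order

    def _default_root(self) -> int:
        internal = [u for u in sorted(self._adj) if not self.is_leaf(u)]
        if internal:
            return internal[0]
        return min(self._adj)  # 2-leaf tree: root at a leaf

    def with_edge_params(self, params: Dict[Split, float]) -> "PhyloTree":
        """Copy of this topology with (a subset of) edge parameters replaced."""
        new = dict(self.edge_params)
        for s, p in params.items():
            s = frozenset(s)
            if s not in new:
                raise ValueError(f"unknown edge split {sorted(s)}")
            new[s] = _check_p(p)
        return PhyloTree(self._adj, self._leaf_label, new)

    def set_all_edges(self, p: float) -> "PhyloTree":
        return self.with_edge_params({s: p for s in self.edge_params})

    # -- presentation ---------------------------------------------------

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({write_newick(self, include_params=False)!r})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return self.same_topology(other) and self.edge_params == other.edge_params

    def __hash__(self) -> int:
        return hash((frozenset(self.taxa), self.nontrivial_splits()))


# -- Newick I/O ---------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into an unrooted :class:`PhyloTree`.

    Branch lengths, when present, are read as JC substitution probabilities
    p(e) and must lie in [0, 3/4].  A bifurcating (rooted) outermost node is
    suppressed, composing its two incident edges' probabilities as a serial
    JC channel.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    labels = [lf.taxon.label if lf.taxon else None for lf in dtree.leaf_node_iter()]
    if any(lab is None for lab in labels):
        raise NewickParseError("every leaf must carry a label")
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickParseError(f"duplicate leaf labels: {dup}")
    if len(labels) < 2:
        raise NewickParseError("need at least 2 leaves")

    # Build adjacency; collapse the root if it has exactly 2 children.
    adjacency: Dict[int, List[int]] = {}
    leaf_labels: Dict[int, str] = {}
    ids: Dict[object, int] = {}
    edge_p: Dict[Tuple[int, int], float] = {}

    def nid(node) -> int:
        if node not in ids:
            ids[node] = len(ids)
            adjacency[ids[node]] = []
        return ids[node]

    for node in dtree.preorder_node_iter():
        u = nid(node)
        if node.is_leaf():
            leaf_labels[u] = node.taxon.label
        for child in node.child_nodes():
            v = nid(child)
            adjacency[u].append(v)
            adjacency[v].append(u)
            p = child.edge.length if child.edge.length is not None else 0.0
            try:
                p = _check_p(p, f"edge above {child.taxon.label if child.taxon else 'internal node'}")
            except ValueError as exc:
                raise NewickParseError(str(exc)) from exc
            key = (min(u, v), max(u, v))
            edge_p[key] = p

    root = ids[dtree.seed_node]
    if len(adjacency[root]) == 2:
        a, b = adjacency[root]
        pa = edge_p.pop((min(root, a), max(root, a)))
        pb = edge_p.pop((min(root, b), max(root, b)))
        adjacency[a] = [x if x != root else b for x in adjacency[a]]
        adjacency[b] = [x if x != root else a for x in adjacency[b]]
        del adjacency[root]
        edge_p[(min(a, b), max(a, b))] = compose_jc(pa, pb)
    elif len(adjacency[root]) not in (3,) and len(adjacency) > 2:
        # root with 1 child ("((a,b));" style) or multifurcation
        if len(adjacency[root]) == 1:
            raise NewickParseError("outermost node has a single child; not binary")

    tree = _build_validated(adjacency, leaf_labels, edge_p)
    return tree


def _build_validated(adjacency, leaf_labels, edge_p) -> PhyloTree:
    try:
        skeleton = PhyloTree(adjacency, leaf_labels)
    except ValueError as exc:
        raise NewickParseError(str(exc)) from exc
    splits = skeleton.edge_splits()
    params = {splits[k]: p for k, p in edge_p.items()}
    return PhyloTree(adjacency, leaf_labels, params)


def write_newick(tree: PhyloTree, include_params: bool = True) -> str:
    """Serialise a tree to Newick, branch lengths = p(e) (full precision)."""
    root = tree._default_root()
    splits = tree.edge_splits()

    def fmt(u: int, parent: int) -> str:
        if tree.is_leaf(u):
            body = tree.leaf_label(u)
        else:
            kids = [w for w in tree.neighbors(u) if w != parent]
            body = "(" + ",".join(fmt(w, u) for w in sorted(kids)) + ")"
        if parent == -1:
            return body
        if not include_params:
            return body
        key = (min(u, parent), max(u, parent))
        p = tree.edge_params[splits[key]]
        return f"{body}:{p!r}"

    if tree.n_leaves == 2:
        a, b = sorted(tree._label_node)
        p = next(iter(tree.edge_params.values()))
        if include_params:
            return f"({a}:{p!r},{b}:0.0);"
        return f"({a},{b});"
    return fmt(root, -1) + ";"


# -- enumeration and comparison -----------------------------------------


def n_unrooted_topologies(n: int) -> int:
    """(2n-5)!! — the number of distinct unrooted binary topologies."""
    if n < 3:
        raise ValueError("need at least 3 taxa")
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out


def enumerate_unrooted_topologies(taxa: Sequence[str]) -> Iterator[PhyloTree]:
    """Yield every unrooted binary topology on `taxa` exactly once.

    Stepwise addition: each tree on the first k taxa is extended by attaching
    the (k+1)-th taxon to every edge.  Deterministic order (taxa sorted).
    """
    taxa = sorted(set(taxa))
    if len(taxa) < 3:
        raise ValueError(f"topology enumeration needs ≥ 3 taxa, got {len(taxa)}")

    # seed: the unique 3-leaf star. nodes 0..2 leaves, 3 internal
    seed_adj = {0: [3], 1: [3], 2: [3], 3: [0, 1, 2]}
    seed_leaves = {0: taxa[0], 1: taxa[1], 2: taxa[2]}

    def grow(adj, leaves, next_taxon_idx) -> Iterator[PhyloTree]:
        if next_taxon_idx == len(taxa):
            yield PhyloTree(adj, leaves)
            return
        label = taxa[next_taxon_idx]
        edges = sorted(
            (min(u, v), max(u, v)) for u in adj for v in adj[u] if u < v
        )
        for (u, v) in edges:
            mid = max(adj) + 1
            tip = mid + 1
            new_adj = {k: [x for x in vs] for k, vs in adj.items()}
            new_adj[u] = [x if x != v else mid for x in new_adj[u]]
            new_adj[v] = [x if x != u else mid for x in new_adj[v]]
            new_adj[mid] = [u, v, tip]
            new_adj[tip] = [mid]
            new_leaves = dict(leaves)
            new_leaves[tip] = label
            yield from grow(new_adj, new_leaves, next_taxon_idx + 1)

    yield from grow(seed_adj, seed_leaves, 3)


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds distance: |symmetric difference of non-trivial splits|."""
    if set(t1.taxa) != set(t2.taxa):
        raise ValueError("trees must share an identical leaf set")
    return len(t1.nontrivial_splits() ^ t2.nontrivial_splits())
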