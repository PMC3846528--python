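"""Tree primitives: Newick I/O, bipartitions, monophyly, distance summaries.

Gene trees are consumed as unrooted, possibly multifurcating topologies with
bootstrap support values (BSV, 0-100) attached to internal edges, encoded in
the common supports-as-internal-node-labels Newick dialect.  All clade
questions are answered on bipartitions, never on a rooted topology, so
results are invariant under re-rooting and Newick rotation.

Parsing and bipartition encoding are delegated to dendropy; the unrooted
monophyly test, the adjacency view used by the transfer classifier, and the
alignment distance summary are implemented here.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field

import dendropy

__all__ = [
    "AnnotatedTree",
    "TaxonMap",
    "Bipartition",
    "AlignmentDistanceSummary",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "is_monophyletic",
    "alignment_distance_summary",
    "parse_taxon_map",
]


class NewickParseError(ValueError):
    """Unreadable Newick text (unbalanced parentheses, duplicate labels...)."""


@dataclass(frozen=True)
class Bipartition:
    """The two leaf sets separated by one internal edge, with its support."""

    side_a: frozenset[str]
    side_b: frozenset[str]
    support: int | None = None

    def __post_init__(self) -> None:
        if not self.side_a or not self.side_b or self.side_a & self.side_b:
            raise ValueError("bipartition sides must be disjoint and non-empty")

    def key(self) -> frozenset[frozenset[str]]:
        """Orientation-free identity of the split."""
        return frozenset({self.side_a, self.side_b})


@dataclass(frozen=True)
class AlignmentDistanceSummary:
    max_pct: float
    median_pct: float
    n_pairs: int


#: label -> (domain, group); domain in {Bacteria, Archaea, Eukaryota}
TaxonMap = dict


def parse_taxon_map(text: str) -> TaxonMap:
    """Read a 3-column TSV (label, domain, group) into a TaxonMap."""
    out: TaxonMap = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        label, domain, group = line.rstrip("\n").split("\t")[:3]
        out[label] = (domain, group)
    return out


class AnnotatedTree:
    """Unrooted multifurcating gene tree with edge supports.

    Thin wrapper over a dendropy tree that exposes an adjacency view keyed by
    leaf labels, so downstream code never depends on dendropy's internal
    rooting of the Newick string.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._dtree = dtree
        self.leaves: list[str] = [
            lf.taxon.label for lf in dtree.leaf_node_iter()
        ]
        if len(self.leaves) != len(set(self.leaves)):
            raise NewickParseError("duplicate leaf labels")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._dtree

    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaves)

    def __len__(self) -> int:
        return len(self.leaves)


def _support_of(node: dendropy.Node) -> int | None:
    """Bootstrap support encoded as the internal node label."""
    lbl = node.label
    if lbl is None:
        return None
    try:
        v = int(float(lbl))
    except ValueError:
        return None
    if not 0 <= v <= 100:
        raise NewickParseError(f"support {lbl!r} outside [0, 100]")
    return v


def parse_newick(text: str) -> AnnotatedTree:
    """Parse Newick text; supports are internal node labels.

    Raises :class:`NewickParseError` for malformed input or duplicate leaf
    labels.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as e:  # dendropy raises several error types
        raise NewickParseError(str(e)) from e
    if any(lf.taxon is None for lf in dtree.leaf_node_iter()):
        raise NewickParseError("leaf without label")
    dtree.is_rooted = False
    return AnnotatedTree(dtree)


def write_newick(tree: AnnotatedTree) -> str:
    """Serialize back to Newick, keeping supports as internal node labels."""
    s = tree.dendropy_tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return s.strip() + ("" if s.strip().endswith(";") else ";")


def _nontrivial_edges(tree: AnnotatedTree):
    """Internal edges as (leafset-of-child-side, support) pairs."""
    dtree = tree.dendropy_tree
    all_leaves = tree.leaf_set()
    out = []
    for node in dtree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(below) <= 1 or len(all_leaves - below) <= 1:
            continue  # trivial split (leaf edge or root artifact)
        out.append((below, _support_of(node)))
    return out


def bipartitions(tree: AnnotatedTree) -> list[Bipartition]:
    """All non-trivial bipartitions (one per internal edge) with supports.

    A binary unrooted n-leaf tree yields n-3 of them; a star tree none.
    """
    if len(tree) < 3:
        raise ValueError("bipartitions need at least 3 leaves")
    all_leaves = tree.leaf_set()
    seen: dict[frozenset, Bipartition] = {}
    for below, sup in _nontrivial_edges(tree):
        bp = Bipartition(side_a=below, side_b=all_leaves - below, support=sup)
        k = bp.key()
        if k not in seen:  # basal child of dendropy's root duplicates a split
            seen[k] = bp
        elif seen[k].support is None and sup is not None:
            seen[k] = bp
    return list(seen.values())


def is_monophyletic(
    tree: AnnotatedTree, query: frozenset[str] | set[str]
) -> tuple[bool, int | None]:
    """Unrooted convexity: can a single edge cut separate exactly ``query``?

    Returns the separating edge's support when true (None for a single leaf,
    whose pendant edge carries no support).  Symmetric in query/complement.
    """
    query = frozenset(query)
    all_leaves = tree.leaf_set()
    if not query or not query <= all_leaves:
        raise ValueError("query must be a non-empty subset of the leaves")
    if query == all_leaves:
        raise ValueError("query equals the full leaf set")
    if len(query) == 1 or len(all_leaves - query) == 1:
        return True, None
    for bp in bipartitions(tree):
        if query in (bp.side_a, bp.side_b):
            return True, bp.support
    return False, None


def alignment_distance_summary(
    aligned_sequences: list[str],
) -> AlignmentDistanceSummary:
    """Max and median pairwise percent difference over an alignment.

    Columns where either sequence of a pair carries a gap ('-' or '.') are
    skipped for that pair; a pair with no comparable columns is excluded with
    a warning.  The median of an even pair count is the mean of the two
    central values.
    """
    if len(aligned_sequences) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(aligned_sequences[0])
    if any(len(s) != n for s in aligned_sequences):
        raise ValueError("sequences must have equal lengths")
    gaps = {"-", "."}
    dists: list[float] = []
    for i in range(len(aligned_sequences)):
        for j in range(i + 1, len(aligned_sequences)):
            a, b = aligned_sequences[i], aligned_sequences[j]
            comparable = diff = 0
            for x, y in zip(a, b):
                if x in gaps or y in gaps:
                    continue
                comparable += 1
                if x != y:
                    diff += 1
            if comparable == 0:
                warnings.warn(
                    f"sequence pair ({i}, {j}) has no comparable columns; excluded"
                )
                continue
            dists.append(100.0 * diff / comparable)
    if not dists:
        raise ValueError("no comparable sequence pairs")
    return AlignmentDistanceSummary(
        max_pct=max(dists),
        median_pct=float(statistics.median(dists)),
        n_pairs=len(dists),
    )


# ---------------------------------------------------------------------------
# Adjacency view for the transfer classifier
# ---------------------------------------------------------------------------

@dataclass
class _Adj:
    """Unrooted adjacency structure with per-edge supports and leaf sets."""

    neighbors: dict[int, list[int]] = field(default_factory=dict)
    edge_support: dict[frozenset[int], int | None] = field(default_factory=dict)
    leaf_label: dict[int, str] = field(default_factory=dict)

    def side_leaves(self, a: int, b: int) -> frozenset[str]:
        """Leaf labels on the b-side of edge (a, b)."""
        seen = {a, b}
        stack = [b]
        out = []
        while stack:
            v = stack.pop()
            if v in self.leaf_label:
                out.append(self.leaf_label[v])
            for w in self.neighbors[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return frozenset(out)


def adjacency(tree: AnnotatedTree) -> _Adj:
    """Flatten the dendropy tree into an unrooted adjacency graph.

    dendropy's arbitrary root (degree-2 node for rooted input) is dissolved
    so the structure depends only on the unrooted topology.
    """
    adj = _Adj()
    ids: dict[dendropy.Node, int] = {}

    def nid(node: dendropy.Node) -> int:
        if node not in ids:
            ids[node] = len(ids)
            adj.neighbors[ids[node]] = []
            if node.is_leaf():
                adj.leaf_label[ids[node]] = node.taxon.label
        return ids[node]

    def connect(a: int, b: int, support: int | None) -> None:
        adj.neighbors[a].append(b)
        adj.neighbors[b].append(a)
        adj.edge_support[frozenset({a, b})] = support

    dtree = tree.dendropy_tree
    root = dtree.seed_node
    for node in dtree.preorder_node_iter():
        if node is root:
            continue
        sup = _support_of(node) if not node.is_leaf() else None
        connect(nid(node.parent_node), nid(node), sup)
    # dissolve a degree-2 root: merge its two incident edges
    rid = ids.get(root)
    if rid is not None and len(adj.neighbors[rid]) == 2:
        a, b = adj.neighbors[rid]
        sa = adj.edge_support.pop(frozenset({rid, a}))
        sb = adj.edge_support.pop(frozenset({rid, b}))
        adj.neighbors[a].remove(rid)
        adj.neighbors[b].remove(rid)
        del adj.neighbors[rid]
        sup = sa if sa is not None else sb
        adj.neighbors[a].append(b)
        adj.neighbors[b].append(a)
        adj.edge_support[frozenset({a, b})] = sup
    return adj
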