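"""Tree utilities: Newick I/O (via dendropy) and canonical bipartitions.

Trees are :class:`dendropy.Tree` objects throughout the package. A
:class:`Bipartition` is identified by the leaf set on the side *not*
containing the lexicographically smallest leaf label of the universe, so
the same split hashes identically regardless of which tree produced it.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .errors import AflPhyloError

__all__ = [
    "Bipartition",
    "restrict_bipartition",
    "tree_bipartitions",
    "from_newick",
    "to_newick",
    "leaf_labels",
    "build_tree",
]


@dataclass(frozen=True)
class Bipartition:
    """A canonical unrooted split of ``universe`` into ``side`` and its complement."""

    side: frozenset
    universe: frozenset

    @staticmethod
    def of(side, universe) -> "Bipartition":
        side = frozenset(side)
        universe = frozenset(universe)
        if not side <= universe:
            raise AflPhyloError("bipartition side must be a subset of the universe")
        ref = min(universe)
        if ref in side:
            side = universe - side
        return Bipartition(side, universe)

    @property
    def complement(self) -> frozenset:
        return self.universe - self.side

    def is_trivial(self) -> bool:
        return len(self.side) < 2 or len(self.complement) < 2

    def key(self) -> tuple:
        return tuple(sorted(self.side))

    def __repr__(self) -> str:  # compact, for logs and reports
        return "{" + ",".join(sorted(self.side)) + "}"


def restrict_bipartition(bipartition: Bipartition, removed_leaves) -> Bipartition | None:
    """Project a split onto a reduced leaf set; ``None`` if it becomes trivial.

    Leaves in ``removed_leaves`` absent from the universe are ignored.
    """
    removed = frozenset(removed_leaves)
    universe = bipartition.universe - removed
    a = bipartition.side - removed
    b = bipartition.complement - removed
    if len(a) < 2 or len(b) < 2:
        return None
    return Bipartition.of(a, universe)


# ---------------------------------------------------------------------------
# dendropy bridging
# ---------------------------------------------------------------------------

def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(lf.taxon.label for lf in tree.leaf_node_iter())


def tree_bipartitions(tree: dendropy.Tree, include_trivial: bool = False) -> set[Bipartition]:
    """Non-trivial splits induced by the internal edges of ``tree``.

    Works on rooted and unrooted trees alike; a degree-2 root does not
    produce a duplicate split because canonical keys coincide.
    """
    universe = frozenset(leaf_labels(tree))
    out: set[Bipartition] = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        bp = Bipartition.of(below, universe)
        if include_trivial or not bp.is_trivial():
            out.add(bp)
    return out


def from_newick(source: str) -> dendropy.Tree:
    """Parse a Newick string (or contents of a file already read)."""
    return dendropy.Tree.get(data=source, schema="newick", preserve_underscores=True)


def to_newick(
    tree: dendropy.Tree,
    support: dict[Bipartition, float] | None = None,
    min_displayed_support: float | None = None,
) -> str:
    """Serialize to Newick, optionally labelling internal nodes with support.

    ``min_displayed_support`` suppresses labels at or below the cutoff
    (rendering convention only; full values belong in the support table).
    """
    if support is not None:
        universe = frozenset(leaf_labels(tree))
        for node in tree.postorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            below = frozenset(lf.taxon.label for lf in node.leaf_iter())
            bp = Bipartition.of(below, universe)
            val = support.get(bp)
            if val is None:
                continue
            if min_displayed_support is not None and val <= min_displayed_support:
                node.label = None
            else:
                node.label = f"{val:g}"
    return tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()


def root_with_outgroup(tree: dendropy.Tree, outgroup_labels) -> dendropy.Tree:
    """Reroot (for display) on the edge above the outgroup's common ancestor.

    ``outgroup_labels`` may name any subset of leaves; support bookkeeping
    is on unrooted bipartitions and unaffected by the choice of root.
    """
    labels = set(outgroup_labels)
    taxa = [lf.taxon for lf in tree.leaf_node_iter() if lf.taxon.label in labels]
    if not taxa:
        raise AflPhyloError(f"no leaves match outgroup {sorted(labels)!r}")
    tree = tree.clone(depth=1)
    tree.is_rooted = True
    taxa = [lf.taxon for lf in tree.leaf_node_iter() if lf.taxon.label in labels]
    mrca = tree.mrca(taxa=taxa) if len(taxa) > 1 else \
        tree.find_node_with_taxon_label(taxa[0].label)
    if mrca.parent_node is None:  # outgroup spans the root already
        return tree
    length = mrca.edge.length or 0.0
    tree.reroot_at_edge(mrca.edge, length1=length / 2, length2=length / 2)
    return tree


def build_tree(edges: dict, leaf_names: list[str]) -> dendropy.Tree:
    """Assemble a dendropy tree from ``{node_id: (parent_id, branch_length)}``.

    ``leaf_names`` maps node ids ``0..n_leaves-1`` to taxon labels; the entry
    whose parent is ``None`` is the (possibly trifurcating) seed node.
    """
    taxon_namespace = dendropy.TaxonNamespace(leaf_names)
    nodes: dict[int, dendropy.Node] = {}
    root_id = None
    for node_id, (parent_id, _) in edges.items():
        nodes[node_id] = dendropy.Node()
        if parent_id is None:
            root_id = node_id
    if root_id is None:
        raise AflPhyloError("edge map has no root")
    for node_id, (parent_id, length) in edges.items():
        node = nodes[node_id]
        if node_id < len(leaf_names):
            node.taxon = taxon_namespace.get_taxon(leaf_names[node_id])
        if parent_id is not None:
            nodes[parent_id].add_child(node)
            node.edge.length = float(length)
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.seed_node = nodes[root_id]
    tree.is_rooted = False
    return tree
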