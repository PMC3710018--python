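"""Rooted guide trees and speciation-event extraction.

In tree-based mode every species of a taxonomy must be a clade of a rooted,
strictly bifurcating guide tree (in the motivating data set, the mtDNA gene
tree).  A taxonomy with k clade-species then supports exactly k - 1 speciation
events: the internal nodes whose subtended leaves are a disjoint union of two
or more complete species.  Node identity is topological — a node *is* its
leaf set — so two newick rotations of the same topology yield identical event
sets.

Polytomies are refused for event extraction: the "events = species - 1"
identity assumes a dichotomous tree, and no sharing semantics is defined for
soft polytomies; tree-free mode handles such data instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .errors import (
    NonCladePartitionError,
    PolytomyError,
    TableFormatError,
    UniverseMismatchError,
)
from .partition import SpeciesPartition

__all__ = ["GuideTree", "EventSet", "read_newick", "check_clade_partition", "extract_event_nodes"]


class GuideTree:
    """A rooted tree over the specimen universe, with topological node identity.

    Wraps a :class:`dendropy.Tree`.  Internal nodes are exposed as frozensets
    of the leaf labels they subtend; reports render a node as its sorted leaf
    list.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if any(lab is None for lab in labels):
            raise TableFormatError("guide tree contains unlabeled leaves")
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TableFormatError(f"duplicate leaf label(s) in guide tree: {sorted(dupes)}")
        self._leaf_labels = tuple(labels)
        # postorder pass caches each node's subtended leaf set
        self._clades: list[frozenset[str]] = []
        self._max_out_degree = 0
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                node.leafset = frozenset([node.taxon.label])
            else:
                kids = node.child_nodes()
                self._max_out_degree = max(self._max_out_degree, len(kids))
                node.leafset = frozenset().union(*(k.leafset for k in kids))
                self._clades.append(node.leafset)
        self._clade_set = frozenset(self._clades)

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return self._leaf_labels

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_labels)

    @property
    def internal_clades(self) -> tuple[frozenset[str], ...]:
        """Leaf sets of internal nodes, in postorder (root last)."""
        return tuple(self._clades)

    @property
    def n_internal(self) -> int:
        return len(self._clades)

    @property
    def is_binary(self) -> bool:
        return self._max_out_degree <= 2

    def is_clade(self, leaves: frozenset[str]) -> bool:
        """True if ``leaves`` is a single leaf or the exact leaf set of one node."""
        if len(leaves) == 1:
            return leaves <= frozenset(self._leaf_labels)
        return leaves in self._clade_set

    def check_universe(self, p: SpeciesPartition) -> None:
        tree_set = frozenset(self._leaf_labels)
        if tree_set != p.universe.idset:
            raise UniverseMismatchError(
                tree_set - p.universe.idset,
                p.universe.idset - tree_set,
                context=f"guide tree vs method {p.method_name!r}",
            )

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    @staticmethod
    def render_node(leaves: frozenset[str]) -> str:
        return "{" + ",".join(sorted(leaves)) + "}"


@dataclass(frozen=True)
class EventSet:
    """Speciation-event hypotheses of one taxonomy, as guide-tree nodes.

    Each event is identified by the frozenset of leaf labels below the node.
    For a taxonomy with k species the set has exactly k - 1 members.
    """

    method_name: str
    nodes: frozenset[frozenset[str]]

    def __len__(self) -> int:
        return len(self.nodes)


def read_newick(path) -> GuideTree:
    """Read one rooted newick tree; branch lengths are read but unused."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        if "Duplicate taxon" in str(exc):
            raise TableFormatError(
                f"duplicate leaf label(s) in newick file {path}: {exc}"
            ) from exc
        raise TableFormatError(f"could not parse newick file {path}: {exc}") from exc
    return GuideTree(tree)


def tree_from_string(newick: str) -> GuideTree:
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        if "Duplicate taxon" in str(exc):
            raise TableFormatError(f"duplicate leaf label(s): {exc}") from exc
        raise TableFormatError(f"could not parse newick string: {exc}") from exc
    return GuideTree(tree)


def check_clade_partition(
    p: SpeciesPartition, t: GuideTree
) -> tuple[bool, str | None]:
    """Is every species of ``p`` a clade of ``t``?

    Returns ``(True, None)`` or ``(False, label_of_first_non_clade_species)``,
    iterating species in first-appearance order.  Singleton species qualify
    through their leaf.
    """
    t.check_universe(p)
    for label, members in p.clusters().items():
        if not t.is_clade(members):
            return False, label
    return True, None


def extract_event_nodes(p: SpeciesPartition, t: GuideTree) -> EventSet:
    """Speciation-event nodes of taxonomy ``p`` on guide tree ``t``.

    An internal node is an event iff its subtended leaves are a disjoint union
    of >= 2 complete species of ``p`` — i.e. the node lies above the species
    level.  On a strictly bifurcating tree this yields exactly k - 1 nodes,
    which is asserted.
    """
    if not t.is_binary:
        raise PolytomyError(
            "guide tree contains a polytomy; speciation-event counting assumes a "
            "dichotomous tree — resolve the tree or use tree-free mode"
        )
    ok, witness = check_clade_partition(p, t)
    if not ok:
        raise NonCladePartitionError(
            p.method_name, witness, p.clusters()[witness]
        )
    clusters = p.cluster_sets()
    nodes = []
    for clade in t.internal_clades:
        touching = [c for c in clusters if c & clade]
        if len(touching) >= 2 and all(c <= clade for c in touching):
            nodes.append(clade)
    events = EventSet(method_name=p.method_name, nodes=frozenset(nodes))
    assert len(events) == p.n_species - 1, (
        f"event extraction invariant violated for {p.method_name!r}: "
        f"{len(events)} events, {p.n_species} species"
    )
    return events
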