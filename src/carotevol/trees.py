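"""Rooted, branch-length-bearing trees with optional leaf annotations.

``LabeledTree`` is a thin wrapper around a :class:`dendropy.Tree` that gives
every node a stable name (so per-branch parameters such as omega can be keyed
by the child node of each branch), and carries an optional mapping from leaf
names to annotations: seed function labels for clade-based annotation, or
binary presence states for gain/loss parsimony.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Optional

import dendropy


class TreeError(ValueError):
    """Raised for malformed or inconsistent tree input."""


def _node_name(node: dendropy.Node) -> Optional[str]:
    if node.taxon is not None and node.taxon.label is not None:
        return node.taxon.label
    return node.label


@dataclass
class LabeledTree:
    """A rooted tree with named nodes, branch lengths and leaf annotations.

    Parameters
    ----------
    tree:
        The underlying dendropy tree. Every node must carry a unique name
        (leaves via their taxon label, internal nodes via ``node.label``);
        use :meth:`from_newick` or the simulator to obtain one.
    leaf_labels:
        Optional mapping ``leaf name -> annotation`` (seed enzyme-family
        symbol, or a presence state). Leaves absent from the mapping are
        unannotated.
    """

    tree: dendropy.Tree
    leaf_labels: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._ensure_named()
        names = [self.name_of(n) for n in self.tree.preorder_node_iter()]
        if len(names) != len(set(names)):
            raise TreeError("node names are not unique")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeError(f"negative branch length on {self.name_of(edge.head_node)}")
        unknown = set(self.leaf_labels) - set(self.leaf_names())
        if unknown:
            raise TreeError(f"leaf_labels refer to unknown leaves: {sorted(unknown)}")

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(
        cls, newick: str, leaf_labels: Optional[Dict[str, str]] = None
    ) -> "LabeledTree":
        """Parse a Newick string; quoted labels are preserved verbatim."""
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=False,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"could not parse Newick: {exc}") from exc
        return cls(tree, dict(leaf_labels or {}))

    def _ensure_named(self) -> None:
        seen = {
            _node_name(n)
            for n in self.tree.preorder_node_iter()
            if _node_name(n) is not None
        }
        counter = 0
        for node in self.tree.preorder_node_iter():
            if _node_name(node) is None:
                counter += 1
                name = f"n{counter}"
                while name in seen:
                    counter += 1
                    name = f"n{counter}"
                node.label = name
                seen.add(name)

    # -- queries ------------------------------------------------------

    @staticmethod
    def name_of(node: dendropy.Node) -> str:
        name = _node_name(node)
        assert name is not None
        return name

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def leaf_names(self) -> list[str]:
        return [self.name_of(l) for l in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def node(self, name: str) -> dendropy.Node:
        for n in self.tree.preorder_node_iter():
            if self.name_of(n) == name:
                return n
        raise KeyError(name)

    def branches(self) -> Iterator[tuple[str, float]]:
        """Yield ``(child node name, branch length)`` for every real branch."""
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                yield self.name_of(node), float(node.edge.length or 0.0)

    def total_branch_length(self) -> float:
        return sum(length for _, length in self.branches())

    def branch_lengths(self) -> Dict[str, float]:
        return dict(self.branches())

    def set_branch_length(self, child_name: str, length: float) -> None:
        if length < 0:
            raise TreeError("branch length must be non-negative")
        self.node(child_name).edge.length = length

    def scale_branch_lengths(self, factor: float) -> "LabeledTree":
        clone = self.copy()
        for node in clone.tree.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is not None:
                node.edge.length = node.edge.length * factor
        return clone

    def leaves_under(self, node: dendropy.Node) -> list[str]:
        return [self.name_of(l) for l in node.leaf_iter()]

    def copy(self) -> "LabeledTree":
        return LabeledTree.from_newick(self.newick(), dict(self.leaf_labels))

    # -- serialization -------------------------------------------------

    def newick(self) -> str:
        return (
            self.tree.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
                suppress_internal_node_labels=False,
            ).strip()
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")

    @classmethod
    def read(cls, path, leaf_labels: Optional[Dict[str, str]] = None) -> "LabeledTree":
        with open(path) as fh:
            return cls.from_newick(fh.read(), leaf_labels)


def robinson_foulds(a: LabeledTree, b: LabeledTree) -> int:
    """Unweighted Robinson–Foulds distance via brute-force bipartition sets.

    Computed directly from leaf bipartitions (not via library tree
    comparison) so it can serve as an independent check on Newick
    round-tripping.
    """
    if set(a.leaf_names()) != set(b.leaf_names()):
        raise TreeError("trees must share a leaf set")

    def splits(t: LabeledTree) -> set[frozenset[str]]:
        all_leaves = frozenset(t.leaf_names())
        out = set()
        for node in t.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(t.leaves_under(node))
            if 1 < len(side) < len(all_leaves) - 1:
                # store the canonical (lexicographically smaller) side
                other = all_leaves - side
                out.add(min(side, other, key=lambda s: sorted(s)))
        return out

    sa, sb = splits(a), splits(b)
    return len(sa ^ sb)
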