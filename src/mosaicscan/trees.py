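"""Unrooted phylogenetic trees with branch lengths.

Thin wrapper around :mod:`dendropy` providing the operations the scan
needs: Newick round-trips, leaf-label sets, and decomposition of a tree
into its edge bipartitions (splits) keyed canonically so that trees on
the same taxa can be compared edge-by-edge.
"""

from __future__ import annotations

import io
from typing import Dict, FrozenSet, Iterator, Tuple

import dendropy

Split = FrozenSet[str]


class PhyloTree:
    """An unrooted tree with labelled leaves and non-negative branch lengths.

    Internally stores a :class:`dendropy.Tree`; any root bifurcation is
    collapsed on construction so edge sets (and hence bipartitions) are
    those of the unrooted tree.
    """

    def __init__(self, dtree: dendropy.Tree):
        dtree.is_rooted = False
        # collapse a degree-2 root so a rooted Newick and its unrooted
        # equivalent yield identical edge sets
        if dtree.seed_node.num_child_nodes() == 2:
            dtree.collapse_basal_bifurcation()
        self._tree = dtree
        self._splits: Dict[Split, float] | None = None

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(dtree)

    @classmethod
    def read(cls, path) -> "PhyloTree":
        dtree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
        return cls(dtree)

    # -- basic accessors ----------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> FrozenSet[str]:
        return frozenset(lf.taxon.label for lf in self._tree.leaf_node_iter())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def n_edges(self) -> int:
        """Number of edges of the unrooted tree."""
        return sum(1 for _ in self._edge_iter())

    def total_length(self) -> float:
        return sum(length for _, length in self.bipartitions().items())

    # -- serialization ------------------------------------------------

    def to_newick(self, precision: int = 6) -> str:
        out = io.StringIO()
        self._tree.write(
            file=out,
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=f".{precision}f",
        )
        return out.getvalue().strip()

    def write(self, path, precision: int = 6) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(precision=precision) + "\n")

    # -- bipartitions -------------------------------------------------

    def _edge_iter(self) -> Iterator[Tuple[dendropy.Node, float]]:
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            yield node, (node.edge.length if node.edge.length is not None else 0.0)

    def bipartitions(self) -> Dict[Split, float]:
        """Map each edge to its split, keyed by the side *not* containing
        the lexicographically first leaf; value is the branch length.

        Terminal edges therefore key as the singleton leaf set, except for
        the first leaf's own pendant edge which keys as its complement.
        """
        if self._splits is not None:
            return self._splits
        labels = sorted(self.leaf_labels)
        first = labels[0]
        all_leaves = frozenset(labels)
        below: Dict[int, FrozenSet[str]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                below[id(node)] = frozenset([node.taxon.label])
            else:
                acc: FrozenSet[str] = frozenset()
                for ch in node.child_nodes():
                    acc = acc | below[id(ch)]
                below[id(node)] = acc
        splits: Dict[Split, float] = {}
        for node, length in self._edge_iter():
            side = below[id(node)]
            if first in side:
                side = all_leaves - side
            splits[side] = splits.get(side, 0.0) + length
        self._splits = splits
        return splits

    def internal_bipartitions(self, min_length: float = 0.0) -> Dict[Split, float]:
        """Non-trivial splits (both sides >= 2 leaves); splits induced by
        edges shorter than ``min_length`` excluded."""
        n = self.n_leaves
        return {
            s: ln
            for s, ln in self.bipartitions().items()
            if 1 < len(s) < n - 1 and ln > min_length
        }

    # -- misc ---------------------------------------------------------

    def scaled(self, factor: float) -> "PhyloTree":
        """A copy with every branch length multiplied by ``factor``."""
        dtree = self._tree.clone(depth=1)
        for edge in dtree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * factor
        return PhyloTree(dtree)

    def leaf_path_distance(self, a: str, b: str) -> float:
        pdm = self._tree.phylogenetic_distance_matrix()
        ta = self._tree.taxon_namespace.get_taxon(a)
        tb = self._tree.taxon_namespace.get_taxon(b)
        return pdm.patristic_distance(ta, tb)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_leaves={self.n_leaves})"
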