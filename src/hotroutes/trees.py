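"""Indexed phylogeny container used throughout the package.

Trees are read and written with dendropy; for the numerical routines
(tip-rate computation, pruning likelihoods, stochastic mapping) we convert
once into a flat array representation with a cached postorder, node ages in
Ma before present, and integer child/parent pointers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["IndexedTree", "read_newick"]


@dataclass
class IndexedTree:
    """Rooted binary ultrametric tree with branch lengths in Ma.

    Nodes are indexed 0..n_nodes-1 with tips first (0..n_tips-1 in the
    order of ``tip_labels``).  ``parent[root] == -1`` and the root branch
    length is 0.
    """

    tip_labels: list[str]
    parent: np.ndarray          # (n_nodes,) int
    children: np.ndarray        # (n_nodes, 2) int, -1 for tips
    blen: np.ndarray            # (n_nodes,) float, branch above node
    postorder: np.ndarray       # internal+tip indices, children before parents
    ages: np.ndarray = field(init=False)   # Ma before present, tips ~ 0

    def __post_init__(self) -> None:
        n = len(self.parent)
        depth = np.zeros(n)
        for v in self.postorder[::-1]:
            p = self.parent[v]
            depth[v] = (depth[p] if p >= 0 else 0.0) + self.blen[v]
        self.ages = depth.max() - depth

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(np.nonzero(self.parent == -1)[0][0])

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        tip_ages = self.ages[: self.n_tips]
        return bool(np.all(np.abs(tip_ages) <= rel_tol * max(self.root_age, 1e-300)))

    # ------------------------------------------------------------------
    # conversion
    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "IndexedTree":
        nodes = list(tree.preorder_node_iter())
        tips = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        for nd in internals:
            if len(nd.child_nodes()) != 2:
                raise ValueError("tree must be strictly binary")
        order = tips + internals
        index = {id(nd): i for i, nd in enumerate(order)}
        n = len(order)
        parent = np.full(n, -1, dtype=int)
        children = np.full((n, 2), -1, dtype=int)
        blen = np.zeros(n)
        for nd in order:
            i = index[id(nd)]
            blen[i] = nd.edge.length or 0.0
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
            kids = nd.child_nodes()
            if kids:
                children[i] = [index[id(kids[0])], index[id(kids[1])]]
        post = [index[id(nd)] for nd in tree.postorder_node_iter()]
        labels = [nd.taxon.label if nd.taxon else f"t{index[id(nd)]}" for nd in tips]
        return cls(labels, parent, children, blen, np.asarray(post, dtype=int))

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace(self.tip_labels)
        tree = dendropy.Tree(taxon_namespace=taxa)
        nodes = {}
        for v in self.postorder:
            nd = dendropy.Node()
            nd.edge.length = float(self.blen[v])
            if v < self.n_tips:
                nd.taxon = taxa.get_taxon(self.tip_labels[v])
            else:
                for c in self.children[v]:
                    nd.add_child(nodes[c])
            nodes[v] = nd
        tree.seed_node = nodes[self.root]
        tree.seed_node.edge.length = None
        return tree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_newick(cls, newick: str) -> "IndexedTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    # ------------------------------------------------------------------
    def tips_below(self) -> list[np.ndarray]:
        """For every node, the array of tip indices in its subtree."""
        below: list = [None] * self.n_nodes
        for v in self.postorder:
            if v < self.n_tips:
                below[v] = np.array([v])
            else:
                c0, c1 = self.children[v]
                below[v] = np.concatenate([below[c0], below[c1]])
        return below

    def scale(self, factor: float) -> "IndexedTree":
        return IndexedTree(
            list(self.tip_labels),
            self.parent.copy(),
            self.children.copy(),
            self.blen * factor,
            self.postorder.copy(),
        )


def read_newick(path: str) -> IndexedTree:
    tree = dendropy.Tree.get(path=path, schema="newick")
    return IndexedTree.from_dendropy(tree)
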