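"""Indexed array representation of a time-scaled binary tree.

Likelihood code, simulators and the Brownian-motion machinery all traverse
the same arrays (parent pointers, branch lengths, node ages in Ma) rather
than walking a dendropy object graph.  dendropy remains the I/O layer:
trees enter and leave as Newick.
"""

from __future__ import annotations

import dendropy
import numpy as np


class IndexedTree:
    """A rooted binary tree with branch lengths in Myr and node ages in Ma.

    Nodes are indexed 0..n_nodes-1 with tips first (0..n_tips-1, in the
    order of `tip_labels`) followed by internal nodes in postorder; the
    root is the last index.  Ages are computed by placing the deepest tip
    at `youngest_tip_age` Ma (default 0, the present) unless explicit ages
    are supplied.
    """

    def __init__(self, dtree: dendropy.Tree, youngest_tip_age: float = 0.0):
        dtree = dtree.clone(depth=1)
        dtree.suppress_unifurcations()
        leaves = [lf for lf in dtree.leaf_node_iter()]
        internals = [nd for nd in dtree.postorder_node_iter() if not nd.is_leaf()]
        for nd in internals:
            if len(nd.child_nodes()) != 2:
                raise ValueError("tree must be strictly binary")
        self.n_tips = len(leaves)
        self.n_nodes = len(leaves) + len(internals)
        self.tip_labels = [
            (lf.taxon.label if lf.taxon is not None else f"tip{i}")
            for i, lf in enumerate(leaves)
        ]
        index = {}
        for i, lf in enumerate(leaves):
            index[id(lf)] = i
        for j, nd in enumerate(internals):
            index[id(nd)] = self.n_tips + j

        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.branch_length = np.zeros(self.n_nodes)
        self.children = [[] for _ in range(self.n_nodes)]
        for nd in dtree.preorder_node_iter():
            i = index[id(nd)]
            self.branch_length[i] = nd.edge.length or 0.0
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
        self.root = index[id(dtree.seed_node)]
        # postorder over all nodes (tips as encountered before their parents)
        self.postorder = self._compute_postorder()

        depth = np.zeros(self.n_nodes)
        for i in reversed(self.postorder):  # preorder
            if self.parent[i] >= 0:
                depth[i] = depth[self.parent[i]] + self.branch_length[i]
        self.age = (depth[: self.n_tips].max() + youngest_tip_age) - depth
        self._newick = dtree.as_string(schema="newick", suppress_rooting=True).strip()

    def _compute_postorder(self) -> list[int]:
        order: list[int] = []
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or not self.children[node]:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self.children[node]:
                    stack.append((c, False))
        return order

    @classmethod
    def from_newick(cls, newick: str, youngest_tip_age: float = 0.0) -> "IndexedTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(dtree, youngest_tip_age=youngest_tip_age)

    @classmethod
    def from_file(cls, path, youngest_tip_age: float = 0.0) -> "IndexedTree":
        with open(path) as fh:
            return cls.from_newick(fh.read(), youngest_tip_age=youngest_tip_age)

    def as_newick(self) -> str:
        return self._newick

    @property
    def internal_nodes(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.children[i]]

    @property
    def tip_indices(self) -> list[int]:
        return list(range(self.n_tips))

    def tip_index(self, label: str) -> int:
        return self.tip_labels.index(label)

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        return bool(np.ptp(self.age[: self.n_tips]) <= tol)

    def subtree_nodes(self, node: int) -> list[int]:
        """All node indices in the clade rooted at `node` (inclusive)."""
        out = []
        stack = [node]
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(self.children[i])
        return out

    def mrca(self, tip_labels) -> int:
        """Most recent common ancestor of a set of tip labels."""
        want = {self.tip_index(lb) for lb in tip_labels}
        if not want:
            raise ValueError("empty tip set")
        # count tips under each node in postorder
        counts = np.zeros(self.n_nodes, dtype=int)
        for i in self.postorder:
            if not self.children[i]:
                counts[i] = 1 if i in want else 0
            else:
                counts[i] = sum(counts[c] for c in self.children[i])
            if counts[i] == len(want):
                return i
        raise RuntimeError("unreachable")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick() + "\n")


def enforce_min_branch_length(newick: str, minimum: float = 0.1) -> str:
    """Raise every zero or sub-minimum branch to `minimum` Myr.

    Ancestral-range and BM machinery both require strictly positive branch
    lengths; zero-length branches are rescaled, matching standard practice
    for time-scaled fossil trees.
    """
    dtree = dendropy.Tree.get(data=newick, schema="newick")
    for edge in dtree.preorder_edge_iter():
        if edge.head_node.parent_node is None:
            continue
        if edge.length is None or edge.length < minimum:
            edge.length = minimum
    return dtree.as_string(schema="newick", suppress_rooting=True).strip()
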