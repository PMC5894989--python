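"""Array-backed tree view for fast, repeated fair-proportion evaluation.

The removal experiment recomputes ED on thousands of pruned versions of the
same tree.  Pruning a tree and collapsing degree-2 nodes never changes the
fair-proportion partition relative to simply (a) dropping edges with no
retained descendant and (b) dividing each remaining edge among its *retained*
descendants: a collapsed chain of edges shares one descendant set, so its
summed length divided by the common count equals the sum of the per-edge
contributions.  ``IndexedTree`` exploits this to evaluate ED on any leaf
subset without rebuilding a tree object.
"""

from __future__ import annotations

import numpy as np

from .exceptions import TreeError


class IndexedTree:
    """Immutable arrays (parent pointers, edge lengths, level order) for one
    rooted tree.  Node 0 is the root; a root edge, when present, is stored as
    the root's length and treated as ancestral to every leaf.
    """

    def __init__(self, tree) -> None:
        nodes = list(tree.preorder_node_iter())
        if not nodes:
            raise TreeError("empty tree")
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        length = np.zeros(n, dtype=np.float64)
        depth = np.zeros(n, dtype=np.int64)
        leaf_ids: list[int] = []
        labels: list[str] = []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                parent[i] = p
                depth[i] = depth[p] + 1
            el = nd.edge.length
            if el is not None:
                el = float(el)
                if not np.isfinite(el):
                    raise TreeError(f"non-finite edge length at node {i}")
                if el < 0:
                    raise TreeError(f"negative edge length {el} at node {i}")
                length[i] = el
            if nd.is_leaf():
                lab = nd.taxon.label if nd.taxon is not None else nd.label
                if lab is None or str(lab).strip() == "":
                    raise TreeError("unlabelled leaf")
                leaf_ids.append(i)
                labels.append(str(lab).strip())
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeError(f"duplicate leaf labels: {dupes}")
        self.parent = parent
        self.length = length
        self.leaf_ids = np.asarray(leaf_ids, dtype=np.int64)
        self.leaf_labels: list[str] = labels
        self.leaf_index = {lab: k for k, lab in enumerate(labels)}
        # nodes grouped by depth, deepest first, for vectorised sweeps
        maxd = int(depth.max())
        self._levels = [
            np.flatnonzero(depth == d) for d in range(maxd, 0, -1)
        ]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def _descendant_counts(self, keep: np.ndarray | None) -> np.ndarray:
        counts = np.zeros(len(self.parent), dtype=np.int64)
        if keep is None:
            counts[self.leaf_ids] = 1
        else:
            counts[self.leaf_ids] = keep.astype(np.int64)
        for level in self._levels:
            np.add.at(counts, self.parent[level], counts[level])
        return counts

    def fair_proportion(self, keep: np.ndarray | None = None) -> np.ndarray:
        """Fair-proportion ED for every leaf (aligned with ``leaf_labels``).

        ``keep`` is an optional boolean mask over leaves: ED is then computed
        as if the tree had been pruned to the retained leaves (degree-2 nodes
        collapsed).  Entries for dropped leaves are NaN.
        """
        counts = self._descendant_counts(keep)
        total = counts[0]
        if total < 2:
            raise TreeError("fair proportion requires >= 2 (retained) leaves")
        n = len(self.parent)
        acc = np.zeros(n, dtype=np.float64)
        acc[0] = self.length[0] / total  # root edge shared by all leaves
        with np.errstate(divide="ignore", invalid="ignore"):
            share = np.where(counts > 0, self.length / np.maximum(counts, 1), 0.0)
        for level in reversed(self._levels):  # shallow -> deep
            acc[level] = acc[self.parent[level]] + share[level]
        ed = acc[self.leaf_ids]
        if keep is not None:
            ed = np.where(keep, ed, np.nan)
        return ed

    def total_pd(self, keep: np.ndarray | None = None) -> float:
        """Sum of edge lengths (root edge included); with ``keep``, the PD of
        the implied pruned tree."""
        if keep is None:
            return float(self.length.sum())
        counts = self._descendant_counts(keep)
        return float(self.length[counts > 0].sum())

    def terminal_lengths(self) -> np.ndarray:
        return self.length[self.leaf_ids]
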