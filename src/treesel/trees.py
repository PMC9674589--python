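"""Local genealogies (per-SNP trees) with a marked mutation branch.

A :class:`LocalTree` is the genealogy of the sampled haplotypes at one SNP:
a rooted tree with node times in generations before present (tips at 0),
plus the branch on which the focal derived mutation arose.  The leaves below
that branch are exactly the carriers of the derived allele.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = ["LocalTree", "ClassSchedule"]


@dataclass(frozen=True)
class ClassSchedule:
    """Coalescence-event schedule split by allelic class.

    ``derived_times`` / ``ancestral_times`` are sorted times (generations
    ago) of coalescences internal to each class; ``t_child`` and
    ``t_parent`` bound the mutation branch (``t_parent`` is ``inf`` when the
    mutation sits on the root branch).  Ancestral events above ``t_parent``
    are excluded: past the mutation's origin the allelic classes have merged
    and the remaining history carries no information about selection on the
    focal allele.
    """

    derived_times: np.ndarray
    ancestral_times: np.ndarray
    t_child: float
    t_parent: float
    n_derived: int
    n_ancestral: int


class LocalTree:
    """Rooted genealogy with node times and a marked mutation branch.

    Parameters
    ----------
    parent
        Integer array, ``parent[i]`` is the parent node of ``i`` (-1 at the
        root).  Nodes ``0..n_leaves-1`` are the leaves.
    time
        Node times in generations before present; leaves at (close to) 0.
    leaf_labels
        Haplotype labels for nodes ``0..n_leaves-1``.
    mutation_node
        The child node of the branch carrying the focal derived mutation.
        Leaves below it are the derived carriers.
    """

    def __init__(
        self,
        parent: np.ndarray,
        time: np.ndarray,
        leaf_labels: tuple[str, ...],
        mutation_node: int,
        meta: dict | None = None,
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.time = np.asarray(time, dtype=float)
        self.leaf_labels = tuple(leaf_labels)
        self.mutation_node = int(mutation_node)
        self.meta = dict(meta or {})
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(len(self.parent))]
        for i, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(i)
        return kids

    def _validate(self) -> None:
        n_nodes = len(self.parent)
        if len(self.time) != n_nodes:
            raise ValueError("parent and time arrays must have equal length")
        n_leaves = len(self.leaf_labels)
        if not (1 <= n_leaves < n_nodes):
            raise ValueError("leaf labels must cover nodes 0..n_leaves-1")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        has_parent = self.parent >= 0
        if np.any(self.time[self.parent[has_parent]] < self.time[has_parent] - 1e-9):
            raise ValueError("parent node times must be >= child node times")
        if not (0 <= self.mutation_node < n_nodes):
            raise ValueError("mutation_node out of range")
        kids = self._children()
        for i in range(n_leaves):
            if kids[i]:
                raise ValueError("nodes 0..n_leaves-1 must be leaves")
        # mutation_node == root (all leaves derived) is tolerated as the
        # degenerate single-class case; the likelihood rejects it explicitly
        nd = len(self.derived_leaf_indices)
        if nd < 1:
            raise ValueError("derived carrier set must be non-empty")

    # -- basic properties -----------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def _subtree_leaves(self, node: int) -> list[int]:
        kids = self._children()
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if v < self.n_leaves:
                out.append(v)
            stack.extend(kids[v])
        return sorted(out)

    @property
    def derived_leaf_indices(self) -> list[int]:
        return self._subtree_leaves(self.mutation_node)

    @property
    def derived_leaves(self) -> set[str]:
        return {self.leaf_labels[i] for i in self.derived_leaf_indices}

    @property
    def n_derived(self) -> int:
        return len(self.derived_leaf_indices)

    @property
    def t_child(self) -> float:
        """Time of the lower end of the mutation branch (derived TMRCA)."""
        return float(self.time[self.mutation_node])

    @property
    def t_parent(self) -> float:
        """Time of the upper end of the mutation branch (inf on root branch)."""
        p = self.parent[self.mutation_node]
        return float(self.time[p]) if p >= 0 else np.inf

    # -- event schedule for the likelihood ------------------------------------

    def class_schedule(self) -> ClassSchedule:
        """Split internal coalescences into derived- and ancestral-class events."""
        kids = self._children()
        # ancestors of the mutation node (cross-class merges; excluded)
        anc: set[int] = set()
        v = self.parent[self.mutation_node]
        while v >= 0:
            anc.add(int(v))
            v = self.parent[v]
        in_derived = set()
        stack = [self.mutation_node]
        while stack:
            v = stack.pop()
            in_derived.add(v)
            stack.extend(kids[v])
        t_parent = self.t_parent
        derived_times, ancestral_times = [], []
        for node in range(self.n_leaves, len(self.parent)):
            if node in anc:
                continue
            if node in in_derived:
                derived_times.append(self.time[node])
            elif self.time[node] < t_parent - 1e-12:
                ancestral_times.append(self.time[node])
        return ClassSchedule(
            derived_times=np.sort(np.asarray(derived_times, dtype=float)),
            ancestral_times=np.sort(np.asarray(ancestral_times, dtype=float)),
            t_child=self.t_child,
            t_parent=t_parent,
            n_derived=self.n_derived,
            n_ancestral=self.n_leaves - self.n_derived,
        )

    # -- newick round trip ----------------------------------------------------

    def to_newick(self) -> str:
        kids = self._children()

        def render(v: int) -> str:
            if v < self.n_leaves:
                return self.leaf_labels[v]
            inner = ",".join(
                f"{render(c)}:{self.time[v] - self.time[c]:.8g}" for c in kids[v]
            )
            return f"({inner})"

        return render(self.root) + ";"

    @classmethod
    def from_newick(
        cls,
        newick: str,
        derived_leaves: set[str] | list[str],
        ultrametric_tol: float = 1.0,
    ) -> "LocalTree":
        """Build from a newick string with branch lengths in generations.

        ``derived_leaves`` must form a clade; its MRCA's parent branch is the
        mutation branch.  Tip times must be 0 within ``ultrametric_tol``
        generations.
        """
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        dtree.calc_node_root_distances(return_leaf_distances_only=False)
        max_depth = max(lf.root_distance for lf in dtree.leaf_node_iter())
        nodes = list(dtree.leaf_node_iter()) + [
            nd for nd in dtree.preorder_node_iter() if not nd.is_leaf()
        ]
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        time = np.zeros(n)
        labels = []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
            time[i] = max_depth - nd.root_distance
            if nd.is_leaf():
                labels.append(nd.taxon.label if nd.taxon else f"leaf{i}")
        tip_times = time[: len(labels)]
        if np.any(np.abs(tip_times) > ultrametric_tol):
            raise ValueError(
                f"tree is not ultrametric: tip times deviate up to "
                f"{np.max(np.abs(tip_times)):.3g} generations from 0"
            )
        time[: len(labels)] = 0.0
        want = set(derived_leaves)
        lab2idx = {lab: i for i, lab in enumerate(labels)}
        missing = want - set(labels)
        if missing:
            raise ValueError(f"derived carriers not in tree: {sorted(missing)[:5]}")
        # MRCA of carriers by repeated parent-walking
        carrier_idx = [lab2idx[w] for w in want]
        mrca = carrier_idx[0]
        for c in carrier_idx[1:]:
            mrca = _pairwise_mrca(parent, mrca, c)
        tree = cls(parent, time, tuple(labels), mrca)
        if tree.derived_leaves != want:
            raise ValueError(
                "derived carrier set is not a clade: mutation cannot map to a "
                "single branch"
            )
        return tree


def _pairwise_mrca(parent: np.ndarray, a: int, b: int) -> int:
    seen = set()
    while a >= 0:
        seen.add(a)
        a = parent[a]
    while b not in seen:
        b = parent[b]
        if b < 0:
            raise ValueError("disconnected tree")
    return int(b)
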