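"""Rooted time-trees (chronograms).

A :class:`TimeTree` is a rooted, binary tree over a fixed taxon set whose
nodes carry ages in millions of years (My) before present.  Tips sit at age
zero (extant taxa); every internal node is strictly older than its children,
and branch *durations* (parent age minus child age) are the time-scale
quantities that clock models convert into expected substitutions per site.

Nodes are integer ids: tips ``0 .. n_tips-1`` (in the order of ``taxa``),
internal nodes ``n_tips .. 2*n_tips-2``.  Topology is stored as parent and
children arrays, which keeps copying cheap inside MCMC.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import numpy as np
import dendropy

# topology identity tokens: unique per distinct topology instance, shared by
# copies, refreshed on any topological change — safe as external cache keys
_TOPOLOGY_TOKENS = itertools.count(1)

__all__ = ["TimeTree", "random_constrained_topology", "ConstraintConflictError"]


class ConstraintConflictError(ValueError):
    """Raised when monophyly constraints are mutually incompatible."""


class TimeTree:
    """Rooted binary tree with node ages in My before present."""

    __slots__ = ("taxa", "parent", "children", "ages", "topology_version", "_post")

    def __init__(
        self,
        taxa: Sequence[str],
        parent: np.ndarray,
        children: np.ndarray,
        ages: np.ndarray,
        validate: bool = True,
    ):
        self.taxa = list(taxa)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = np.asarray(children, dtype=np.int64)
        self.ages = np.asarray(ages, dtype=np.float64)
        self.topology_version = next(_TOPOLOGY_TOKENS)
        self._post = None
        if validate:
            self.validate()

    # ------------------------------------------------------------------ basic
    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_tips - 1

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def is_tip(self, node: int) -> bool:
        return node < self.n_tips

    def validate(self) -> None:
        n = self.n_tips
        if n < 2:
            raise ValueError("a time-tree needs at least two tips")
        if len(set(self.taxa)) != n:
            raise ValueError("duplicate taxon labels")
        if self.parent.shape != (2 * n - 1,) or self.children.shape != (2 * n - 1, 2):
            raise ValueError("inconsistent array shapes")
        if np.sum(self.parent < 0) != 1:
            raise ValueError("tree must have exactly one root")
        for i in range(2 * n - 1):
            p = self.parent[i]
            if p >= 0 and self.ages[p] <= self.ages[i]:
                raise ValueError(
                    f"age-order violation: node {i} (age {self.ages[i]}) not younger "
                    f"than parent {p} (age {self.ages[p]})"
                )
        if self.ages[self.root] <= 0:
            raise ValueError("root age must be positive")

    def copy(self) -> "TimeTree":
        t = TimeTree.__new__(TimeTree)
        t.taxa = self.taxa
        t.parent = self.parent.copy()
        t.children = self.children.copy()
        t.ages = self.ages.copy()
        t.topology_version = self.topology_version
        t._post = self._post
        return t

    def invalidate_topology(self) -> None:
        self.topology_version = next(_TOPOLOGY_TOKENS)
        self._post = None

    # ------------------------------------------------------------- traversals
    def postorder(self) -> np.ndarray:
        """Node ids, children always before parents (tips included)."""
        if self._post is not None:
            return self._post
        order = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            if not self.is_tip(node):
                stack.extend(self.children[node])
        post = np.array(order[::-1], dtype=np.int64)
        self._post = post
        return post

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1]

    def internal_nodes(self) -> np.ndarray:
        return np.arange(self.n_tips, self.n_nodes, dtype=np.int64)

    def durations(self) -> np.ndarray:
        """Branch duration above each node (My); 0 for the root."""
        dur = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        dur[has_parent] = self.ages[self.parent[has_parent]] - self.ages[has_parent]
        return dur

    # ----------------------------------------------------------------- clades
    def clade_tip_indices(self) -> dict[int, frozenset[int]]:
        """Tip-index set below each node."""
        sets: dict[int, frozenset[int]] = {}
        for node in self.postorder():
            if self.is_tip(node):
                sets[node] = frozenset((node,))
            else:
                a, b = self.children[node]
                sets[node] = sets[a] | sets[b]
        return sets

    def clade_taxon_sets(self) -> dict[int, frozenset[str]]:
        return {
            node: frozenset(self.taxa[i] for i in tips)
            for node, tips in self.clade_tip_indices().items()
        }

    def find_clade(self, taxa: Iterable[str]) -> int | None:
        """Node whose tip set equals ``taxa``, or None if not a clade here."""
        target = frozenset(taxa)
        for node, tips in self.clade_taxon_sets().items():
            if tips == target:
                return node
        return None

    def is_monophyletic(self, taxa: Iterable[str]) -> bool:
        return self.find_clade(taxa) is not None

    def mrca(self, taxa: Iterable[str]) -> int:
        """Most recent common ancestor of the given taxa."""
        want = {self.taxa.index(t) for t in taxa}
        sets = self.clade_tip_indices()
        best, best_size = self.root, self.n_tips + 1
        for node in self.postorder():
            tips = sets[node]
            if want <= tips and len(tips) < best_size:
                best, best_size = node, len(tips)
        return int(best)

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial clades (as taxon sets), root and tips excluded."""
        out = set()
        all_taxa = frozenset(self.taxa)
        for node, tips in self.clade_taxon_sets().items():
            if 1 < len(tips) < len(all_taxa):
                out.add(tips)
        return out

    # ------------------------------------------------------------------- I/O
    def to_newick(self, include_lengths: bool = True) -> str:
        def rec(node: int) -> str:
            if self.is_tip(node):
                label = _quote(self.taxa[node])
            else:
                a, b = self.children[node]
                label = f"({rec(a)},{rec(b)})"
            p = self.parent[node]
            if include_lengths and p >= 0:
                label += f":{self.ages[p] - self.ages[node]:.10g}"
            return label

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str, taxa: Sequence[str] | None = None) -> "TimeTree":
        """Parse a Newick string whose branch lengths are durations in My.

        Tips are placed at age 0; ages are recovered as (max root-to-tip
        depth) − depth, so non-ultrametric inputs are rejected.
        """
        dtree = dendropy.Tree.get(data=newick, schema="newick", suppress_internal_node_taxa=True)
        return cls.from_dendropy(dtree, taxa=taxa)

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree", taxa: Sequence[str] | None = None) -> "TimeTree":
        leaves = [lf for lf in dtree.leaf_node_iter()]
        labels = [lf.taxon.label for lf in leaves]
        if taxa is None:
            taxa = sorted(labels)
        if set(taxa) != set(labels):
            raise ValueError("taxon set mismatch between tree and expected taxa")
        n = len(taxa)
        index = {t: i for i, t in enumerate(taxa)}
        parent = np.full(2 * n - 1, -1, dtype=np.int64)
        children = np.full((2 * n - 1, 2), -1, dtype=np.int64)
        depth: dict[int, float] = {}
        ids: dict[int, int] = {}
        next_internal = n

        for node in dtree.preorder_node_iter():
            if node.parent_node is None:
                d = 0.0
            else:
                edge = node.edge.length if node.edge.length is not None else 0.0
                d = depth[id(node.parent_node)] + float(edge)
            depth[id(node)] = d
            if node.is_leaf():
                nid = index[node.taxon.label]
            else:
                kids = node.child_nodes()
                if len(kids) != 2:
                    raise ValueError("tree must be strictly bifurcating")
                nid = next_internal
                next_internal += 1
            ids[id(node)] = nid
            if node.parent_node is not None:
                pid = ids[id(node.parent_node)]
                slot = 0 if children[pid, 0] < 0 else 1
                children[pid, slot] = nid
                parent[nid] = pid

        tip_depths = np.array([depth[id(lf)] for lf in leaves])
        height = float(tip_depths.max())
        if height > 0 and not np.allclose(tip_depths, height, rtol=1e-6, atol=1e-6 * height):
            raise ValueError("tree is not ultrametric; cannot recover node ages")
        ages = np.zeros(2 * n - 1)
        for key, nid in ids.items():
            ages[nid] = height - depth[key]
        for i in range(n):
            ages[i] = 0.0
        return cls(taxa, parent, children, ages)


def _quote(label: str) -> str:
    if any(ch in label for ch in " ():,;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def random_constrained_topology(
    taxa: Sequence[str],
    constraints: Sequence[Iterable[str]],
    rng: np.random.Generator,
) -> TimeTree:
    """Random resolved rooted topology honoring monophyly constraints.

    Constraint clades must be nested-compatible (any two are disjoint or
    nested).  Ages are placeholders (node rank order) — callers draw real
    ages from the calibrated tree prior afterwards.
    """
    taxa = list(taxa)
    taxon_set = frozenset(taxa)
    clades = []
    for c in constraints:
        fc = frozenset(c)
        unknown = fc - taxon_set
        if unknown:
            raise ConstraintConflictError(f"constraint taxa not in taxon set: {sorted(unknown)}")
        if len(fc) >= 2 and fc != taxon_set and fc not in clades:
            clades.append(fc)
    for i, a in enumerate(clades):
        for b in clades[i + 1 :]:
            if a & b and not (a <= b or b <= a):
                raise ConstraintConflictError(
                    f"constraints overlap without nesting: {sorted(a)} vs {sorted(b)}"
                )

    n = len(taxa)
    index = {t: i for i, t in enumerate(taxa)}
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    children = np.full((2 * n - 1, 2), -1, dtype=np.int64)
    counter = [n]  # next internal node id

    def join(units: list[int]) -> int:
        """Randomly pair up subtree roots into one binary tree; return root id."""
        units = list(units)
        while len(units) > 1:
            i, j = rng.choice(len(units), size=2, replace=False)
            a, b = units[int(i)], units[int(j)]
            nid = counter[0]
            counter[0] += 1
            children[nid] = (a, b)
            parent[a] = nid
            parent[b] = nid
            units = [u for u in units if u not in (a, b)] + [nid]
        return units[0]

    def build(block: frozenset[str], avail: list[frozenset[str]]) -> int:
        inner = [c for c in avail if c < block]
        maximal = [c for c in inner if not any(c < d for d in inner)]
        covered: set[str] = set()
        units = []
        for c in sorted(maximal, key=lambda s: sorted(s)):
            units.append(build(c, inner))
            covered |= c
        for t in sorted(block - covered):
            units.append(index[t])
        if len(units) == 1:
            return units[0]
        return join(units)

    root = build(taxon_set, clades)
    # placeholder ages: each internal node older than its children by rank
    ages = np.zeros(2 * n - 1)
    order = []
    stack = [root]
    while stack:
        node = stack.pop()
        order.append(node)
        if children[node, 0] >= 0:
            stack.extend(children[node])
    for node in order[::-1]:
        if children[node, 0] >= 0:
            a, b = children[node]
            ages[node] = max(ages[a], ages[b]) + 1.0
    return TimeTree(taxa, parent, children, ages)
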