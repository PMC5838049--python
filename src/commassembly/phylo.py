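"""Rooted phylogenies with branch lengths: newick I/O, tree algebra, consensus.

The :class:`Phylogeny` container is a flat, postorder-indexed array
representation of a rooted tree.  It is the substrate for every
phylogenetic computation in the package: patristic distances (mean
pairwise phylogenetic distance), the Brownian-motion variance-covariance
matrix (Blomberg's K, trait simulation), Faith's PD, and the
Fritz-Purvis D bookkeeping.  Polytomies are allowed everywhere,
including in majority-rule consensus output.

Newick parsing is delegated to :mod:`dendropy`; writing is done here so
that branch lengths round-trip at shortest-repr precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from skbio import DistanceMatrix

__all__ = [
    "TreeError",
    "Phylogeny",
    "TreeSample",
    "read_newick",
    "write_newick",
    "load_tree",
    "save_tree",
    "majority_rule_consensus",
]

#: relative tolerance on root-to-tip depths used to flag ultrametric trees
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Raised for malformed, inconsistent, or degenerate tree input."""


class Phylogeny:
    """A rooted tree with tip labels and (optionally) branch lengths.

    Nodes are indexed ``0 .. n_nodes-1`` in postorder, with the root
    last.  ``children[i]`` lists the child indices of node ``i`` (empty
    for tips), ``lengths[i]`` is the length of the edge above node ``i``
    (``nan`` when absent; the root's entry is ignored) and ``labels[i]``
    is the node's label (required, unique and nonempty for tips).

    Parameters
    ----------
    children : sequence of sequences of int
        Child indices per node, in postorder.
    lengths : sequence of float
        Edge length above each node; ``nan`` for missing.
    labels : sequence of str or None
        Node labels; tips must be labelled.
    """

    def __init__(
        self,
        children: Sequence[Sequence[int]],
        lengths: Sequence[float],
        labels: Sequence[str | None],
    ) -> None:
        n = len(children)
        if not (n == len(lengths) == len(labels)):
            raise TreeError("children, lengths and labels must have equal size")
        if n == 0:
            raise TreeError("empty tree")
        self.children: tuple[tuple[int, ...], ...] = tuple(
            tuple(int(c) for c in ch) for ch in children
        )
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels: tuple[str | None, ...] = tuple(labels)
        self._validate()

    # ------------------------------------------------------------------
    # construction / validation
    # ------------------------------------------------------------------

    def _validate(self) -> None:
        n = self.n_nodes
        seen_as_child = np.zeros(n, dtype=bool)
        for i, ch in enumerate(self.children):
            for c in ch:
                if not 0 <= c < i:
                    raise TreeError(
                        f"node {i}: child index {c} violates postorder numbering"
                    )
                if seen_as_child[c]:
                    raise TreeError(f"node {c} has more than one parent")
                seen_as_child[c] = True
        if seen_as_child[n - 1]:
            raise TreeError("root (last node) must not be a child")
        if not seen_as_child[: n - 1].all():
            orphan = int(np.flatnonzero(~seen_as_child[: n - 1])[0])
            raise TreeError(f"node {orphan} is disconnected from the root")
        tips = [i for i, ch in enumerate(self.children) if not ch]
        labels = [self.labels[i] for i in tips]
        if any(lbl is None or lbl == "" for lbl in labels):
            raise TreeError("every tip must carry a nonempty label")
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
        finite = self.lengths[np.isfinite(self.lengths)]
        if (finite < 0).any():
            raise TreeError("negative branch length")

    @classmethod
    def _from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        order = list(dtree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(order)}
        children, lengths, labels = [], [], []
        for nd in order:
            children.append([index[id(c)] for c in nd.child_nodes()])
            l = nd.edge.length
            lengths.append(float("nan") if l is None else float(l))
            if nd.is_leaf():
                lbl = nd.taxon.label if nd.taxon is not None else nd.label
                labels.append(lbl)
            else:
                labels.append(nd.label)
        return cls(children, lengths, labels)

    # ------------------------------------------------------------------
    # basic structure
    # ------------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.children)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tip_nodes(self) -> np.ndarray:
        """Node indices of the tips, in postorder (left-to-right)."""
        return np.array([i for i, ch in enumerate(self.children) if not ch])

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_nodes]

    @property
    def n_tips(self) -> int:
        return len(self.tip_nodes)

    @property
    def parent(self) -> np.ndarray:
        """Parent index per node (-1 for the root)."""
        p = np.full(self.n_nodes, -1, dtype=int)
        for i, ch in enumerate(self.children):
            p[list(ch)] = i
        return p

    def _require_lengths(self) -> np.ndarray:
        """Branch lengths with the root entry zeroed; error on missing."""
        lengths = self.lengths.copy()
        lengths[self.root] = 0.0
        if np.isnan(lengths).any():
            bad = int(np.flatnonzero(np.isnan(lengths))[0])
            raise TreeError(f"missing branch length above node {bad}")
        return lengths

    @property
    def depths(self) -> np.ndarray:
        """Root-to-node path length per node (root depth 0)."""
        lengths = self._require_lengths()
        depth = np.zeros(self.n_nodes)
        for node in range(self.n_nodes - 1, -1, -1):  # preorder
            for c in self.children[node]:
                depth[c] = depth[node] + lengths[c]
        return depth

    @property
    def total_branch_length(self) -> float:
        lengths = self._require_lengths()
        return float(lengths.sum() - lengths[self.root])

    @property
    def is_ultrametric(self) -> bool:
        d = self.depths[self.tip_nodes]
        span = d.max() - d.min()
        return bool(span <= ULTRAMETRIC_RTOL * max(d.max(), 1e-300))

    # ------------------------------------------------------------------
    # tree algebra
    # ------------------------------------------------------------------

    def vcv(self) -> np.ndarray:
        """Brownian-motion variance-covariance matrix among tips.

        ``V[i, j]`` is the root-to-MRCA path length of tips ``i`` and
        ``j`` (the shared evolutionary history under Brownian motion);
        ``V[i, i]`` is the root-to-tip depth.  Tip order matches
        :attr:`tip_labels`.
        """
        depth = self.depths
        tip_nodes = self.tip_nodes
        pos = {int(t): k for k, t in enumerate(tip_nodes)}
        n = len(tip_nodes)
        V = np.zeros((n, n))
        below: list[list[int] | None] = [None] * self.n_nodes
        for node in range(self.n_nodes):
            ch = self.children[node]
            if not ch:
                below[node] = [pos[node]]
                continue
            sets = [below[c] for c in ch]
            d = depth[node]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    V[np.ix_(sets[a], sets[b])] = d
                    V[np.ix_(sets[b], sets[a])] = d
            below[node] = [t for s in sets for t in s]
        V[np.diag_indices(n)] = depth[tip_nodes]
        return V

    def patristic_distances(self) -> DistanceMatrix:
        """Pairwise path-length (patristic) distances among tips."""
        if self.n_tips < 2:
            raise TreeError("patristic distances require at least 2 tips")
        V = self.vcv()
        depth = np.diag(V)
        D = depth[:, None] + depth[None, :] - 2.0 * V
        D = 0.5 * (D + D.T)
        np.fill_diagonal(D, 0.0)
        D[D < 0] = 0.0
        return DistanceMatrix(D, ids=self.tip_labels)

    def prune_to(self, keep: Iterable[str]) -> "Phylogeny":
        """Restrict the tree to a subset of tips.

        Degree-2 internal nodes created by the pruning are collapsed and
        their edge lengths summed, so patristic distances among the kept
        tips are preserved exactly.
        """
        keep_set = set(keep)
        if not keep_set:
            raise TreeError("cannot prune to an empty tip set")
        missing = sorted(keep_set - set(self.tip_labels))
        if missing:
            raise TreeError(f"unknown species: {missing}")

        # rep[node]: None, or (children_reps, length_above, label)
        # where children_reps == [] marks a kept tip.
        rep: list[tuple | None] = [None] * self.n_nodes
        for node in range(self.n_nodes):
            ch = self.children[node]
            length = float(self.lengths[node])
            if not ch:
                if self.labels[node] in keep_set:
                    rep[node] = ([], length, self.labels[node])
                continue
            kept = [rep[c] for c in ch if rep[c] is not None]
            if not kept:
                continue
            if len(kept) == 1:
                sub_ch, sub_len, sub_lbl = kept[0]
                rep[node] = (sub_ch, sub_len + length, sub_lbl)
            else:
                rep[node] = (kept, length, self.labels[node])

        top = rep[self.root]
        assert top is not None
        children: list[list[int]] = []
        lengths: list[float] = []
        labels: list[str | None] = []

        def build(node_rep: tuple, is_root: bool) -> int:
            sub, length, label = node_rep
            idx_children = [build(c, False) for c in sub]
            children.append(idx_children)
            lengths.append(float("nan") if is_root else length)
            labels.append(label)
            return len(children) - 1

        build(top, True)
        return Phylogeny(children, lengths, labels)

    # ------------------------------------------------------------------
    # newick I/O
    # ------------------------------------------------------------------

    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Phylogeny: {self.n_tips} tips, {self.n_nodes} nodes>"


def _fmt_length(x: float) -> str:
    if math.isnan(x):
        return ""
    return ":" + np.format_float_positional(x, trim="-")


def write_newick(tree: Phylogeny) -> str:
    """Serialize a :class:`Phylogeny` to a newick string.

    Branch lengths are written at shortest round-trip precision;
    internal node labels (e.g. consensus support) are included.
    """

    def render(node: int, with_length: bool) -> str:
        ch = tree.children[node]
        label = tree.labels[node] or ""
        suffix = _fmt_length(float(tree.lengths[node])) if with_length else ""
        if not ch:
            return f"{label}{suffix}"
        inner = ",".join(render(c, True) for c in ch)
        return f"({inner}){label}{suffix}"

    return render(tree.root, False) + ";"


def read_newick(text: str) -> Phylogeny:
    """Parse a rooted newick string into a :class:`Phylogeny`.

    Basal polytomies are allowed; duplicate or empty tip labels and
    malformed syntax raise :class:`TreeError`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed newick: {exc}") from exc
    if dtree.seed_node is None or not dtree.seed_node.child_nodes():
        raise TreeError("newick string encodes no tree")
    return Phylogeny._from_dendropy(dtree)


def load_tree(path: str | Path) -> Phylogeny:
    return read_newick(Path(path).read_text())


def save_tree(tree: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(write_newick(tree) + "\n")


# ----------------------------------------------------------------------
# tree samples and majority-rule consensus
# ----------------------------------------------------------------------


@dataclass
class TreeSample:
    """An ordered collection of trees over an identical tip set."""

    trees: list[Phylogeny]
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.trees:
            raise TreeError("TreeSample must contain at least one tree")
        ref = set(self.trees[0].tip_labels)
        for k, t in enumerate(self.trees[1:], start=1):
            if set(t.tip_labels) != ref:
                raise TreeError(f"tree {k} has a different tip set from tree 0")


def _clades(tree: Phylogeny) -> dict[int, frozenset[str]]:
    """Tip-label set below each node."""
    out: dict[int, frozenset[str]] = {}
    for node in range(tree.n_nodes):
        ch = tree.children[node]
        if not ch:
            out[node] = frozenset([tree.labels[node]])
        else:
            s: set[str] = set()
            for c in ch:
                s |= out[c]
            out[node] = frozenset(s)
    return out


def majority_rule_consensus(
    sample: TreeSample | Sequence[Phylogeny],
    threshold: float = 0.5,
    lengths: str = "mean",
) -> Phylogeny:
    """Majority-rule consensus of rooted trees.

    A rooted clade (the tip set below an internal node) is retained when
    it occurs in strictly more than ``threshold`` of the trees; retained
    clades are always mutually compatible for ``threshold >= 0.5``.  The
    edge length above a retained clade is the mean (or median, with
    ``lengths="median"``) of that edge's length over the trees that
    contain the clade.  Clade support fractions are written as internal
    node labels and exposed on the result as ``clade_support``.
    """
    if isinstance(sample, TreeSample):
        trees = sample.trees
    else:
        trees = list(sample)
        TreeSample(trees)  # validates shared tip set
    if not 0.5 <= threshold <= 1.0:
        raise TreeError("consensus threshold must be in [0.5, 1.0]")
    if lengths not in ("mean", "median"):
        raise TreeError("lengths must be 'mean' or 'median'")

    n = len(trees)
    counts: dict[frozenset[str], int] = {}
    edge_lengths: dict[frozenset[str], list[float]] = {}
    for t in trees:
        clades = _clades(t)
        for node, clade in clades.items():
            if len(clade) > 1:
                counts[clade] = counts.get(clade, 0) + 1
            l = float(t.lengths[node]) if node != t.root else float("nan")
            edge_lengths.setdefault(clade, []).append(l)

    all_tips = frozenset(trees[0].tip_labels)
    retained = {c for c, k in counts.items() if k / n > threshold}
    retained.add(all_tips)
    singletons = [frozenset([lbl]) for lbl in sorted(all_tips)]

    def mean_length(clade: frozenset[str]) -> float:
        vals = [v for v in edge_lengths.get(clade, []) if not math.isnan(v)]
        if not vals:
            return float("nan")
        agg = np.median if lengths == "median" else np.mean
        return float(agg(vals))

    # nest clades: parent = smallest retained clade strictly containing it
    ordered = sorted(retained, key=len, reverse=True)
    tree_children: dict[frozenset[str], list[frozenset[str]]] = {
        c: [] for c in ordered
    }
    for clade in ordered[1:] + singletons:
        parent = min(
            (p for p in ordered if len(p) > len(clade) and clade < p), key=len
        )
        tree_children[parent].append(clade)

    children: list[list[int]] = []
    out_lengths: list[float] = []
    out_labels: list[str | None] = []
    support: dict[frozenset[str], float] = {}

    def build(clade: frozenset[str], is_root: bool) -> int:
        if len(clade) == 1:
            idx_children: list[int] = []
            label: str | None = next(iter(clade))
        else:
            idx_children = [build(c, False) for c in tree_children[clade]]
            freq = counts.get(clade, n) / n
            support[clade] = freq
            label = np.format_float_positional(freq, trim="-")
        children.append(idx_children)
        out_lengths.append(float("nan") if is_root else mean_length(clade))
        out_labels.append(label)
        return len(children) - 1

    build(all_tips, True)
    out = Phylogeny(children, out_lengths, out_labels)
    out.clade_support = support  # type: ignore[attr-defined]
    return out
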