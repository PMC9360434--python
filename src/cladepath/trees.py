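"""Rooted phylogenies: Newick I/O, traversal primitives, genus collapsing.

The tree is stored as flat parent/child/length arrays indexed by node id
(preorder from the root), which keeps the downstream rate statistics and
GLS covariance construction simple and fast.  Parsing is delegated to
dendropy; serialization is a small recursive writer so that branch lengths
round-trip at 12 significant digits.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "Tree",
    "parse_newick",
    "write_newick",
    "read_newick",
    "root_to_tip_path",
    "collapse_to_genera",
    "prune_to_tips",
    "read_genus_map",
]


class TreeError(ValueError):
    """Raised for structurally invalid trees or tree queries."""


class Tree:
    """A rooted tree with branch lengths, stored as flat arrays.

    Attributes
    ----------
    parent : (m,) int array, -1 for the root.
    children : list of lists of child ids (input order preserved).
    lengths : (m,) float array; branch length to the parent (0.0 at root).
    labels : list of tip label or None per node.
    root : id of the root node.
    """

    def __init__(self, parent, children, lengths, labels):
        self.parent = np.asarray(parent, dtype=int)
        self.children = [list(c) for c in children]
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels = list(labels)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self._validate()
        self.tips = [i for i, c in enumerate(self.children) if not c]
        self.tip_labels = [self.labels[i] for i in self.tips]
        self._tip_index = {self.labels[i]: i for i in self.tips}

    # -- construction / validation -------------------------------------
    def _validate(self):
        m = len(self.parent)
        if not (len(self.children) == len(self.lengths) == len(self.labels) == m):
            raise TreeError("inconsistent array lengths")
        for i in range(m):
            if i != self.root and not np.isfinite(self.lengths[i]):
                raise TreeError(f"node {i} lacks a branch length")
            if i != self.root and self.lengths[i] < 0:
                raise TreeError(f"negative branch length at node {i}")
        seen = {}
        for i, c in enumerate(self.children):
            if not c and self.labels[i] is None:
                raise TreeError(f"unlabeled tip at node {i}")
            if not c:
                if self.labels[i] in seen:
                    raise TreeError(f"duplicate tip label {self.labels[i]!r}")
                seen[self.labels[i]] = i
        # acyclicity: every node must reach the root in <= m steps
        for i in range(m):
            j, steps = i, 0
            while j != self.root:
                j = self.parent[j]
                steps += 1
                if steps > m:
                    raise TreeError("cycle detected in parent pointers")
        if np.any(self.lengths[[i for i in range(m) if i != self.root]] == 0):
            warnings.warn("tree contains zero-length branches", stacklevel=3)

    # -- basic queries ---------------------------------------------------
    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def tip_id(self, label: str) -> int:
        try:
            return self._tip_index[label]
        except KeyError:
            raise TreeError(f"unknown tip label {label!r}") from None

    def preorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def postorder(self) -> list[int]:
        return self.preorder()[::-1]

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node (root depth 0)."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder():
            if v != self.root:
                d[v] = d[self.parent[v]] + self.lengths[v]
        return d

    def height(self) -> float:
        return float(self.depths().max())

    def subtree_tips(self, node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if not self.children[v]:
                out.append(v)
            else:
                stack.extend(self.children[v])
        return out

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children if c is not None) and all(
            len(self.children[v]) != 1 for v in range(self.n_nodes)
        ) and len(self.children[self.root]) == 2

    def mrca(self, a: int, b: int) -> int:
        anc = set()
        v = a
        while True:
            anc.add(v)
            if v == self.root:
                break
            v = int(self.parent[v])
        v = b
        while v not in anc:
            v = int(self.parent[v])
        return v

    def tip_covariance(self) -> np.ndarray:
        """BM tip covariance: shared root-path length of each tip pair."""
        d = self.depths()
        n = self.n_tips
        V = np.zeros((n, n))
        pos = {t: k for k, t in enumerate(self.tips)}
        for v in self.postorder():
            kids = self.children[v]
            if not kids:
                continue
            groups = [[pos[t] for t in self.subtree_tips(c)] for c in kids]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        V[a, groups[gj]] = d[v]
                        V[np.array(groups[gj]), a] = d[v]
        for t in self.tips:
            V[pos[t], pos[t]] = d[t]
        return V

    # -- serialization ---------------------------------------------------
    def newick(self) -> str:
        def fmt(v: int) -> str:
            if self.children[v]:
                inner = ",".join(fmt(c) for c in self.children[v])
                s = f"({inner})"
            else:
                s = self.labels[v]
            if v != self.root:
                s += f":{self.lengths[v]:.12g}"
            elif self.lengths[v]:
                s += f":{self.lengths[v]:.12g}"
            return s

        return fmt(self.root) + ";"

    def copy(self) -> "Tree":
        return Tree(self.parent.copy(), self.children, self.lengths.copy(), self.labels)

    def __repr__(self) -> str:
        return f"<Tree: {self.n_tips} tips, {self.n_nodes} nodes>"


def parse_newick(text: str) -> Tree:
    """Parse one rooted Newick tree.

    Branch lengths are required on every non-root edge; duplicate tip
    labels, negative lengths, and malformed parentheses raise
    :class:`TreeError`.  NHX-style comments are stripped with a warning.
    """
    if "[" in text:
        warnings.warn("stripping bracketed comments from Newick input", stacklevel=2)
        out, depth = [], 0
        for ch in text:
            if ch == "[":
                depth += 1
            elif ch == "]":
                depth = max(0, depth - 1)
            elif depth == 0:
                out.append(ch)
        text = "".join(out)
    try:
        dt = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed Newick: {exc}") from exc

    ids: dict[int, int] = {}
    parent, children, lengths, labels = [], [], [], []
    for nd in dt.preorder_node_iter():
        i = len(parent)
        ids[id(nd)] = i
        if nd.parent_node is None:
            parent.append(-1)
            lengths.append(float(nd.edge.length or 0.0))
        else:
            parent.append(ids[id(nd.parent_node)])
            if nd.edge.length is None:
                raise TreeError("missing branch length on a non-root edge")
            lengths.append(float(nd.edge.length))
            children[parent[-1]].append(i)
        children.append([])
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise TreeError("unlabeled tip")
            labels.append(nd.taxon.label.replace(" ", "_"))
        else:
            labels.append(None)
    return Tree(parent, children, lengths, labels)


def write_newick(tree: Tree, path=None) -> str:
    s = tree.newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


def read_newick(path) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read())


def root_to_tip_path(tree: Tree, tip: str) -> list[tuple[float, int]]:
    """Ordered (branch length, node id) list from a tip's own branch to the root.

    The first entry is the tip's pendant branch; the list has one entry per
    edge between the tip and the root, so its lengths sum to the tip depth.
    """
    v = tree.tip_id(tip)
    out = []
    while v != tree.root:
        out.append((float(tree.lengths[v]), v))
        v = int(tree.parent[v])
    return out


def prune_to_tips(tree: Tree, keep: Iterable[str]) -> Tree:
    """Restrict to a tip subset; unifurcations are suppressed with branch
    lengths summed, so every retained tip keeps its root distance."""
    keep = set(keep)
    unknown = keep - set(tree.tip_labels)
    if unknown:
        raise TreeError(f"unknown tip labels: {sorted(unknown)}")
    if not keep:
        raise TreeError("cannot prune to an empty tip set")

    keep_node = np.zeros(tree.n_nodes, dtype=bool)
    for v in tree.postorder():
        if not tree.children[v]:
            keep_node[v] = tree.labels[v] in keep
        else:
            keep_node[v] = any(keep_node[c] for c in tree.children[v])

    # rebuild top-down, summing lengths through dropped unifurcations
    parent, children, lengths, labels = [], [], [], []

    def build(v: int, extra: float, new_parent: int) -> None:
        kids = [c for c in tree.children[v] if keep_node[c]]
        if len(kids) == 1 and tree.children[v]:
            build(kids[0], extra + tree.lengths[kids[0]], new_parent)
            return
        i = len(parent)
        parent.append(new_parent)
        children.append([])
        lengths.append(extra)
        labels.append(tree.labels[v])
        if new_parent >= 0:
            children[new_parent].append(i)
        for c in kids:
            build(c, float(tree.lengths[c]), i)

    r = tree.root
    # if the root itself became unifurcating, descend to the first fork
    extra = float(tree.lengths[r]) if tree.lengths[r] else 0.0
    while sum(keep_node[c] for c in tree.children[r]) == 1 and tree.children[r]:
        (r,) = [c for c in tree.children[r] if keep_node[c]]
        extra += float(tree.lengths[r])
    build(r, extra, -1)
    return Tree(parent, children, lengths, labels)


def read_genus_map(path) -> dict[str, str]:
    """2-column TSV (tip_label, genus) -> dict."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tip, genus = line.split("\t")[:2]
            out[tip] = genus
    return out


def assign_genus_clades(tree: Tree, genus_map: Mapping[str, str]) -> dict[str, list[str]]:
    """For each genus, the members recovered in its core clade.

    The core clade is the largest pure clade (an internal node or single tip
    whose descendant tips all belong to the genus) — species outside it are
    treated as misplaced and dropped from richness tallies and collapsing.
    Ties are broken by preorder position.
    """
    unmapped = [t for t in tree.tip_labels if t not in genus_map]
    if unmapped:
        raise TreeError(f"tips missing from genus map: {unmapped[:5]}")
    order = tree.preorder()
    retained: dict[str, list[str]] = {}
    for genus in dict.fromkeys(genus_map[t] for t in tree.tip_labels):
        members = {t for t in tree.tip_labels if genus_map[t] == genus}
        best: list[str] = []
        for v in order:
            tips = [tree.labels[t] for t in tree.subtree_tips(v)]
            if set(tips) <= members and len(tips) > len(best):
                best = tips
        retained[genus] = sorted(best)
    return retained


def collapse_to_genera(
    tree: Tree,
    genus_map: Mapping[str, str],
    occurrence_counts: Mapping[str, int] | None = None,
) -> tuple[Tree, dict[str, str]]:
    """Collapse to one tip per genus.

    The representative tip is the retained congener with the most occurrence
    records (ties alphabetical); its root distance is preserved.  Returns the
    collapsed tree and the genus -> representative-tip map; tip labels in the
    collapsed tree are replaced by genus names.
    """
    clades = assign_genus_clades(tree, genus_map)
    reps: dict[str, str] = {}
    for genus, members in clades.items():
        if not members:
            continue
        if occurrence_counts:
            key = lambda s: (-occurrence_counts.get(s, 0), s)
        else:
            key = lambda s: s
        reps[genus] = sorted(members, key=key)[0]
    if not reps:
        raise TreeError("no genus could be placed on the tree")
    pruned = prune_to_tips(tree, reps.values())
    rep_to_genus = {v: k for k, v in reps.items()}
    pruned.labels = [rep_to_genus.get(l, l) if l else None for l in pruned.labels]
    pruned.tip_labels = [pruned.labels[i] for i in pruned.tips]
    pruned._tip_index = {pruned.labels[i]: i for i in pruned.tips}
    return pruned, reps
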