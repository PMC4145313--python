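"""Reference phylogeny handling: parsing, midpoint rooting, branch-length queries.

The reference tree is the fixed scaffold against which marker-gene fragments
are placed.  Branch lengths are in substitutions/site.  Edges carry integer
numbers compatible with placement files (jplace ``{N}`` annotations); when a
newick string has no such annotations, deterministic post-order numbers are
assigned so that placements generated against the same tree remain joinable.
"""

from __future__ import annotations

import hashlib
import io
import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Tuple

import dendropy
import numpy as np

__all__ = [
    "ReferenceTree",
    "TreeError",
    "read_newick",
    "write_newick",
    "midpoint_root",
    "root_to_tip_lengths",
    "phylum_reference_medians",
    "read_taxonomy",
]

_EDGE_NUM_RE = re.compile(r"\{(\d+)\}")


class TreeError(ValueError):
    """Raised for malformed trees or invalid tree operations."""


def _median(values) -> float:
    """Median with the even-count rule: mean of the two central values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise TreeError("median of empty sequence")
    return float(np.median(arr))


@dataclass
class ReferenceTree:
    """Rooted (or rootable) phylogeny with branch lengths and edge numbers.

    Nodes are integer ids.  ``lengths[v]`` is the length of the edge above
    ``v`` (toward the parent); the root has length 0.  ``edge_nums[v]`` is the
    integer edge number of that same edge, matching placement files.
    """

    root: int
    parent: Dict[int, Optional[int]]
    children: Dict[int, List[int]]
    lengths: Dict[int, float]
    labels: Dict[int, str]  # tip node -> taxon id
    edge_nums: Dict[int, int] = field(default_factory=dict)
    rooted: bool = False

    # -- basic queries -----------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def tip_labels(self) -> List[str]:
        return [self.labels[v] for v in self._postorder() if v in self.labels]

    def nodes(self) -> List[int]:
        return list(self.parent)

    def is_tip(self, v: int) -> bool:
        return not self.children.get(v)

    def total_length(self) -> float:
        return float(sum(l for v, l in self.lengths.items() if v != self.root))

    def _postorder(self) -> Iterator[int]:
        stack = [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if done:
                yield v
            else:
                stack.append((v, True))
                for c in reversed(self.children.get(v, [])):
                    stack.append((c, False))

    def depths(self) -> Dict[int, float]:
        """Root-to-node path lengths for every node."""
        out = {self.root: 0.0}
        stack = list(self.children.get(self.root, []))
        while stack:
            v = stack.pop()
            out[v] = out[self.parent[v]] + self.lengths[v]
            stack.extend(self.children.get(v, []))
        return out

    def edge_by_number(self) -> Dict[int, int]:
        """Map edge number -> child node of that edge."""
        return {n: v for v, n in self.edge_nums.items()}

    def assign_postorder_edge_numbers(self) -> None:
        """Number every non-root edge 0..E-1 in post-order."""
        self.edge_nums = {}
        i = 0
        for v in self._postorder():
            if v != self.root:
                self.edge_nums[v] = i
                i += 1

    def checksum(self) -> str:
        """Stable digest of topology + lengths + edge numbers."""
        return hashlib.sha256(
            write_newick(self, edge_numbers=True).encode()
        ).hexdigest()

    def validate(self) -> None:
        if self.root not in self.parent:
            raise TreeError("root missing from node set")
        if self.parent[self.root] is not None:
            raise TreeError("root has a parent")
        seen = set()
        for v in self._postorder():
            if v in seen:
                raise TreeError("cycle detected")
            seen.add(v)
            if v != self.root and self.lengths[v] < 0:
                raise TreeError(f"negative branch length on node {v}")
        if seen != set(self.parent):
            raise TreeError("tree is not connected")
        labels = list(self.labels.values())
        if len(labels) != len(set(labels)):
            raise TreeError("duplicate tip labels")
        nums = list(self.edge_nums.values())
        if len(nums) != len(set(nums)):
            raise TreeError("duplicate edge numbers")


# -- newick I/O ------------------------------------------------------------


def read_newick(text: str) -> ReferenceTree:
    """Parse a newick string into a :class:`ReferenceTree`.

    jplace-style ``{N}`` edge-number annotations are honoured when present on
    every non-root edge; otherwise deterministic post-order numbers are
    assigned.  Every non-root edge must carry a branch length.
    """
    had_edge_nums = bool(_EDGE_NUM_RE.search(text))
    prepared = _EDGE_NUM_RE.sub(lambda m: f"[&edge={m.group(1)}]", text)
    try:
        dtree = dendropy.Tree.get(
            data=prepared,
            schema="newick",
            suppress_internal_node_taxa=True,
            extract_comment_metadata=False,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed newick: {exc}") from exc

    tree = ReferenceTree(root=0, parent={}, children={}, lengths={}, labels={})
    ids: Dict[object, int] = {}
    for i, nd in enumerate(dtree.preorder_node_iter()):
        ids[nd] = i
        tree.parent[i] = ids[nd.parent_node] if nd.parent_node else None
        tree.children[i] = []
        if nd.parent_node is not None:
            tree.children[ids[nd.parent_node]].append(i)
            if nd.edge.length is None:
                raise TreeError(
                    f"missing branch length on edge above node {i}"
                )
            tree.lengths[i] = float(nd.edge.length)
        else:
            tree.root = i
            tree.lengths[i] = 0.0
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise TreeError("unlabeled tip")
            tree.labels[i] = str(nd.taxon.label)
        for comment in nd.comments:
            m = re.fullmatch(r"&edge=(\d+)", comment)
            if m:
                tree.edge_nums[i] = int(m.group(1))

    n_edges = len(tree.parent) - 1
    if had_edge_nums and len(tree.edge_nums) != n_edges:
        raise TreeError(
            f"partial edge numbering: {len(tree.edge_nums)} of {n_edges} "
            "edges annotated"
        )
    if not had_edge_nums:
        tree.assign_postorder_edge_numbers()
    tree.rooted = len(tree.children[tree.root]) <= 2
    tree.validate()
    return tree


def write_newick(tree: ReferenceTree, edge_numbers: bool = False) -> str:
    """Serialize to newick; optionally with jplace ``{N}`` edge annotations."""

    def render(v: int) -> str:
        if tree.is_tip(v):
            body = tree.labels[v]
        else:
            body = "(" + ",".join(render(c) for c in tree.children[v]) + ")"
        if v == tree.root:
            return body
        out = f"{body}:{tree.lengths[v]:.12g}"
        if edge_numbers:
            out += "{%d}" % tree.edge_nums[v]
        return out

    return render(tree.root) + ";"


# -- rooting ---------------------------------------------------------------


def _undirected_adjacency(tree: ReferenceTree) -> Dict[int, List[Tuple[int, float]]]:
    adj: Dict[int, List[Tuple[int, float]]] = {v: [] for v in tree.parent}
    for v, p in tree.parent.items():
        if p is not None:
            adj[v].append((p, tree.lengths[v]))
            adj[p].append((v, tree.lengths[v]))
    return adj


def _distances_from(adj, start: int) -> Dict[int, float]:
    dist = {start: 0.0}
    stack = [start]
    while stack:
        u = stack.pop()
        for w, l in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + l
                stack.append(w)
    return dist


def _path(adj, a: int, b: int) -> List[int]:
    prev = {a: None}
    stack = [a]
    while stack:
        u = stack.pop()
        if u == b:
            break
        for w, _ in adj[u]:
            if w not in prev:
                prev[w] = u
                stack.append(w)
    path = [b]
    while prev[path[-1]] is not None:
        path.append(prev[path[-1]])
    return path[::-1]


def _reroot_at(tree: ReferenceTree, new_root: int) -> ReferenceTree:
    """Reorient all edges away from ``new_root``; suppress a stranded
    degree-2 former root so lengths and topology are conserved."""
    adj = _undirected_adjacency(tree)
    parent: Dict[int, Optional[int]] = {new_root: None}
    children: Dict[int, List[int]] = {v: [] for v in tree.parent}
    lengths: Dict[int, float] = {new_root: 0.0}
    stack = [new_root]
    while stack:
        u = stack.pop()
        for w, l in adj[u]:
            if w not in parent:
                parent[w] = u
                children[u].append(w)
                lengths[w] = l
                stack.append(w)
    out = ReferenceTree(
        root=new_root,
        parent=parent,
        children=children,
        lengths=lengths,
        labels=dict(tree.labels),
        rooted=True,
    )
    # old root may now be a pass-through (one child, one parent): merge it.
    old = tree.root
    if old != new_root and len(out.children[old]) == 1 and old not in out.labels:
        child = out.children[old][0]
        up = out.parent[old]
        out.lengths[child] = out.lengths[child] + out.lengths[old]
        out.parent[child] = up
        out.children[up][out.children[up].index(old)] = child
        del out.parent[old], out.children[old], out.lengths[old]
    out.assign_postorder_edge_numbers()
    return out


def midpoint_root(tree: ReferenceTree) -> ReferenceTree:
    """Root at the midpoint of the longest tip-to-tip path.

    The midpoint either coincides with an existing node (which becomes the
    root) or falls inside an edge, in which case a degree-2 root node is
    inserted; total tree length is conserved either way.  Ties in the longest
    path are broken by lexicographic tip-pair order.  Edge numbers are
    reassigned post-order on the returned tree.
    """
    if tree.n_tips < 2:
        raise TreeError("midpoint rooting requires at least 2 tips")
    adj = _undirected_adjacency(tree)
    tips = sorted(
        (v for v in tree.parent if tree.is_tip(v)), key=lambda v: tree.labels[v]
    )
    if tree.total_length() == 0.0:
        warnings.warn("all branch lengths zero; rooting at an internal node")
        internal = [v for v in tree.parent if not tree.is_tip(v)]
        return _reroot_at(tree, internal[0] if internal else tree.root)

    best: Tuple[float, Tuple[str, str], int, int] = (-1.0, ("", ""), -1, -1)
    dist_cache = {}
    for a in tips:
        dist_cache[a] = _distances_from(adj, a)
    for i, a in enumerate(tips):
        for b in tips[i + 1 :]:
            d = dist_cache[a][b]
            key = (tree.labels[a], tree.labels[b])
            if d > best[0] + 1e-15 or (abs(d - best[0]) <= 1e-15 and key < best[1]):
                best = (d, key, a, b)
    diameter, _, a, b = best
    target = diameter / 2.0

    path = _path(adj, a, b)
    acc = 0.0
    for u, v in zip(path, path[1:]):
        # length of undirected edge u-v
        l = tree.lengths[v] if tree.parent.get(v) == u else tree.lengths[u]
        if acc + l >= target - 1e-12:
            x = target - acc  # distance from u into edge u-v
            if x <= 1e-12:
                return _reroot_at(tree, u)
            if x >= l - 1e-12:
                return _reroot_at(tree, v)
            return _reroot_on_edge(tree, u, v, x)
        acc += l
    return _reroot_at(tree, b)  # numerically degenerate; root at far tip


def _reroot_on_edge(tree: ReferenceTree, u: int, v: int, x: float) -> ReferenceTree:
    """Insert a degree-2 root inside undirected edge u-v at distance x from u."""
    # orient: child end of the edge in the current structure
    if tree.parent.get(v) == u:
        child, par, from_parent = v, u, x  # x measured from parent side
    else:
        child, par, from_parent = u, v, tree.lengths[u] - x
    new_id = max(tree.parent) + 1
    t2 = ReferenceTree(
        root=tree.root,
        parent=dict(tree.parent),
        children={k: list(c) for k, c in tree.children.items()},
        lengths=dict(tree.lengths),
        labels=dict(tree.labels),
    )
    t2.parent[new_id] = par
    t2.children[par][t2.children[par].index(child)] = new_id
    t2.children[new_id] = [child]
    t2.parent[child] = new_id
    t2.lengths[new_id] = from_parent
    t2.lengths[child] = tree.lengths[child] - from_parent
    return _reroot_at(t2, new_id)


# -- branch-length queries -------------------------------------------------


def root_to_tip_lengths(tree: ReferenceTree) -> Dict[str, float]:
    """Sum of branch lengths on the root->tip path, keyed by taxon id."""
    if not tree.rooted:
        raise TreeError("tree is unrooted; apply midpoint_root first")
    depths = tree.depths()
    return {tree.labels[v]: depths[v] for v in tree.labels}


def phylum_reference_medians(
    tree: ReferenceTree, taxonomy: Dict[str, str]
) -> Dict[str, float]:
    """Per-phylum median of tip root-to-tip lengths.

    Every tip must be mapped to a phylum.  Phyla with zero mapped tips are
    simply absent from the result (a warning is emitted if the taxonomy names
    phyla with no tips on the tree).
    """
    tip_lengths = root_to_tip_lengths(tree)
    missing = [t for t in tip_lengths if t not in taxonomy]
    if missing:
        raise TreeError(f"tips missing from taxonomy: {missing[:5]}")
    groups: Dict[str, List[float]] = {}
    for taxon, length in tip_lengths.items():
        groups.setdefault(taxonomy[taxon], []).append(length)
    empty = set(taxonomy.values()) - set(groups)
    if empty:
        warnings.warn(f"phyla with no tips on the tree: {sorted(empty)}")
    return {ph: _median(v) for ph, v in sorted(groups.items())}


def read_taxonomy(source) -> Dict[str, str]:
    """Read a ``taxon_id<TAB>phylum`` TSV (header required) into a dict."""
    if hasattr(source, "read"):
        fh = source
    elif isinstance(source, str) and "\t" in source:
        fh = io.StringIO(source)
    else:
        fh = open(source, encoding="utf-8")
    try:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise TreeError("taxonomy TSV must have taxon_id and phylum columns")
        out: Dict[str, str] = {}
        for line in fh:
            if not line.strip():
                continue
            taxon, phylum = line.rstrip("\n").split("\t")[:2]
            if taxon in out:
                raise TreeError(f"duplicate taxon in taxonomy: {taxon}")
            out[taxon] = phylum
        return out
    finally:
        if fh is not source:
            fh.close()
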