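"""Unrooted leaf-labeled trees, Newick I/O and Robinson-Foulds distances.

Trees are stored in unrooted canonical form: a rooted Newick string is read
as an unrooted tree, and every internal node of degree 2 (including the
artificial "root" of a bifurcating Newick expression) is suppressed, summing
branch lengths across the removed node.  Topology identity is defined by the
set of non-trivial bipartitions (splits) induced by internal edges.

The Robinson-Foulds (RF) distance used throughout the package counts, for an
ordered pair of trees on the same leaf set, how many splits of the first tree
have no matching split in the second.  On binary trees this coincides with
the usual halved symmetric difference: it is symmetric, zero iff the
topologies agree, and at most ``n - 3`` on ``n`` leaves.  Against a
multifurcating reference (e.g. a taxonomy with polytomies) only the splits
the reference actually resolves can be missed, so the maximum distance is
the reference's internal-edge count, strictly below ``n - 3``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Optional, Set, Tuple

__all__ = [
    "Bipartition",
    "NewickError",
    "PhyloTree",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "restrict_to_leaves",
    "rf_distance",
    "rf_to_reference",
    "max_rf",
    "relative_rf",
    "zero_one_distance",
    "read_newick_file",
]


class NewickError(ValueError):
    """Malformed Newick input; ``offset`` is the 0-based character position."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class TreeValidationError(ValueError):
    """Semantically invalid tree or invalid operation arguments."""


@dataclass(frozen=True)
class Bipartition:
    """A non-trivial split of a leaf set induced by one internal edge.

    Canonical orientation: ``side_a`` is the side containing the
    lexicographically smallest leaf, so equality and hashing are well
    defined regardless of how the split was produced.
    """

    side_a: frozenset
    side_b: frozenset

    def __post_init__(self):
        a, b = frozenset(self.side_a), frozenset(self.side_b)
        if not a or not b:
            raise TreeValidationError("bipartition sides must be non-empty")
        if a & b:
            raise TreeValidationError("bipartition sides must be disjoint")
        if min(b) < min(a):
            a, b = b, a
        object.__setattr__(self, "side_a", a)
        object.__setattr__(self, "side_b", b)

    @property
    def leaves(self) -> frozenset:
        return self.side_a | self.side_b

    def is_trivial(self) -> bool:
        return len(self.side_a) < 2 or len(self.side_b) < 2

    def restrict(self, keep: Iterable[str]) -> Optional["Bipartition"]:
        """Restriction to a leaf subset, or ``None`` if it becomes trivial."""
        keep = frozenset(keep)
        a, b = self.side_a & keep, self.side_b & keep
        if len(a) < 2 or len(b) < 2:
            return None
        return Bipartition(a, b)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        fmt = lambda s: ",".join(sorted(s))
        return f"{fmt(self.side_a)}|{fmt(self.side_b)}"


class PhyloTree:
    """An unrooted tree with uniquely labeled leaves and optional lengths.

    Instances are treated as immutable; all operations return new trees.
    """

    def __init__(
        self,
        adjacency: Dict[int, Dict[int, Optional[float]]],
        leaf_labels: Dict[int, str],
    ):
        self._adj = {u: dict(nbrs) for u, nbrs in adjacency.items()}
        self._labels = dict(leaf_labels)
        self._canonicalize()
        self._validate()
        self._by_label = {lab: u for u, lab in self._labels.items()}
        self._splits: Optional[frozenset] = None

    # -- construction helpers -------------------------------------------------

    def _canonicalize(self) -> None:
        """Suppress unlabeled degree-2 nodes (summing branch lengths)."""
        changed = True
        while changed:
            changed = False
            for u in list(self._adj):
                if u in self._labels:
                    continue
                nbrs = self._adj[u]
                if len(nbrs) == 2:
                    (a, la), (b, lb) = nbrs.items()
                    length = la + lb if (la is not None and lb is not None) else None
                    del self._adj[u]
                    del self._adj[a][u]
                    del self._adj[b][u]
                    self._adj[a][b] = length
                    self._adj[b][a] = length
                    changed = True

    def _validate(self) -> None:
        labels = list(self._labels.values())
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise TreeValidationError(f"duplicate leaf labels: {dup}")
        for u, nbrs in self._adj.items():
            if u in self._labels:
                if len(nbrs) > 1:
                    raise TreeValidationError(
                        f"leaf {self._labels[u]!r} has degree {len(nbrs)}"
                    )
            elif len(nbrs) < 3 and len(self._adj) > 1:
                raise TreeValidationError("internal node of degree < 3 survived")
        # connectivity
        if self._adj:
            seen: Set[int] = set()
            stack = [next(iter(self._adj))]
            while stack:
                u = stack.pop()
                if u in seen:
                    continue
                seen.add(u)
                stack.extend(self._adj[u])
            if seen != set(self._adj):
                raise TreeValidationError("tree is not connected")

    # -- basic queries ---------------------------------------------------------

    @property
    def leaves(self) -> frozenset:
        return frozenset(self._labels.values())

    @property
    def n_leaves(self) -> int:
        return len(self._labels)

    def is_binary(self) -> bool:
        """True iff every internal node has degree exactly 3."""
        return all(
            len(nbrs) == 3
            for u, nbrs in self._adj.items()
            if u not in self._labels
        )

    def has_branch_lengths(self) -> bool:
        return all(
            l is not None for nbrs in self._adj.values() for l in nbrs.values()
        )

    def edges(self) -> Iterator[Tuple[int, int, Optional[float]]]:
        for u, nbrs in self._adj.items():
            for v, l in nbrs.items():
                if u < v:
                    yield u, v, l

    def leaf_path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        if a not in self._by_label or b not in self._by_label:
            raise TreeValidationError(f"unknown leaf label {a!r} or {b!r}")
        src, dst = self._by_label[a], self._by_label[b]
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            if u == dst:
                return dist[u]
            for v, l in self._adj[u].items():
                if v not in dist:
                    if l is None:
                        raise TreeValidationError("missing branch length on path")
                    dist[v] = dist[u] + l
                    stack.append(v)
        raise TreeValidationError("leaves not connected")  # pragma: no cover

    # -- splits ----------------------------------------------------------------

    def bipartitions(self) -> frozenset:
        """The set of non-trivial :class:`Bipartition` of this tree."""
        if self._splits is not None:
            return self._splits
        n = self.n_leaves
        if n < 4:
            self._splits = frozenset()
            return self._splits
        all_leaves = self.leaves
        # Root at an arbitrary leaf; the leaf set below each tree edge gives
        # one candidate split per edge, each internal edge exactly once.
        root = next(iter(self._labels))
        below: Dict[Tuple[int, int], Set[str]] = {}
        order: List[Tuple[int, int]] = []
        stack: List[Tuple[int, int]] = [(root, v) for v in self._adj[root]]
        visited = {root}
        while stack:
            u, v = stack.pop()
            visited.add(v)
            order.append((u, v))
            for w in self._adj[v]:
                if w not in visited:
                    stack.append((v, w))
        splits: Set[Bipartition] = set()
        for u, v in reversed(order):
            if v in self._labels:
                below[(u, v)] = {self._labels[v]}
            else:
                s: Set[str] = set()
                for w in self._adj[v]:
                    if w != u:
                        s |= below[(v, w)]
                below[(u, v)] = s
            if 2 <= len(below[(u, v)]) <= n - 2:
                side = frozenset(below[(u, v)])
                splits.add(Bipartition(side, all_leaves - side))
        self._splits = frozenset(splits)
        return self._splits

    # -- manipulation ----------------------------------------------------------

    def restrict(self, keep: Iterable[str]) -> "PhyloTree":
        """Prune to ``keep`` and suppress any resulting degree-2 nodes."""
        keep = set(keep)
        unknown = keep - self.leaves
        if unknown:
            raise TreeValidationError(f"unknown leaf labels: {sorted(unknown)}")
        if not keep:
            raise TreeValidationError("cannot restrict to an empty leaf set")
        adj = {u: dict(nbrs) for u, nbrs in self._adj.items()}
        labels = {u: lab for u, lab in self._labels.items() if lab in keep}
        # Iteratively strip dropped leaves and dangling internal nodes.
        frontier = [u for u, lab in self._labels.items() if lab not in keep]
        while frontier:
            u = frontier.pop()
            for v in list(adj[u]):
                del adj[v][u]
                if len(adj[v]) == 1 and v not in labels:
                    frontier.append(v)
            del adj[u]
        return PhyloTree(adj, labels)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._adj, self._labels)

    def _internal_nodes(self) -> List[int]:
        return [u for u in self._adj if u not in self._labels]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloTree({write_newick(self)!r})"


# -- Newick I/O ----------------------------------------------------------------

_LABEL_STOP = set("(),:;")


class _Parser:
    """Recursive-descent Newick reader.

    Dialect: labels are taken verbatim (no quoting, no underscore
    interpretation); internal-node labels and support values are parsed and
    discarded; branch lengths after ``:`` are kept.
    """

    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> NewickError:
        return NewickError(msg, self.pos)

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def read_label(self) -> str:
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] not in _LABEL_STOP:
            self.pos += 1
        return self.text[start : self.pos].strip()

    def read_length(self) -> Optional[float]:
        if self.peek() != ":":
            return None
        self.pos += 1
        self.skip_ws()
        start = self.pos
        while self.pos < len(self.text) and (
            self.text[self.pos] in "+-.eE" or self.text[self.pos].isdigit()
        ):
            self.pos += 1
        token = self.text[start : self.pos]
        try:
            return float(token)
        except ValueError:
            self.pos = start
            raise self.error(f"invalid branch length {token!r}")

    def parse(self):
        self.skip_ws()
        node = self.subtree()
        self.skip_ws()
        if self.peek() != ";":
            raise self.error("expected ';' at end of tree")
        self.pos += 1
        self.skip_ws()
        if self.pos != len(self.text):
            raise self.error("unexpected trailing characters after ';'")
        return node

    def subtree(self):
        """Returns (children, label, length) with children = [] for leaves."""
        self.skip_ws()
        if self.peek() == "(":
            self.pos += 1
            children = [self.subtree()]
            self.skip_ws()
            while self.peek() == ",":
                self.pos += 1
                children.append(self.subtree())
                self.skip_ws()
            if self.peek() != ")":
                raise self.error("expected ')' or ','")
            self.pos += 1
            label = self.read_label()  # internal label / support: ignored
            length = self.read_length()
            return (children, label, length)
        label = self.read_label()
        if not label:
            raise self.error("expected a leaf label")
        length = self.read_length()
        return ([], label, length)


def parse_newick(text: str) -> PhyloTree:
    """Parse one Newick expression into an unrooted :class:`PhyloTree`.

    A bifurcating "root" is treated as a degree-2 node and suppressed, so
    rooted and unrooted writings of the same topology compare equal.
    """
    root = _Parser(text).parse()
    adj: Dict[int, Dict[int, Optional[float]]] = {}
    labels: Dict[int, str] = {}
    counter = [0]

    def build(node) -> int:
        children, label, _length = node
        uid = counter[0]
        counter[0] += 1
        adj[uid] = {}
        if not children:
            labels[uid] = label
        for child in children:
            cid = build(child)
            adj[uid][cid] = child[2]
            adj[cid][uid] = child[2]
        return uid

    build(root)
    return PhyloTree(adj, labels)


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree; re-parsing yields an RF-identical topology."""
    labels = tree._labels
    adj = tree._adj
    if tree.n_leaves == 1:
        return f"{next(iter(labels.values()))};"
    if tree.n_leaves == 2:
        (u, v, l) = next(tree.edges())
        a, b = labels[u], labels[v]
        if l is None:
            return f"({a},{b});"
        return f"({a}:0.0,{b}:{l:g});"
    internal = tree._internal_nodes()
    root = internal[0]

    def render(u: int, parent: int) -> str:
        if u in labels:
            return labels[u]
        parts = [
            render(v, u) + ("" if adj[u][v] is None else f":{adj[u][v]:g}")
            for v in adj[u]
            if v != parent
        ]
        return "(" + ",".join(parts) + ")"

    parts = [
        render(v, root) + ("" if adj[root][v] is None else f":{adj[root][v]:g}")
        for v in adj[root]
    ]
    return "(" + ",".join(parts) + ");"


def read_newick_file(path) -> List[PhyloTree]:
    """Read trees from a file, one Newick expression per non-empty line."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


# -- functional wrappers and distances ----------------------------------------


def bipartitions(tree: PhyloTree) -> frozenset:
    return tree.bipartitions()


def restrict_to_leaves(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    return tree.restrict(keep)


def _check_same_leaves(t1: PhyloTree, t2: PhyloTree) -> None:
    if t1.leaves != t2.leaves:
        only1 = sorted(t1.leaves - t2.leaves)
        only2 = sorted(t2.leaves - t1.leaves)
        raise TreeValidationError(
            f"leaf sets differ (first only: {only1}, second only: {only2}); "
            "restrict to the shared leaves first"
        )


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Splits of ``t1`` with no matching split in ``t2``.

    Equals the halved symmetric RF difference when both trees are binary
    (both then carry ``n - 3`` splits), where it is symmetric and at most
    ``n - 3``.
    """
    _check_same_leaves(t1, t2)
    return len(t1.bipartitions() - t2.bipartitions())


def rf_to_reference(tree: PhyloTree, ref: PhyloTree) -> int:
    """Splits of the (possibly multifurcating) reference missing from ``tree``.

    A polytomy in the reference asserts no resolution, so extra resolution in
    ``tree`` is never penalized; only the splits the reference does resolve
    can be missed.
    """
    _check_same_leaves(tree, ref)
    return len(ref.bipartitions() - tree.bipartitions())


def max_rf(tree: PhyloTree, ref: PhyloTree) -> int:
    """Largest possible :func:`rf_to_reference` value for this reference.

    ``n - 3`` for a binary reference; the reference's internal-edge count
    (strictly below ``n - 3``) when it carries polytomies.
    """
    _check_same_leaves(tree, ref)
    if tree.n_leaves < 4:
        raise TreeValidationError("max_rf requires at least 4 leaves")
    return len(ref.bipartitions())


def relative_rf(tree: PhyloTree, ref: PhyloTree) -> Optional[float]:
    """``rf_to_reference / max_rf`` in [0, 1]; ``None`` for a star reference."""
    m = max_rf(tree, ref)
    if m == 0:
        return None
    return rf_to_reference(tree, ref) / m


def zero_one_distance(tree: PhyloTree, ref: PhyloTree) -> int:
    """0 iff ``tree`` is consistent with every split of the reference."""
    return 0 if rf_to_reference(tree, ref) == 0 else 1
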