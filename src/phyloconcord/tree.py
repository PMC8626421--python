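"""Phylogenetic tree data model, newick I/O, splits and induced quartets.

Trees are rooted containers but all split/quartet logic treats them as
unrooted.  Branch support values are normalised to the [0, 100] scale on
read: values in (0, 1] (posterior probabilities) are multiplied by 100 so
that percentage thresholds apply uniformly.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "UNIT_NONE",
    "UNIT_COALESCENT",
    "UNIT_MUTATION",
    "UNRESOLVED",
    "MISSING",
    "NewickError",
    "Node",
    "PhyloTree",
    "Split",
    "GeneTreeSet",
    "parse_newick",
    "write_newick",
    "bipartitions",
    "internal_edge_lengths",
    "induced_quartet_topology",
    "topological_distance_matrix",
    "read_newick_file",
    "write_newick_file",
]

UNIT_NONE = "none"
UNIT_COALESCENT = "coalescent"
UNIT_MUTATION = "mutation"

#: sentinel returned by :func:`induced_quartet_topology`
UNRESOLVED = "unresolved"
MISSING = "missing"


class NewickError(ValueError):
    """Raised on malformed newick input; the message names the offending token."""


class Node:
    """A tree node.  Tips carry a label; internal nodes may carry a support value."""

    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(
        self,
        label: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ) -> None:
        self.label = label
        self.length = length
        self.support = support
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        # iterative to be safe on deep caterpillars
        stack: list[tuple["Node", bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for ch in reversed(node.children):
                    stack.append((ch, False))

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["Node"]:
        return [n for n in self.postorder() if n.is_leaf]

    def copy(self) -> "Node":
        dup = Node(self.label, self.length, self.support)
        for ch in self.children:
            dup.add_child(ch.copy())
        return dup


class PhyloTree:
    """Rooted tree with tip labels, optional branch lengths and supports.

    Parameters
    ----------
    root:
        Root :class:`Node` of the tree.
    unit_tag:
        One of ``"coalescent"``, ``"mutation"`` or ``"none"``, recording the
        unit system of the branch lengths.
    """

    def __init__(self, root: Node, unit_tag: str = UNIT_NONE) -> None:
        if unit_tag not in (UNIT_NONE, UNIT_COALESCENT, UNIT_MUTATION):
            raise ValueError(f"unknown unit_tag {unit_tag!r}")
        self.root = root
        self.unit_tag = unit_tag
        self._validate()

    # -- validation ------------------------------------------------------
    def _validate(self) -> None:
        labels: list[str] = []
        for node in self.root.postorder():
            if node.is_leaf:
                if not node.label:
                    raise ValueError("tip with empty label")
                labels.append(node.label)
            if node.length is not None:
                if not math.isfinite(node.length):
                    raise ValueError(f"non-finite branch length {node.length!r}")
                if node.length < 0:
                    raise ValueError(f"negative branch length {node.length!r}")
            if node.support is not None and not (0 <= node.support <= 100):
                raise ValueError(f"support {node.support!r} outside [0, 100]")
        if not labels:
            raise ValueError("tree has no tips")
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip label(s): {', '.join(dup)}")
        self._taxa = tuple(sorted(labels))

    # -- basic queries ---------------------------------------------------
    @property
    def taxa(self) -> tuple[str, ...]:
        """Sorted tuple of tip labels."""
        return self._taxa

    @property
    def n_tips(self) -> int:
        return len(self._taxa)

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def is_binary(self) -> bool:
        """True if the root has exactly two children and all other internals two."""
        for node in self.root.postorder():
            if not node.is_leaf and len(node.children) != 2:
                return False
        return True

    def copy(self, unit_tag: Optional[str] = None) -> "PhyloTree":
        return PhyloTree(self.root.copy(), unit_tag or self.unit_tag)

    def newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PhyloTree({self.newick()!r}, unit_tag={self.unit_tag!r})"


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


class Split:
    """An unordered bipartition of a taxon set into two non-empty blocks."""

    __slots__ = ("block1", "block2", "_hash")

    def __init__(self, block1: Iterable[str], block2: Iterable[str]) -> None:
        b1 = frozenset(block1)
        b2 = frozenset(block2)
        if not b1 or not b2:
            raise ValueError("split blocks must be non-empty")
        if b1 & b2:
            raise ValueError("split blocks must be disjoint")
        # canonical orientation: block containing the smallest taxon first
        if min(b2) < min(b1):
            b1, b2 = b2, b1
        self.block1 = b1
        self.block2 = b2
        self._hash = hash((b1, b2))

    @property
    def taxa(self) -> frozenset[str]:
        return self.block1 | self.block2

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Split):
            return NotImplemented
        return self.block1 == other.block1 and self.block2 == other.block2

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        return "{%s | %s}" % (
            ",".join(sorted(self.block1)),
            ",".join(sorted(self.block2)),
        )

    def sort_key(self) -> tuple:
        return (tuple(sorted(self.block1)), tuple(sorted(self.block2)))

    def restrict(self, taxa: Iterable[str]) -> Optional["Split"]:
        """Restrict to a taxon subset; None if a block becomes empty."""
        tset = frozenset(taxa)
        b1 = self.block1 & tset
        b2 = self.block2 & tset
        if not b1 or not b2:
            return None
        return Split(b1, b2)

    def is_trivial(self) -> bool:
        """A split with a singleton block carries no topological information."""
        return len(self.block1) < 2 or len(self.block2) < 2

    def conflicts_with(self, other: "Split") -> bool:
        """True if the two splits (on the same taxon set) are incompatible.

        Two splits are compatible iff at least one of the four pairwise
        block intersections is empty.
        """
        return bool(
            self.block1 & other.block1
            and self.block1 & other.block2
            and self.block2 & other.block1
            and self.block2 & other.block2
        )


# ---------------------------------------------------------------------------
# newick parsing / writing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*([(),;:]|[^\s(),;:]+)")


def _tokenize(text: str) -> list[str]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


def _normalise_support(value: float, token: str) -> float:
    if value < 0 or value > 100:
        raise NewickError(f"support value {token!r} outside [0, 100]")
    if 0 < value <= 1:
        return value * 100.0
    return value


def parse_newick(text: str, unit_tag: str = UNIT_NONE) -> PhyloTree:
    """Parse a single newick statement into a :class:`PhyloTree`.

    Numeric internal-node labels are interpreted as branch supports;
    supports in (0, 1] are rescaled to percent.  Non-numeric internal
    labels are stored on the node but otherwise unused.

    Raises
    ------
    NewickError
        On unbalanced parentheses, duplicate tip labels, negative branch
        lengths or other malformed input; the message names the offending
        token.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise NewickError("empty newick string")
    root = Node()
    cur = root
    depth = 0
    saw_semicolon = False
    i = 0
    n_tokens = len(tokens)
    while i < n_tokens:
        tok = tokens[i]
        if saw_semicolon:
            raise NewickError(f"trailing content after ';': {tok!r}")
        if tok == "(":
            depth += 1
            cur = cur.add_child(Node())
        elif tok == ",":
            if cur.parent is None:
                raise NewickError("unexpected ',' outside parentheses")
            cur = cur.parent.add_child(Node())
        elif tok == ")":
            depth -= 1
            if depth < 0 or cur.parent is None:
                raise NewickError("unbalanced parentheses: unexpected ')'")
            cur = cur.parent
        elif tok == ":":
            i += 1
            if i >= n_tokens:
                raise NewickError("branch length expected after ':'")
            num = tokens[i]
            try:
                length = float(num)
            except ValueError:
                raise NewickError(f"invalid branch length {num!r}") from None
            if not math.isfinite(length):
                raise NewickError(f"non-finite branch length {num!r}")
            if length < 0:
                raise NewickError(f"negative branch length {num!r}")
            cur.length = length
        elif tok == ";":
            saw_semicolon = True
        else:  # a label
            if cur.children:  # internal node label -> support if numeric
                try:
                    value = float(tok)
                except ValueError:
                    cur.label = tok
                else:
                    cur.support = _normalise_support(value, tok)
            else:
                if cur.label is not None:
                    raise NewickError(f"unexpected token {tok!r} after label")
                cur.label = tok
        i += 1
    if depth != 0:
        raise NewickError("unbalanced parentheses: missing ')'")
    if not saw_semicolon:
        raise NewickError("newick statement must end with ';'")
    # unwrap the synthetic outer node: its single child is the actual root
    if len(root.children) == 1 and root.label is None and root.length is None:
        actual = root.children[0]
        actual.parent = None
    else:
        actual = root
    try:
        return PhyloTree(actual, unit_tag=unit_tag)
    except ValueError as exc:
        raise NewickError(str(exc)) from None


def _format_number(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return format(x, ".10g")


def _node_newick(node: Node) -> str:
    if node.is_leaf:
        s = node.label or ""
    else:
        s = "(" + ",".join(_node_newick(ch) for ch in node.children) + ")"
        if node.support is not None:
            s += _format_number(node.support)
        elif node.label:
            s += node.label
    if node.length is not None:
        s += ":" + _format_number(node.length)
    return s


def write_newick(tree: PhyloTree) -> str:
    """Serialise a tree to newick; inverse of :func:`parse_newick`."""
    return _node_newick(tree.root) + ";"


# ---------------------------------------------------------------------------
# splits / quartets
# ---------------------------------------------------------------------------


def _clades(tree: PhyloTree) -> dict[int, frozenset[str]]:
    """Map id(node) -> frozenset of descendant tip labels."""
    clades: dict[int, frozenset[str]] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            clades[id(node)] = frozenset((node.label,))
        else:
            acc: set[str] = set()
            for ch in node.children:
                acc |= clades[id(ch)]
            clades[id(node)] = frozenset(acc)
    return clades


def bipartitions(tree: PhyloTree) -> set[Split]:
    """Non-trivial splits of the (unrooted) tree, one per internal edge.

    Returns the empty set for trees with fewer than four tips.
    """
    taxa = frozenset(tree.taxa)
    if len(taxa) < 4:
        return set()
    clades = _clades(tree)
    splits: set[Split] = set()
    for node in tree.root.postorder():
        if node.is_leaf or node.parent is None:
            continue
        clade = clades[id(node)]
        rest = taxa - clade
        if len(clade) >= 2 and len(rest) >= 2:
            splits.add(Split(clade, rest))
    return splits


def internal_edge_lengths(tree: PhyloTree) -> dict[Split, float]:
    """Branch length per non-trivial split (unrooted edges).

    For a rooted binary tree the two edges incident to the root belong to
    a single unrooted edge; their lengths are summed.  Edges without a
    length are skipped.
    """
    taxa = frozenset(tree.taxa)
    clades = _clades(tree)
    lengths: dict[Split, float] = {}
    for node in tree.root.postorder():
        if node.is_leaf or node.parent is None or node.length is None:
            continue
        clade = clades[id(node)]
        rest = taxa - clade
        if len(clade) < 2 or len(rest) < 2:
            continue
        split = Split(clade, rest)
        lengths[split] = lengths.get(split, 0.0) + node.length
    return lengths


def topological_distance_matrix(
    tree: PhyloTree, taxon_index: dict[str, int]
) -> np.ndarray:
    """Pairwise tip distances in edge counts, as a dense matrix.

    Entries for taxa absent from the tree are NaN.  The matrix supports
    four-point quartet resolution: a quartet ``{a,b,c,d}`` is resolved as
    ``ab|cd`` iff ``d(a,b)+d(c,d)`` is strictly smaller than both
    alternative pairings.
    """
    n = len(taxon_index)
    D = np.full((n, n), np.nan)
    # depths of leaves below each node, merged bottom-up
    below: dict[int, dict[int, int]] = {}
    for node in tree.root.postorder():
        if node.is_leaf:
            idx = taxon_index.get(node.label)
            below[id(node)] = {} if idx is None else {idx: 0}
            continue
        merged: dict[int, int] = {}
        for ch in node.children:
            sub = below.pop(id(ch))
            for i, di in sub.items():
                dpi = di + 1
                for j, dj in merged.items():
                    d = dpi + dj
                    D[i, j] = d
                    D[j, i] = d
            for i, di in sub.items():
                merged[i] = di + 1
        below[id(node)] = merged
    present = set(tree.taxa)
    for label, i in taxon_index.items():
        if label in present:
            D[i, i] = 0.0
    return D


def induced_quartet_topology(tree: PhyloTree, quartet: Sequence[str]):
    """Unrooted resolution of a four-taxon subset induced by the tree.

    Returns a :class:`Split` pairing the sister taxa (e.g. ``{c,d | a,e}``),
    or the string sentinels :data:`UNRESOLVED` (star restriction) or
    :data:`MISSING` (some tip absent).  Invariant under re-rooting.
    """
    q = list(quartet)
    if len(q) != 4 or len(set(q)) != 4:
        raise ValueError("quartet must contain 4 distinct taxon labels")
    taxa = set(tree.taxa)
    if any(t not in taxa for t in q):
        return MISSING
    index = {t: i for i, t in enumerate(q)}
    D = topological_distance_matrix(tree, index)
    a, b, c, d = 0, 1, 2, 3
    s = (
        D[a, b] + D[c, d],
        D[a, c] + D[b, d],
        D[a, d] + D[b, c],
    )
    smin = min(s)
    winners = [i for i, v in enumerate(s) if v == smin]
    if len(winners) != 1:
        return UNRESOLVED
    pairings = ((a, b, c, d), (a, c, b, d), (a, d, b, c))
    w = pairings[winners[0]]
    return Split((q[w[0]], q[w[1]]), (q[w[2]], q[w[3]]))


# ---------------------------------------------------------------------------
# collections and file I/O
# ---------------------------------------------------------------------------


@dataclass
class GeneTreeSet:
    """An ordered collection of trees over (subsets of) a common taxon set."""

    trees: list[PhyloTree]
    taxa: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValueError("GeneTreeSet must contain at least one tree")
        if not self.taxa:
            union: set[str] = set()
            for t in self.trees:
                union |= set(t.taxa)
            self.taxa = tuple(sorted(union))
        else:
            self.taxa = tuple(sorted(self.taxa))
            ref = set(self.taxa)
            for t in self.trees:
                extra = set(t.taxa) - ref
                if extra:
                    raise ValueError(
                        f"tree tips {sorted(extra)} not in reference taxon set"
                    )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[PhyloTree]:
        return iter(self.trees)

    def __getitem__(self, i: int) -> PhyloTree:
        return self.trees[i]


def read_newick_file(path, unit_tag: str = UNIT_NONE) -> GeneTreeSet:
    """Read a multi-newick file: one tree per line, '#' lines ignored."""
    trees = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                trees.append(parse_newick(line, unit_tag=unit_tag))
            except NewickError as exc:
                raise NewickError(f"{path}:{lineno}: {exc}") from None
    if not trees:
        raise ValueError(f"no trees found in {path}")
    return GeneTreeSet(trees)


def write_newick_file(trees: Iterable[PhyloTree], path) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(write_newick(tree) + "\n")
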