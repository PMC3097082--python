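"""Rooted phylogenetic trees: newick I/O, splits, consensus, pruning.

Trees are rooted, carry optional non-negative branch lengths, and optional
clade support values (posterior probabilities in [0, 1]) on internal nodes,
read from and written to newick internal-node labels -- the dominant
consensus-tree convention.  Conflict analysis downstream works on unrooted
splits, so rooting differences between two trees cannot create spurious
conflicts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy

from .errors import NewickParseError, ValidationError

__all__ = [
    "Node",
    "Tree",
    "Split",
    "TreeSample",
    "parse_newick",
    "write_newick",
    "extract_splits",
    "majority_consensus",
    "prune",
    "resolve_polytomies",
    "is_monophyletic",
]


class Node:
    """A tree node.  Leaves have a ``name``; internals may have ``support``."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name=None, length=None, support=None, children=None):
        self.name = name
        self.length = length
        self.support = support
        self.children = []
        self.parent = None
        for child in children or ():
            self.add_child(child)

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self):
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaf_names(self) -> frozenset:
        return frozenset(n.name for n in self.postorder() if n.is_leaf)

    def copy(self) -> "Node":
        clone = Node(self.name, self.length, self.support)
        for child in self.children:
            clone.add_child(child.copy())
        return clone


@dataclass
class Tree:
    """A rooted tree with unique leaf names."""

    root: Node

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        names = [n.name for n in self.root.postorder() if n.is_leaf]
        if len(names) != len(set(names)):
            dupes = sorted({x for x in names if names.count(x) > 1})
            raise ValidationError(f"duplicate leaf names: {dupes}")
        if any(not n for n in names):
            raise ValidationError("empty leaf name")
        for node in self.root.postorder():
            if node.length is not None and node.length < 0:
                raise ValidationError(f"negative branch length {node.length}")
            if node.is_leaf and node.support is not None:
                raise ValidationError("support on a leaf node")
            if node.support is not None and not (0.0 <= node.support <= 1.0):
                raise ValidationError(f"support {node.support} outside [0, 1]")

    @property
    def leaves(self) -> frozenset:
        return self.root.leaf_names()

    def copy(self) -> "Tree":
        return Tree(self.root.copy())

    def postorder(self):
        return self.root.postorder()

    def preorder(self):
        return self.root.preorder()

    def clades(self, include_leaves: bool = True):
        """Yield (node, frozenset of descendant leaf names) for every node."""
        sets: dict[int, frozenset] = {}
        for node in self.root.postorder():
            if node.is_leaf:
                s = frozenset([node.name])
            else:
                s = frozenset().union(*(sets[id(c)] for c in node.children))
            sets[id(node)] = s
            if include_leaves or not node.is_leaf:
                yield node, s

    def signature(self):
        """Multiset of (clade, length, support); equal iff trees identical."""
        return sorted(
            (tuple(sorted(s)), node.length, node.support)
            for node, s in self.clades()
        )

    def __str__(self) -> str:
        return write_newick(self)


@dataclass(frozen=True)
class Split:
    """An unrooted bipartition of a taxon universe with optional support.

    ``side_a`` is canonical: the side containing the lexicographically
    smallest taxon, so a split and its complement compare equal.
    ``clade_side`` records which side was the clade (descendant set) in the
    source rooted tree; it does not take part in equality.
    """

    side_a: frozenset
    universe: frozenset
    support: float | None = field(default=None, compare=False)
    clade_side: frozenset | None = field(default=None, compare=False)

    @staticmethod
    def from_clade(clade, universe, support=None) -> "Split":
        clade = frozenset(clade)
        universe = frozenset(universe)
        if not clade or clade >= universe:
            raise ValidationError("split side must be a proper nonempty subset")
        side = clade if min(universe) in clade else universe - clade
        return Split(side, universe, support=support, clade_side=clade)

    @property
    def side_b(self) -> frozenset:
        return self.universe - self.side_a

    @property
    def size(self) -> int:
        """Size of the smaller side."""
        return min(len(self.side_a), len(self.side_b))

    def is_trivial(self) -> bool:
        return self.size < 2

    def restrict(self, taxa) -> "Split | None":
        """The induced split on ``taxa``; None if it collapses to trivial."""
        taxa = frozenset(taxa)
        a = self.side_a & taxa
        b = self.side_b & taxa
        if len(a) < 2 or len(b) < 2:
            return None
        clade = (self.clade_side & taxa) if self.clade_side is not None else a
        return Split.from_clade(clade if clade else a, taxa, support=self.support)

    def sort_key(self):
        return (self.size, tuple(sorted(self.side_a)), tuple(sorted(self.universe)))


@dataclass
class TreeSample:
    """An ordered, non-empty list of trees on one leaf set."""

    trees: list

    def __post_init__(self):
        if not self.trees:
            raise ValidationError("empty tree sample")
        ref = self.trees[0].leaves
        for i, t in enumerate(self.trees):
            if t.leaves != ref:
                raise ValidationError(
                    f"tree {i} has a different leaf set from tree 0"
                )

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


# ---------------------------------------------------------------------------
# newick I/O


def parse_newick(text: str) -> Tree:
    """Parse a single newick statement.

    Numeric internal-node labels are read as support values in [0, 1].
    Bracketed comments and other exotic annotations are rejected.
    """
    if "[" in text or "]" in text:
        raise NewickParseError(
            "bracketed comments/annotations are not supported", text.find("[")
        )
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError("newick statement must end with ';'", len(text) - 1)
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        offset = getattr(exc, "col_num", None)
        offset = offset - 1 if isinstance(offset, int) and offset > 0 else None
        raise NewickParseError(str(exc), offset) from None

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else dnode.label
            if name is None or name == "":
                raise NewickParseError("unnamed leaf")
            return Node(name=name, length=dnode.edge.length)
        support = None
        if dnode.label is not None:
            try:
                support = float(dnode.label)
            except ValueError:
                raise NewickParseError(
                    f"non-numeric internal node label {dnode.label!r}"
                ) from None
            if not (0.0 <= support <= 1.0):
                raise NewickParseError(
                    f"internal label {support} is not a support in [0, 1]"
                )
        node = Node(length=dnode.edge.length, support=support)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    return Tree(convert(dtree.seed_node))


def _fmt(x: float) -> str:
    s = repr(float(x))
    return s[:-2] if s.endswith(".0") else s


def _write_node(node: Node, out: io.StringIO) -> None:
    if node.is_leaf:
        out.write(node.name)
    else:
        out.write("(")
        for i, child in enumerate(node.children):
            if i:
                out.write(",")
            _write_node(child, out)
        out.write(")")
        if node.support is not None:
            out.write(_fmt(node.support))
    if node.length is not None:
        out.write(f":{_fmt(node.length)}")


def write_newick(tree: Tree) -> str:
    """Serialize deterministically (children in stored order)."""
    out = io.StringIO()
    _write_node(tree.root, out)
    out.write(";")
    return out.getvalue()


def read_trees(path) -> list:
    """Read one tree per newick statement from a file."""
    with open(path) as fh:
        text = fh.read()
    return [
        parse_newick(chunk + ";")
        for chunk in text.split(";")
        if chunk.strip()
    ]


def write_trees(trees, path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(write_newick(t) + "\n")


# ---------------------------------------------------------------------------
# splits and consensus


def extract_splits(tree: Tree, min_support: float | None = 0.0) -> set:
    """Non-trivial splits of ``tree``, one per internal edge.

    With a numeric ``min_support``, only edges whose support is present and
    >= min_support are returned (an unlabeled edge is never "supported").
    ``min_support=None`` returns every internal edge regardless of labels.
    """
    universe = tree.leaves
    if len(universe) < 3:
        return set()
    found: dict[Split, Split] = {}
    for node, clade in tree.clades(include_leaves=False):
        if node is tree.root:
            continue
        if len(clade) < 2 or len(universe - clade) < 2:
            continue
        if min_support is not None and (
            node.support is None or node.support < min_support
        ):
            continue
        split = Split.from_clade(clade, universe, support=node.support)
        prev = found.get(split)
        if prev is None or (prev.support or -1) < (split.support or -1):
            found[split] = split
    return set(found.values())


def majority_consensus(sample: TreeSample, cutoff: float = 0.5) -> Tree:
    """Majority-rule consensus of a tree sample.

    Contains exactly the clades whose frequency is strictly greater than
    ``cutoff`` (in [0.5, 1]), each annotated with support = frequency.
    """
    if not 0.5 <= cutoff <= 1.0:
        raise ValidationError(f"cutoff {cutoff} outside [0.5, 1]")
    universe = sample.trees[0].leaves
    counts: dict[frozenset, int] = {}
    for t in sample:
        for _node, clade in t.clades(include_leaves=False):
            if 1 < len(clade) < len(universe):
                counts[clade] = counts.get(clade, 0) + 1
    n = len(sample)
    # strict "> cutoff" (avoids ties at exactly 0.5), except that unanimous
    # clades are always retained so cutoff=1.0 means strict consensus
    kept = sorted(
        (c for c, k in counts.items() if k / n > cutoff or k == n),
        key=lambda c: (-len(c), sorted(c)),
    )
    root = Node()
    node_sets: dict[int, frozenset] = {id(root): universe}
    for name in sorted(universe):
        leaf = Node(name=name)
        root.add_child(leaf)
        node_sets[id(leaf)] = frozenset([name])

    for clade in kept:
        # walk to the smallest current node containing the clade
        host = root
        descended = True
        while descended:
            descended = False
            for child in host.children:
                if clade <= node_sets[id(child)]:
                    host, descended = child, True
                    break
        if node_sets[id(host)] == clade:  # already present (e.g. root)
            continue
        new = Node(support=counts[clade] / n)
        movers = [c for c in host.children if node_sets[id(c)] <= clade]
        host.children = [c for c in host.children if c not in movers]
        for m in movers:
            new.add_child(m)
        host.add_child(new)
        node_sets[id(new)] = clade
    return Tree(root)


# ---------------------------------------------------------------------------
# topology editing


def prune(tree: Tree, keep) -> Tree:
    """Restrict to leaf set ``keep``, suppressing unifurcations.

    Suppressed paths sum their branch lengths and retain the support of the
    edge closest to the leaves.
    """
    keep = frozenset(keep)
    missing = sorted(keep - tree.leaves)
    if missing:
        raise ValidationError(f"taxa not in tree: {missing}")
    if len(keep) < 2:
        raise ValidationError("need at least 2 taxa to keep")

    def rebuild(node: Node) -> Node | None:
        if node.is_leaf:
            if node.name in keep:
                return Node(node.name, node.length)
            return None
        kids = [k for k in (rebuild(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            only = kids[0]
            if node.length is not None or only.length is not None:
                only.length = (node.length or 0.0) + (only.length or 0.0)
            return only  # support of the child edge is retained
        new = Node(length=node.length, support=node.support)
        for k in kids:
            new.add_child(k)
        return new

    root = rebuild(tree.root)
    while not root.is_leaf and len(root.children) == 1:
        root = root.children[0]
    root.parent = None
    return Tree(root)


def resolve_polytomies(tree: Tree) -> Tree:
    """Arbitrarily resolve multifurcations with zero-length branches.

    Children are combined left-to-right in stored order, so the result is
    deterministic; inserted branches have length 0 and no support, which
    leaves Mk-model likelihoods unchanged.
    """
    out = tree.copy()
    for node in list(out.postorder()):
        while len(node.children) > 2:
            first, second = node.children[0], node.children[1]
            joined = Node(length=0.0, children=[first, second])
            node.children = [joined] + node.children[2:]
            joined.parent = node
    return out


def is_monophyletic(tree: Tree, taxa) -> bool:
    """True iff some node's descendant leaf set equals ``taxa`` exactly."""
    taxa = frozenset(taxa)
    unknown = sorted(taxa - tree.leaves)
    if unknown:
        raise ValidationError(f"unknown taxa: {unknown}")
    return any(clade == taxa for _n, clade in tree.clades())
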