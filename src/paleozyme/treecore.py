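"""Shared tree and alignment data model.

Every other module in :mod:`paleozyme` consumes the :class:`Tree` and
:class:`Alignment` containers defined here.  Trees are rooted, node-labelled
structures carrying branch lengths (expected substitutions per site, or time,
depending on context), internal-node supports (normalised to a 0-100 scale)
and optional node ages in Ma.  Polytomies are allowed in storage; operations
that require binary trees say so explicitly.

Newick parsing is delegated to :mod:`dendropy`; writing is done by a small
canonical serialiser (children ordered by smallest descendant leaf label) so
that structurally identical trees always produce identical strings.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import dendropy


class TreeError(ValueError):
    """Structurally invalid tree or invalid tree operation."""


class NewickParseError(TreeError):
    """Malformed Newick input; carries the character offset when known."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (near character offset {offset})"
        super().__init__(message)


class Node:
    """A single tree node.

    ``length`` is the length of the branch *entering* the node (``None`` for
    the root), ``support`` annotates the same branch (stored on the child, on
    a 0-100 scale) and ``age`` is the node's height above the leaves in Ma
    when the tree is dated.
    """

    __slots__ = ("id", "label", "parent", "children", "length", "support", "age")

    def __init__(
        self,
        label: str | None = None,
        length: float | None = None,
        support: float | None = None,
        age: float | None = None,
    ):
        self.id: int = -1
        self.label = label
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.length = length
        self.support = support
        self.age = age

    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    def remove_child(self, node: "Node") -> None:
        self.children.remove(node)
        node.parent = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf() else f"internal({len(self.children)})"
        return f"<Node {self.id} {self.label!r} {kind}>"


class Tree:
    """Rooted tree with unique leaf labels.

    Node ids are postorder indices, reassigned by :meth:`reindex` after any
    structural mutation.
    """

    def __init__(self, root: Node):
        self.root = root
        self._nodes: list[Node] = []
        self.reindex()

    # -- structure -----------------------------------------------------------

    def reindex(self) -> "Tree":
        self._nodes = list(self._postorder(self.root))
        for i, node in enumerate(self._nodes):
            node.id = i
        labels = [n.label for n in self._nodes if n.is_leaf()]
        if any(lab is None for lab in labels):
            raise TreeError("every leaf must carry a label")
        if len(set(labels)) != len(labels):
            seen, dup = set(), set()
            for lab in labels:
                (dup if lab in seen else seen).add(lab)
            raise TreeError(f"duplicate leaf labels: {sorted(dup)}")
        for n in self._nodes:
            if n.length is not None and n.length < 0:
                raise TreeError(f"negative branch length on node {n.label or n.id}")
        return self

    @staticmethod
    def _postorder(root: Node) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def postorder(self) -> Iterator[Node]:
        return iter(self._nodes)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def nodes(self) -> list[Node]:
        return list(self._nodes)

    def node(self, node_id: int) -> Node:
        return self._nodes[node_id]

    def leaves(self) -> list[Node]:
        return [n for n in self._nodes if n.is_leaf()]

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        out = [n for n in self._nodes if not n.is_leaf()]
        if not include_root:
            out = [n for n in out if n is not self.root]
        return out

    @property
    def leaf_labels(self) -> frozenset[str]:
        return frozenset(n.label for n in self.leaves())  # type: ignore[misc]

    @property
    def taxa(self) -> list[str]:
        return sorted(self.leaf_labels)

    def find_leaf(self, label: str) -> Node:
        for n in self.leaves():
            if n.label == label:
                return n
        raise TreeError(f"unknown taxon: {label!r}")

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self._nodes)

    def n_leaves(self) -> int:
        return len(self.leaves())

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length, node.support, node.age)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root))

    # -- queries -------------------------------------------------------------

    def leaf_sets(self) -> dict[int, frozenset[str]]:
        """Leaf-label set below each node, keyed by node id."""
        out: dict[int, frozenset[str]] = {}
        for node in self._nodes:
            if node.is_leaf():
                out[node.id] = frozenset([node.label])  # type: ignore[list-item]
            else:
                acc: set[str] = set()
                for c in node.children:
                    acc |= out[c.id]
                out[node.id] = frozenset(acc)
        return out

    def mrca(self, leaves: Iterable[str]) -> Node:
        """Lowest node whose descendant leaves contain all of ``leaves``."""
        wanted = set(leaves)
        if not wanted:
            raise TreeError("mrca of an empty taxon set is undefined")
        unknown = wanted - self.leaf_labels
        if unknown:
            raise TreeError(f"unknown taxon: {sorted(unknown)[0]!r}")
        sets = self.leaf_sets()
        for node in self._nodes:  # postorder: first covering node is lowest
            if wanted <= sets[node.id]:
                return node
        raise AssertionError("unreachable: root covers all leaves")

    def clade_set(self) -> frozenset[frozenset[str]]:
        """One bipartition per internal edge (edges whose child is an
        internal non-root node), as canonical splits.

        A split is represented by the side containing the alphabetically
        smallest taxon, so the two child edges of the root collapse to a
        single entry (the unrooted view); the root edge itself is excluded.
        """
        universe = self.leaf_labels
        if not universe:
            return frozenset()
        anchor = min(universe)
        sets = self.leaf_sets()
        splits: set[frozenset[str]] = set()
        for node in self._nodes:
            if node is self.root or node.is_leaf():
                continue
            side = sets[node.id]
            if anchor not in side:
                side = universe - side
            if 0 < len(side) < len(universe):
                splits.add(side)
        return frozenset(splits)

    # -- ages / lengths ------------------------------------------------------

    def compute_ages_from_lengths(self, rel_tol: float = 1e-6) -> "Tree":
        """Set node ages from branch lengths; requires an ultrametric tree."""
        depth = {self.root.id: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            if node.length is None:
                raise TreeError("branch lengths required to compute ages")
            depth[node.id] = depth[node.parent.id] + node.length
        total = max(depth[n.id] for n in self.leaves())
        tol = rel_tol * max(total, 1.0)
        for leaf in self.leaves():
            if abs(depth[leaf.id] - total) > tol:
                raise TreeError("tree is not ultrametric; cannot assign ages")
            leaf.age = 0.0
        for node in self._nodes:
            if not node.is_leaf():
                node.age = total - depth[node.id]
        return self

    def set_lengths_from_ages(self) -> "Tree":
        for node in self._nodes:
            if node is self.root:
                node.length = None
                continue
            if node.age is None or node.parent.age is None:
                raise TreeError("ages required on every node")
            length = node.parent.age - node.age
            if length < -1e-9:
                raise TreeError("age(parent) < age(child)")
            node.length = max(length, 0.0)
        return self

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        try:
            self.copy().compute_ages_from_lengths(rel_tol)
        except TreeError:
            return False
        return True

    # -- mutation ------------------------------------------------------------

    def prune_leaf(self, label: str) -> "Tree":
        """Remove a leaf, suppressing the resulting unary node (branch
        lengths are summed across the suppressed node)."""
        leaf = self.find_leaf(label)
        parent = leaf.parent
        if parent is None:
            raise TreeError("cannot prune the only node of a tree")
        parent.remove_child(leaf)
        if len(parent.children) == 1:
            child = parent.children[0]
            grand = parent.parent
            if grand is None:
                child.parent = None
                child.length = None
                self.root = child
            else:
                if child.length is not None and parent.length is not None:
                    child.length = child.length + parent.length
                grand.children[grand.children.index(parent)] = child
                child.parent = grand
        return self.reindex()

    def rerooted_on_edge(self, split: frozenset[str]) -> "Tree":
        """Return a copy re-rooted on the edge above the node whose leaf set
        equals ``split`` (or its complement).  The edge length is divided
        equally between the two new root children; the old degree-two root is
        suppressed."""
        work = self.copy()
        sets = work.leaf_sets()
        universe = work.leaf_labels
        target = None
        for node in work.postorder():
            if node is work.root:
                continue
            if sets[node.id] == split or sets[node.id] == universe - split:
                target = node
                break
        if target is None:
            raise TreeError("no edge induces the requested split")
        return _reroot_above(work, target)

    # -- serialisation -------------------------------------------------------

    def write_newick(self, include: Sequence[str] | str = "auto") -> str:
        return write_newick(self, include)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree n_leaves={self.n_leaves()}>"


def _reroot_above(tree: Tree, target: Node) -> Tree:
    """Re-root ``tree`` (consumed) on the edge above ``target``.

    The split edge's length is divided equally between the two new root
    children; a degree-two old root is suppressed (lengths summed)."""
    if target.parent is None:
        raise TreeError("cannot re-root above the root")
    parent = target.parent

    def invert(
        node: Node, came_from: Node, entry_length: float | None, entry_support
    ) -> Node | None:
        """Everything on the far side of the edge (node, came_from), rooted
        at ``node``, hanging below an edge of ``entry_length``."""
        rest = [c for c in node.children if c is not came_from]
        up = None
        if node.parent is not None:
            up = invert(node.parent, node, node.length, node.support)
        new = Node(label=None, length=entry_length, support=entry_support)
        for c in rest:
            new.add_child(c)
        if up is not None:
            new.add_child(up)
        if not new.children:
            return None  # old root contributed nothing beyond came_from
        if len(new.children) == 1:
            only = new.children[0]
            only.parent = None
            if only.length is None and entry_length is None:
                pass
            else:
                only.length = (only.length or 0.0) + (entry_length or 0.0)
            return only
        return new

    half = None if target.length is None else target.length / 2.0
    other = invert(parent, target, half, target.support)
    target.parent = None
    target.length = half
    if other is None:
        raise TreeError("re-rooting produced an empty far side")
    root = Node()
    root.add_child(target)
    root.add_child(other)
    return Tree(root)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into a :class:`Tree`.

    Numeric internal-node labels are interpreted as branch supports; the
    support scale (0-1 vs 0-100) is auto-detected and normalised to 0-100.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick input", offset=0)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        offset = getattr(exc, "col_num", None)
        if offset is None:
            pos = getattr(exc, "column", None)
            offset = pos if isinstance(pos, int) else None
        raise NewickParseError(str(exc), offset=offset) from exc

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = Node(label=label, length=dnode.edge.length)
        else:
            support = None
            label = dnode.label
            if label is not None:
                try:
                    support = float(label)
                    label = None
                except ValueError:
                    pass
            node = Node(label=label, length=dnode.edge.length, support=support)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    tree = Tree(root)
    _normalise_supports(tree)
    return tree


def _normalise_supports(tree: Tree) -> None:
    supports = [n.support for n in tree.postorder() if n.support is not None]
    if supports and max(supports) <= 1.0:
        for n in tree.postorder():
            if n.support is not None:
                n.support = n.support * 100.0


def _fmt(value: float) -> str:
    s = f"{value:.12g}"
    if "." not in s and "e" not in s and "E" not in s and "n" not in s:
        s += ".0"
    return s


def write_newick(tree: Tree, include: Sequence[str] | str = "auto") -> str:
    """Serialise a tree deterministically (children ordered by smallest
    descendant leaf label).

    ``include`` selects fields: a subset of ``("length", "support")``, or
    ``"auto"`` to serialise whatever is present.  Requesting a field absent
    from the whole tree is an error.
    """
    has_length = any(
        n.length is not None for n in tree.postorder() if n is not tree.root
    )
    has_support = any(n.support is not None for n in tree.postorder())
    if include == "auto":
        fields = set()
        if has_length:
            fields.add("length")
        if has_support:
            fields.add("support")
    else:
        fields = set(include)
        unknown = fields - {"length", "support"}
        if unknown:
            raise TreeError(f"unknown Newick field selection: {sorted(unknown)}")
        if "length" in fields and not has_length:
            raise TreeError("cannot serialise branch lengths: none present")
        if "support" in fields and not has_support:
            raise TreeError("cannot serialise supports: none present")

    min_leaf: dict[int, str] = {}
    for node in tree.postorder():
        if node.is_leaf():
            min_leaf[node.id] = node.label  # type: ignore[assignment]
        else:
            min_leaf[node.id] = min(min_leaf[c.id] for c in node.children)

    def render(node: Node) -> str:
        if node.is_leaf():
            out = node.label or ""
        else:
            kids = sorted(node.children, key=lambda c: min_leaf[c.id])
            out = "(" + ",".join(render(c) for c in kids) + ")"
            if node.label is not None:
                out += node.label
            elif "support" in fields and node.support is not None:
                out += _fmt(node.support)
        if "length" in fields and node is not tree.root and node.length is not None:
            out += ":" + _fmt(node.length)
        return out

    return render(tree.root) + ";"


def read_newick_file(path) -> list[Tree]:
    """Read one or more Newick trees (one per non-empty line / ';' block)."""
    with open(path) as fh:
        text = fh.read()
    trees = []
    for chunk in text.split(";"):
        if chunk.strip():
            trees.append(parse_newick(chunk + ";"))
    return trees


# ---------------------------------------------------------------------------
# Clades
# ---------------------------------------------------------------------------


def canonical_split(side: Iterable[str], universe: Iterable[str]) -> frozenset[str]:
    """Canonical representation of a bipartition: the side containing the
    alphabetically smallest taxon of the universe."""
    side = frozenset(side)
    universe = frozenset(universe)
    if not side or not side < universe:
        raise TreeError("a clade must be a proper nonempty subset of the taxa")
    return side if min(universe) in side else universe - side


def nontrivial_splits(
    splits: Iterable[frozenset[str]], universe: Iterable[str]
) -> frozenset[frozenset[str]]:
    """Drop pendant-edge splits (side size 1 or n-1 in the unrooted view)."""
    universe = frozenset(universe)
    n = len(universe)
    return frozenset(s for s in splits if 1 < len(s) < n - 1)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

#: gap character (indel within an aligned gene)
GAP = "-"
#: missing character (gene absent from a taxon in a supermatrix)
MISSING = "?"


class AlignmentError(ValueError):
    """Inconsistent alignment (unequal lengths, unknown taxa, ...)."""


class Alignment:
    """Fixed set of equal-length sequences over a declared state space.

    ``partitions`` is an optional list of ``(gene, start, end)`` tuples with
    0-based, half-open column intervals.
    """

    def __init__(
        self,
        sequences: dict[str, str],
        partitions: list[tuple[str, int, int]] | None = None,
        alphabet: str = "protein",
    ):
        if not sequences:
            raise AlignmentError("alignment must contain at least one sequence")
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        self.sequences = dict(sequences)
        self.alphabet = alphabet
        self.partitions = list(partitions) if partitions else None
        if self.partitions is not None:
            n = self.n_sites
            for gene, start, end in self.partitions:
                if not (0 <= start < end <= n):
                    raise AlignmentError(
                        f"partition {gene!r} interval [{start},{end}) outside matrix"
                    )

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    @property
    def n_taxa(self) -> int:
        return len(self.sequences)

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.sequences.values())))

    def __getitem__(self, taxon: str) -> str:
        return self.sequences[taxon]

    def subset(self, taxa: Sequence[str]) -> "Alignment":
        missing = [t for t in taxa if t not in self.sequences]
        if missing:
            raise AlignmentError(f"unknown taxa: {missing}")
        return Alignment(
            {t: self.sequences[t] for t in taxa}, self.partitions, self.alphabet
        )

    def columns(self, start: int, end: int) -> "Alignment":
        return Alignment(
            {t: s[start:end] for t, s in self.sequences.items()},
            alphabet=self.alphabet,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.sequences == other.sequences
            and self.partitions == other.partitions
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Alignment {self.n_taxa} taxa x {self.n_sites} sites>"


def read_fasta(path) -> Alignment:
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise AlignmentError(f"no sequences found in {path}")
    return Alignment(seqs)


def write_fasta(alignment: Alignment, path) -> None:
    with open(path, "w") as fh:
        for taxon, seq in alignment.sequences.items():
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_phylip(path) -> Alignment:
    """Relaxed PHYLIP: header line, then ``name  sequence`` records."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise AlignmentError("malformed PHYLIP header")
        ntax, nsites = int(header[0]), int(header[1])
        seqs: dict[str, str] = {}
        for line in fh:
            if not line.strip():
                continue
            name, *rest = line.split()
            seqs[name] = "".join(rest)
    if len(seqs) != ntax or any(len(s) != nsites for s in seqs.values()):
        raise AlignmentError("PHYLIP body does not match header dimensions")
    return Alignment(seqs)


def write_phylip(alignment: Alignment, path) -> None:
    width = max(len(t) for t in alignment.taxa) + 2
    with open(path, "w") as fh:
        fh.write(f"{alignment.n_taxa} {alignment.n_sites}\n")
        for taxon, seq in alignment.sequences.items():
            fh.write(f"{taxon:<{width}}{seq}\n")


def read_partition_table(path) -> list[tuple[str, int, int]]:
    """TSV partition table: gene, start, end (0-based, half-open)."""
    import csv

    out = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "gene":
                continue
            out.append((row[0], int(row[1]), int(row[2])))
    return out


def write_partition_table(partitions: list[tuple[str, int, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tstart\tend\n")
        for gene, start, end in partitions:
            fh.write(f"{gene}\t{start}\t{end}\n")
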