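"""Duplication-loss reconciliation of gene trees against a species tree.

The engine implements parsimony reconciliation under unit duplication and
loss costs via the LCA (last-common-ancestor) mapping: each gene-tree node
maps to the most recent common ancestor of its descendant genomes, a node is
a duplication when it maps to the same species node as one of its children,
and losses are read off the species-tree path skipped along each gene edge.

Per-branch tallies use a *flow* convention so that copy numbers obey a
conservation law on every species branch: ``exiting = entering +
duplications - losses``, with one ancestral copy entering a virtual branch
above the species root.  Losses are charged to the species branch on which
the vanished lineage would have lived (the pruned sibling branches along the
skipped path), including the path from the species root down to the gene
root's mapping.  Duplications at the species root live on the virtual root
branch, which is keyed by the species root's node id.

Within-species (terminal-branch) duplications and losses are tallied like
any other branch but flagged, so reports can exclude them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .treecore import Node, Tree, TreeError


class ReconcileError(ValueError):
    pass


LeafMap = dict  # gene-leaf label -> species-leaf label


def leafmap_from_prefix(gene_tree: Tree, sep: str = ":") -> dict[str, str]:
    """Derive the leaf map from ``genome:family:copy``-style leaf labels."""
    return {lab: lab.split(sep, 1)[0] for lab in gene_tree.leaf_labels}


# ---------------------------------------------------------------------------
# Species-tree scaffolding
# ---------------------------------------------------------------------------


class _SpeciesIndex:
    """Precomputed ancestry structure for LCA queries on the species tree."""

    def __init__(self, species_tree: Tree):
        if not species_tree.is_binary():
            raise ReconcileError("species tree must be binary")
        self.tree = species_tree
        self.depth: dict[int, int] = {}
        self.parent: dict[int, int | None] = {}
        for node in species_tree.preorder():
            if node.parent is None:
                self.depth[node.id] = 0
                self.parent[node.id] = None
            else:
                self.depth[node.id] = self.depth[node.parent.id] + 1
                self.parent[node.id] = node.parent.id
        self.leaf_by_label = {n.label: n.id for n in species_tree.leaves()}

    def lca(self, a: int, b: int) -> int:
        while self.depth[a] > self.depth[b]:
            a = self.parent[a]
        while self.depth[b] > self.depth[a]:
            b = self.parent[b]
        while a != b:
            a = self.parent[a]
            b = self.parent[b]
        return a

    def path_down(self, top: int, bottom: int) -> list[int]:
        """Node ids strictly descending from ``top`` to ``bottom``,
        inclusive of both; ``top`` must be ancestral-or-equal."""
        path = [bottom]
        while bottom != top:
            bottom = self.parent[bottom]
            if bottom is None:
                raise ReconcileError("path_down: top is not an ancestor")
            path.append(bottom)
        return path[::-1]

    def other_child(self, node_id: int, child_id: int) -> int:
        node = self.tree.node(node_id)
        kids = [c.id for c in node.children]
        kids.remove(child_id)
        return kids[0]


# ---------------------------------------------------------------------------
# LCA mapping and event inference
# ---------------------------------------------------------------------------


def lca_map(
    gene_tree: Tree, species_tree: Tree, leafmap: dict[str, str]
) -> dict[int, int]:
    """Map every gene-tree node to a species-tree node: leaves through the
    leaf map, internal nodes to the MRCA of their children's images."""
    index = _SpeciesIndex(species_tree)
    mapping: dict[int, int] = {}
    for node in gene_tree.postorder():
        if node.is_leaf():
            genome = leafmap.get(node.label)
            if genome is None:
                raise ReconcileError(f"gene leaf {node.label!r} has no genome mapping")
            sid = index.leaf_by_label.get(genome)
            if sid is None:
                raise ReconcileError(
                    f"genome {genome!r} is absent from the species tree"
                )
            mapping[node.id] = sid
        else:
            img = mapping[node.children[0].id]
            for child in node.children[1:]:
                img = index.lca(img, mapping[child.id])
            mapping[node.id] = img
    return mapping


@dataclass
class ReconciliationResult:
    """Events and per-species-branch bookkeeping of one reconciliation.

    All per-branch dictionaries are keyed by the species node id at the
    *bottom* of the branch; the species root id keys the virtual root
    branch.  ``cost`` is total duplications + losses (unit costs).
    """

    species_tree: Tree
    mapping: dict[int, int]
    events: dict[int, str]  # gene internal node id -> speciation|duplication
    duplications: dict[int, int]
    losses: dict[int, int]
    entering: dict[int, int]
    exiting: dict[int, int]
    heuristic: bool = False

    @property
    def cost(self) -> int:
        return sum(self.duplications.values()) + sum(self.losses.values())

    @property
    def n_duplications(self) -> int:
        return sum(self.duplications.values())

    @property
    def n_losses(self) -> int:
        return sum(self.losses.values())

    def check_conservation(self) -> None:
        for node in self.species_tree.postorder():
            i = node.id
            if self.entering[i] + self.duplications[i] - self.losses[i] != self.exiting[i]:
                raise AssertionError(f"conservation violated on branch {i}")
            if node.parent is not None and self.entering[i] != self.exiting[node.parent.id]:
                raise AssertionError(f"flow violated at branch {i}")

    def branch_table(self, include_terminal: bool = False) -> pd.DataFrame:
        """Per-branch tallies keyed by the child-node clade.  Terminal
        (within-species) branches are excluded by default."""
        sets = self.species_tree.leaf_sets()
        rows = []
        for node in self.species_tree.postorder():
            terminal = node.is_leaf()
            if terminal and not include_terminal:
                continue
            rows.append(
                {
                    "clade": "|".join(sorted(sets[node.id])),
                    "terminal": terminal,
                    "virtual_root": node.parent is None,
                    "duplications": self.duplications[node.id],
                    "losses": self.losses[node.id],
                    "entering": self.entering[node.id],
                    "exiting": self.exiting[node.id],
                }
            )
        return pd.DataFrame(rows)


def reconcile_dl(
    gene_tree: Tree, species_tree: Tree, leafmap: dict[str, str]
) -> ReconciliationResult:
    """Most-parsimonious duplication-loss reconciliation (unit costs).

    The gene tree must be rooted (polytomies allowed); the species tree must
    be rooted and binary.
    """
    index = _SpeciesIndex(species_tree)
    mapping = lca_map(gene_tree, species_tree, leafmap)

    dups = {n.id: 0 for n in species_tree.postorder()}
    losses = {n.id: 0 for n in species_tree.postorder()}
    events: dict[int, str] = {}

    def charge_path_losses(top: int, bottom: int, include_top: bool) -> None:
        """Losses on the sibling branches pruned along the species path from
        ``top`` down to ``bottom``."""
        path = index.path_down(top, bottom)
        start = 0 if include_top else 1
        for k in range(start, len(path) - 1):
            losses[index.other_child(path[k], path[k + 1])] += 1

    for node in gene_tree.postorder():
        if node.is_leaf():
            continue
        is_dup = any(mapping[c.id] == mapping[node.id] for c in node.children)
        events[node.id] = "duplication" if is_dup else "speciation"
        if is_dup:
            dups[mapping[node.id]] += 1
        for child in node.children:
            charge_path_losses(
                mapping[node.id], mapping[child.id], include_top=is_dup
            )
    # origin: one copy travels from the species root to the gene root's image
    charge_path_losses(species_tree.root.id, mapping[gene_tree.root.id], True)

    entering: dict[int, int] = {}
    exiting: dict[int, int] = {}
    for node in species_tree.preorder():
        i = node.id
        entering[i] = 1 if node.parent is None else exiting[node.parent.id]
        exiting[i] = entering[i] + dups[i] - losses[i]

    result = ReconciliationResult(
        species_tree=species_tree,
        mapping=mapping,
        events=events,
        duplications=dups,
        losses=losses,
        entering=entering,
        exiting=exiting,
    )
    result.check_conservation()
    return result


def ancestral_copy_numbers(
    result: ReconciliationResult, species_nodes: list[int] | None = None
) -> dict[int, int]:
    """Copy count exiting each requested species node (the number of gene
    lineages leaving the node along each child branch)."""
    if species_nodes is None:
        species_nodes = [n.id for n in result.species_tree.postorder()]
    out = {}
    for nid in species_nodes:
        if nid not in result.exiting:
            raise ReconcileError(f"unknown species node id {nid}")
        out[nid] = result.exiting[nid]
    return out


# ---------------------------------------------------------------------------
# Rooting by DL minimisation
# ---------------------------------------------------------------------------


def root_min_dl(
    gene_tree: Tree, species_tree: Tree, leafmap: dict[str, str]
) -> Tree:
    """Root an (effectively unrooted) gene tree on the edge minimising the
    total duplication-loss cost.

    Ties break by smallest duplication count, then by the lexicographically
    smallest induced bipartition, so the result is deterministic.
    """
    if gene_tree.n_leaves() < 3:
        return gene_tree.copy()
    universe = gene_tree.leaf_labels
    sets = gene_tree.leaf_sets()
    seen: set[frozenset[str]] = set()
    best = None
    for node in gene_tree.postorder():
        if node.parent is None:
            continue
        side = sets[node.id]
        canon = side if min(universe) in side else universe - side
        if canon in seen or len(canon) == len(universe):
            continue
        seen.add(canon)
        rooted = gene_tree.rerooted_on_edge(side)
        res = reconcile_dl(rooted, species_tree, leafmap)
        key = (res.cost, res.n_duplications, tuple(sorted(canon)))
        if best is None or key < best[0]:
            best = (key, rooted)
    assert best is not None
    return best[1]


# ---------------------------------------------------------------------------
# Weak-branch rearrangement
# ---------------------------------------------------------------------------


def _insert_everywhere(shape, x):
    """All ways of grafting ``x`` onto an edge of ``shape`` (incl. the root)."""
    yield (shape, x)
    if isinstance(shape, tuple):
        a, b = shape
        for s in _insert_everywhere(a, x):
            yield (s, b)
        for s in _insert_everywhere(b, x):
            yield (a, s)


def _resolution_shapes(indices: tuple[int, ...]):
    """All rooted binary shapes over the given leaf indices, as nested
    pairs; (2k-3)!! of them."""
    if len(indices) == 1:
        yield indices[0]
        return
    for rest in _resolution_shapes(indices[1:]):
        yield from _insert_everywhere(rest, indices[0])


def _materialize(shape, subtrees: list[Node]) -> Node:
    if isinstance(shape, int):
        return subtrees[shape]
    node = Node()
    node.add_child(_materialize(shape[0], subtrees))
    node.add_child(_materialize(shape[1], subtrees))
    return node


def rearrange_weak(
    gene_tree: Tree,
    species_tree: Tree,
    leafmap: dict[str, str],
    support_threshold: float = 70.0,
    exhaustive_limit: int = 7,
) -> tuple[Tree, ReconciliationResult]:
    """Collapse weakly supported gene-tree edges and re-resolve them to
    their most parsimonious position.

    Internal edges with support strictly below ``support_threshold`` (0-100
    scale) are collapsed into polytomies; each polytomy is then re-resolved
    to minimise the total duplication+loss cost -- exhaustively for
    polytomies of up to ``exhaustive_limit`` children, by greedy stepwise
    insertion (flagged ``heuristic``) above that.  The returned cost is
    never larger than the input tree's.
    """
    if not 0.0 <= support_threshold <= 100.0:
        raise ReconcileError("support threshold must lie in [0, 100]")
    input_cost = reconcile_dl(gene_tree, species_tree, leafmap).cost

    work = gene_tree.copy()
    for node in list(work.postorder()):
        if (
            node.parent is not None
            and not node.is_leaf()
            and node.support is not None
            and node.support < support_threshold
        ):
            parent = node.parent
            idx = parent.children.index(node)
            parent.children.pop(idx)
            for k, child in enumerate(node.children):
                parent.children.insert(idx + k, child)
                child.parent = parent
    work.reindex()

    heuristic = False
    # resolve polytomies one at a time (bottom-up); each candidate is scored
    # by the duplication-loss cost of the whole tree
    while True:
        polytomy = next(
            (n for n in work.postorder() if len(n.children) > 2), None
        )
        if polytomy is None:
            break
        k = len(polytomy.children)
        if k <= exhaustive_limit:
            best_tree, best_cost = None, None
            for shape in _resolution_shapes(tuple(range(k))):
                cand = _apply_shape(work, polytomy.id, shape)
                cost = reconcile_dl(cand, species_tree, leafmap).cost
                if best_cost is None or cost < best_cost:
                    best_cost, best_tree = cost, cand
            work = best_tree
        else:
            heuristic = True
            work = _greedy_pair_join(work, polytomy.id, species_tree, leafmap)

    final = reconcile_dl(work, species_tree, leafmap)
    if final.cost > input_cost:  # safeguard: rearrangement must not cost more
        work = gene_tree.copy()
        final = reconcile_dl(work, species_tree, leafmap)
    final.heuristic = heuristic
    return work, final


def _apply_shape(tree: Tree, polytomy_id: int, shape) -> Tree:
    """Copy ``tree`` with the polytomy resolved according to ``shape``
    (nested pairs of child indices); the polytomy node becomes the root of
    the resolution."""
    cand = tree.copy()  # copy preserves postorder ids
    poly = cand.node(polytomy_id)
    subtrees = list(poly.children)
    for c in subtrees:
        c.parent = None
    resolved = _materialize(shape, subtrees)
    poly.children = []
    for c in resolved.children if resolved.children else [resolved]:
        poly.add_child(c)
    return cand.reindex()


def _greedy_pair_join(
    tree: Tree, polytomy_id: int, species_tree: Tree, leafmap: dict[str, str]
) -> Tree:
    """Heuristic resolution of a large polytomy: repeatedly join the pair of
    child subtrees whose grouping yields the lowest whole-tree cost."""
    work = tree
    poly_id = polytomy_id
    while len(work.node(poly_id).children) > 2:
        k = len(work.node(poly_id).children)
        best = None
        for i, j in itertools.combinations(range(k), 2):
            shape = tuple([(i, j)] + [x for x in range(k) if x not in (i, j)])
            # join (i, j) under a new node, keep the rest as a polytomy
            cand = work.copy()
            poly = cand.node(poly_id)
            kids = list(poly.children)
            for c in kids:
                c.parent = None
            joint = Node()
            joint.add_child(kids[i])
            joint.add_child(kids[j])
            poly.children = []
            poly.add_child(joint)
            for x in range(k):
                if x not in (i, j):
                    poly.add_child(kids[x])
            cand.reindex()
            cost = reconcile_dl(cand, species_tree, leafmap).cost
            if best is None or cost < best[0]:
                best = (cost, cand, poly.id)
        _, work, poly_id = best
    return work


# ---------------------------------------------------------------------------
# Bootstrap averaging
# ---------------------------------------------------------------------------


@dataclass
class AveragedReconciliation:
    """Arithmetic means of per-branch duplication counts and exiting copy
    numbers over bootstrap replicates."""

    species_tree: Tree
    n_replicates: int
    mean_duplications: dict[int, float]
    mean_losses: dict[int, float]
    mean_copy_numbers: dict[int, float]
    replicate_results: list[ReconciliationResult] = field(default_factory=list)

    def branch_table(self, include_terminal: bool = False) -> pd.DataFrame:
        sets = self.species_tree.leaf_sets()
        rows = []
        for node in self.species_tree.postorder():
            if node.is_leaf() and not include_terminal:
                continue
            rows.append(
                {
                    "clade": "|".join(sorted(sets[node.id])),
                    "terminal": node.is_leaf(),
                    "mean_duplications": self.mean_duplications[node.id],
                    "mean_losses": self.mean_losses[node.id],
                    "mean_copy_number": self.mean_copy_numbers[node.id],
                }
            )
        return pd.DataFrame(rows)


def bootstrap_average(
    replicate_trees: list[Tree],
    species_tree: Tree,
    leafmap: dict[str, str],
    support_threshold: float | None = None,
) -> AveragedReconciliation:
    """Reconcile each bootstrap replicate independently (optionally after
    weak-branch rearrangement) and average the per-branch duplication
    counts and exiting copy numbers."""
    if not replicate_trees:
        raise ReconcileError("need at least one replicate tree")
    ref_leaves = replicate_trees[0].leaf_labels
    for k, rep in enumerate(replicate_trees[1:], start=2):
        if rep.leaf_labels != ref_leaves:
            raise ReconcileError(f"replicate {k} has a mismatched leaf set")

    results = []
    for rep in replicate_trees:
        if support_threshold is not None:
            _, res = rearrange_weak(rep, species_tree, leafmap, support_threshold)
        else:
            res = reconcile_dl(rep, species_tree, leafmap)
        results.append(res)

    n = len(results)
    ids = [node.id for node in species_tree.postorder()]
    mean_d = {i: sum(r.duplications[i] for r in results) / n for i in ids}
    mean_l = {i: sum(r.losses[i] for r in results) / n for i in ids}
    mean_c = {i: sum(r.exiting[i] for r in results) / n for i in ids}
    return AveragedReconciliation(
        species_tree=species_tree,
        n_replicates=n,
        mean_duplications=mean_d,
        mean_losses=mean_l,
        mean_copy_numbers=mean_c,
        replicate_results=results,
    )
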