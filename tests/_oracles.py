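"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: the likelihood
oracle sums explicitly over internal-state assignments, the reconciliation
oracle enumerates every ancestor-consistent gene-to-species map, and the
single-rate dating oracle optimises the clock likelihood directly.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize

from paleozyme.reconcile import _SpeciesIndex
from paleozyme.treecore import Node, Tree

# ---------------------------------------------------------------------------
# Likelihood: explicit sum over internal-state assignments
# ---------------------------------------------------------------------------


def loglik_bruteforce(tree, alignment, model) -> float:
    """Sum over all internal-node state assignments, site by site and
    category by category (only feasible for tiny instances)."""
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    n = model.n_states
    encoded = {t: model.encode(alignment[t]) for t in alignment.taxa}
    n_sites = alignment.n_sites

    total = 0.0
    for site in range(n_sites):
        site_lik = 0.0
        for rate in model.category_rates:
            P = {
                node.id: model.transition_matrix((node.length or 0.0) * rate)
                for node in nodes
                if node.parent is not None
            }
            cat_lik = 0.0
            for states in itertools.product(range(n), repeat=len(internal)):
                assign = {node.id: s for node, s in zip(internal, states)}
                ok = True
                prob = model.frequencies[assign[tree.root.id]]
                for node in nodes:
                    if node.parent is None:
                        continue
                    if node.is_leaf():
                        obs = encoded[node.label][site] if node.label in encoded else -1
                        if obs < 0:
                            # missing data: sum over leaf states = row sum = 1
                            continue
                        prob *= P[node.id][assign[node.parent.id], obs]
                    else:
                        prob *= P[node.id][assign[node.parent.id], assign[node.id]]
                    if prob == 0.0:
                        ok = False
                        break
                if ok:
                    cat_lik += prob
            site_lik += cat_lik / model.n_categories
        total += math.log(site_lik)
    return total


# ---------------------------------------------------------------------------
# Reconciliation: brute-force minimum over ancestor-consistent maps
# ---------------------------------------------------------------------------


def reconcile_bruteforce_min_cost(gene_tree, species_tree, leafmap) -> int:
    """Minimum duplications + losses over every ancestor-consistent map.

    Event rules: a binary gene node is a speciation only when it maps to the
    LCA of its children's images and those images fall into distinct child
    subtrees; otherwise it is a duplication.  Losses are the skipped species
    edges along each gene edge (one fewer below a speciation) plus the path
    from the species root to the gene root's image (single-origin
    convention, matching the implementation's conservation bookkeeping).
    """
    idx = _SpeciesIndex(species_tree)
    anc: dict[int, frozenset[int]] = {}
    for node in species_tree.postorder():
        chain = [node.id]
        p = node
        while p.parent is not None:
            p = p.parent
            chain.append(p.id)
        anc[node.id] = frozenset(chain)

    def dist(a: int, b: int) -> int:
        return idx.depth[b] - idx.depth[a]

    leaf_ids = {
        n.id: idx.leaf_by_label[leafmap[n.label]] for n in gene_tree.leaves()
    }
    internals = [n for n in gene_tree.postorder() if not n.is_leaf()]
    sp_ids = [n.id for n in species_tree.postorder()]

    best = None
    for combo in itertools.product(sp_ids, repeat=len(internals)):
        M = dict(leaf_ids)
        for node, s in zip(internals, combo):
            M[node.id] = s
        if any(
            M[n.id] not in anc[M[c.id]] for n in internals for c in n.children
        ):
            continue
        D = L = 0
        for node in internals:
            imgs = [M[c.id] for c in node.children]
            lca = imgs[0]
            for x in imgs[1:]:
                lca = idx.lca(lca, x)
            is_speciation = M[node.id] == lca and all(
                x != M[node.id] for x in imgs
            )
            if not is_speciation:
                D += 1
            for c in node.children:
                d = dist(M[node.id], M[c.id])
                L += d if not is_speciation else d - 1
        L += dist(species_tree.root.id, M[gene_tree.root.id])
        cost = D + L
        if best is None or cost < best:
            best = cost
    return best


def all_rooted_shapes(k: int):
    """All rooted binary tree shapes on k ordered leaf slots, as nested
    index pairs ((2k-3)!! shapes)."""

    def insert(shape, x):
        yield (shape, x)
        if isinstance(shape, tuple):
            a, b = shape
            for s in insert(a, x):
                yield (s, b)
            for s in insert(b, x):
                yield (a, s)

    def rec(indices):
        if len(indices) == 1:
            yield indices[0]
            return
        for rest in rec(indices[1:]):
            yield from insert(rest, indices[0])

    yield from rec(tuple(range(k)))


def gene_tree_from_shape(shape, labels: list[str]) -> Tree:
    def build(s) -> Node:
        if isinstance(s, int):
            return Node(label=labels[s])
        node = Node()
        node.add_child(build(s[0]))
        node.add_child(build(s[1]))
        return node

    return Tree(build(shape))


# ---------------------------------------------------------------------------
# Dating: single-rate (strict clock) oracle
# ---------------------------------------------------------------------------


def langley_fitch_oracle(phylogram, root_age: float) -> tuple[float, dict]:
    """Maximum-likelihood single-rate dating with the root age fixed:
    direct optimisation over one rate and the internal node ages (nested
    fraction parameterisation, numeric gradient-free refinement)."""
    tree = phylogram.copy()
    internal = [
        n for n in tree.preorder() if not n.is_leaf() and n.parent is not None
    ]
    x = {
        n.id: (n.length or 0.0)
        for n in tree.postorder()
        if n.parent is not None
    }

    def decode(params):
        ages = {tree.root.id: root_age}
        for n in tree.postorder():
            if n.is_leaf():
                ages[n.id] = 0.0
        for k, n in enumerate(internal):
            ages[n.id] = ages[n.parent.id] * params[k + 1]
        return ages

    def neg(params):
        rate = math.exp(params[0])
        ages = decode(params)
        total = 0.0
        for n in tree.postorder():
            if n.parent is None:
                continue
            t = max(ages[n.parent.id] - ages[n.id], 1e-12)
            mu = rate * t
            total += x[n.id] * math.log(mu) - mu
        return -total

    x0 = np.concatenate([[math.log(1e-3)], np.full(len(internal), 0.5)])
    bounds = [(math.log(1e-10), math.log(10.0))] + [(1e-6, 1 - 1e-6)] * len(internal)
    res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 5000, "ftol": 1e-15})
    ages = decode(res.x)
    return math.exp(res.x[0]), ages
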