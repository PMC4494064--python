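"""Synthetic-data generators with recorded ground truth.

This module produces every input the pipeline consumes: ultrametric species
trees with node ages, gene families evolved by a branch-wise
duplication-loss birth-death process (with the true per-branch event counts
and copy numbers kept in a ledger), alignments simulated under a
substitution model with gamma rate heterogeneity, relaxed-clock phylograms
(i.i.d. lognormal branch rates), ortholog cluster tables with planted
filter violations, and homology hit tables with planted decoys.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylosignal import SubstModel
from .treecore import Alignment, Node, Tree

_DEAD = "__dead__"


class SyntheticDataError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Species trees
# ---------------------------------------------------------------------------


def sim_species_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    root_age: float = 800.0,
    seed: int = 0,
    taxon_prefix: str = "t",
) -> Tree:
    """Ultrametric binary species tree from a Yule process, rescaled so the
    root age equals ``root_age`` (Ma).  Leaves are labelled ``t01 ...`` and
    have age zero."""
    if n_taxa < 2:
        raise SyntheticDataError("need at least two taxa")
    if birth_rate <= 0 or root_age <= 0:
        raise SyntheticDataError("birth_rate and root_age must be positive")
    rng = np.random.default_rng(seed)

    root = Node()
    first = [root.add_child(Node()), root.add_child(Node())]
    split_time = {id(root): 0.0}
    active = list(first)
    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        node = active.pop(int(rng.integers(k)))
        split_time[id(node)] = t
        active.append(node.add_child(Node()))
        active.append(node.add_child(Node()))
    t_end = t + rng.exponential(1.0 / (birth_rate * n_taxa))

    scale = root_age / t_end
    width = max(2, len(str(n_taxa)))
    counter = 0

    def finish(node: Node) -> None:
        nonlocal counter
        if node.children:
            node.age = (t_end - split_time[id(node)]) * scale
            for c in node.children:
                finish(c)
        else:
            counter += 1
            node.label = f"{taxon_prefix}{counter:0{width}d}"
            node.age = 0.0

    finish(root)
    tree = Tree(root)
    tree.set_lengths_from_ages()
    return tree


# ---------------------------------------------------------------------------
# Gene families under duplication-loss birth-death
# ---------------------------------------------------------------------------


@dataclass
class GeneFamilyTruth:
    """A simulated gene family with its true history.

    Event counts and copy numbers are keyed by the species-tree node id of
    the branch *entering* that node; the species root id keys the virtual
    root branch (entering and exiting one ancestral copy, no events).
    Invariants (asserted at construction): on every branch
    ``exiting = entering + duplications - losses``, the entering count of a
    child branch equals the exiting count of its parent branch, and leaf
    exiting counts equal the gene tree's per-genome leaf counts.
    """

    gene_tree: Tree
    species_tree: Tree
    family_id: str
    duplications: dict[int, int]
    losses: dict[int, int]
    entering: dict[int, int]
    exiting: dict[int, int]
    dup_rate: float
    loss_rate: float
    n_resampled: int = 0

    def leaf_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for leaf in self.gene_tree.leaves():
            genome = leaf.label.split(":", 1)[0]
            counts[genome] = counts.get(genome, 0) + 1
        return counts

    def check_conservation(self) -> None:
        for node in self.species_tree.postorder():
            i = node.id
            if (
                self.entering[i] + self.duplications[i] - self.losses[i]
                != self.exiting[i]
            ):
                raise AssertionError(f"conservation violated on branch {i}")
            if node.parent is not None and self.entering[i] != self.exiting[node.parent.id]:
                raise AssertionError(f"flow violated at branch {i}")
        observed = self.leaf_counts()
        for leaf in self.species_tree.leaves():
            if self.exiting[leaf.id] != observed.get(leaf.label, 0):
                raise AssertionError(f"leaf count mismatch for {leaf.label}")


def sim_gene_family(
    species_tree: Tree,
    dup_rate: float,
    loss_rate: float,
    seed: int = 0,
    family_id: str = "fam",
    max_resample: int = 10_000,
) -> GeneFamilyTruth:
    """Evolve one gene family along a dated species tree.

    A single ancestral copy at the species root evolves by a Gillespie
    birth-death process (rates per lineage per Ma) along every species
    branch; each surviving lineage speciates at internal species nodes.
    Families that go globally extinct are resampled (up to ``max_resample``
    attempts, counted on the result).  Gene-tree leaves are labelled
    ``genome:family:copy`` and branch lengths are in Ma.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise SyntheticDataError("rates must be non-negative")
    for node in species_tree.postorder():
        if node.age is None:
            raise SyntheticDataError("species tree must carry node ages")
    rng = np.random.default_rng(seed)

    for attempt in range(max_resample):
        truth = _simulate_family_once(species_tree, dup_rate, loss_rate, rng, family_id)
        if truth is not None:
            truth.n_resampled = attempt
            truth.check_conservation()
            return truth
    raise SyntheticDataError(
        f"family went extinct in {max_resample} consecutive attempts; "
        "loss rate too high for this tree"
    )


def _simulate_family_once(
    species_tree: Tree,
    lam: float,
    mu: float,
    rng: np.random.Generator,
    family_id: str,
) -> GeneFamilyTruth | None:
    dups: dict[int, int] = {}
    losses: dict[int, int] = {}
    entering: dict[int, int] = {}
    exiting: dict[int, int] = {}

    sroot = species_tree.root
    groot = Node(age=sroot.age)
    # virtual root branch: one ancestral copy, no events above the root
    entering[sroot.id] = exiting[sroot.id] = 1
    dups[sroot.id] = losses[sroot.id] = 0

    arrivals: dict[int, list[Node]] = {sroot.id: [groot]}
    for snode in species_tree.preorder():
        for child in snode.children:
            stubs = list(arrivals[snode.id])
            n_in = len(stubs)
            n_dup = n_loss = 0
            t = snode.age
            t_bottom = child.age
            total_rate = lam + mu
            while stubs and total_rate > 0:
                k = len(stubs)
                dt = rng.exponential(1.0 / (k * total_rate))
                if t - dt <= t_bottom:
                    break
                t -= dt
                node = stubs.pop(int(rng.integers(k)))
                if rng.random() < lam / total_rate:
                    ev = node.add_child(Node(age=t))
                    stubs.append(ev)
                    stubs.append(ev)
                    n_dup += 1
                else:
                    node.add_child(Node(label=_DEAD, age=t))
                    n_loss += 1
            dups[child.id] = n_dup
            losses[child.id] = n_loss
            entering[child.id] = n_in
            exiting[child.id] = len(stubs)
            ends: list[Node] = []
            for stub in stubs:
                end = stub.add_child(Node(age=child.age))
                if child.is_leaf():
                    end.label = child.label  # genome; final labels set later
                ends.append(end)
            if not child.is_leaf():
                arrivals[child.id] = ends

    pruned = _prune_dead(groot)
    if pruned is None:
        return None
    pruned.parent = None
    # unique leaf labels genome:family:copy, numbered in traversal order
    per_genome: dict[str, int] = {}
    for node in Tree._postorder(pruned):
        if node.is_leaf():
            genome = node.label
            per_genome[genome] = per_genome.get(genome, 0) + 1
            node.label = f"{genome}:{family_id}:{per_genome[genome]}"
    gene_tree = Tree(pruned)
    gene_tree.set_lengths_from_ages()
    return GeneFamilyTruth(
        gene_tree=gene_tree,
        species_tree=species_tree,
        family_id=family_id,
        duplications=dups,
        losses=losses,
        entering=entering,
        exiting=exiting,
        dup_rate=lam,
        loss_rate=mu,
    )


def _prune_dead(node: Node) -> Node | None:
    """Drop extinct lineages and suppress unary nodes (ages are kept, so
    branch lengths can be recomputed afterwards)."""
    if node.is_leaf():
        return None if node.label == _DEAD else node
    kept = [k for k in (_prune_dead(c) for c in node.children) if k is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    node.children = []
    for k in kept:
        node.add_child(k)
    return node


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------


def sim_alignment(
    tree: Tree, n_sites: int, model: SubstModel, seed: int = 0
) -> Alignment:
    """Simulate sequences root-to-tips under ``model``.

    Branch lengths are expected substitutions per site.  Per-site gamma rate
    categories are drawn uniformly and recorded on the returned alignment as
    ``site_rate_categories``.
    """
    if n_sites < 1:
        raise SyntheticDataError("n_sites must be positive")
    rng = np.random.default_rng(seed)
    n = model.n_states
    cats = rng.integers(model.n_categories, size=n_sites)
    states: dict[int, np.ndarray] = {
        tree.root.id: rng.choice(n, size=n_sites, p=model.frequencies)
    }
    for node in tree.preorder():
        if node is tree.root:
            continue
        if node.length is None:
            raise SyntheticDataError("every non-root branch needs a length")
        parent_states = states[node.parent.id]
        child = np.empty(n_sites, dtype=np.int64)
        for c, rate in enumerate(model.category_rates):
            in_cat = cats == c
            if not in_cat.any():
                continue
            P = model.transition_matrix(node.length * rate)
            for s in range(n):
                mask = in_cat & (parent_states == s)
                m = int(mask.sum())
                if m:
                    child[mask] = rng.choice(n, size=m, p=P[s])
        states[node.id] = child

    symbols = np.array(list(model.symbols))
    seqs = {
        leaf.label: "".join(symbols[states[leaf.id]]) for leaf in tree.leaves()
    }
    aln = Alignment(seqs)
    aln.site_rate_categories = cats  # type: ignore[attr-defined]
    return aln


# ---------------------------------------------------------------------------
# Relaxed-clock phylograms
# ---------------------------------------------------------------------------


@dataclass
class RelaxedPhylogram:
    """Phylogram realised from a dated tree under an uncorrelated lognormal
    clock: per-branch rates are i.i.d. lognormal with arithmetic mean
    ``mean_rate`` and log-scale standard deviation ``sigma``; branch length
    = rate x duration (optionally Poisson-perturbed at ``n_sites`` sites).

    ``true_ages`` and ``true_rates`` are keyed by the clade (leaf-label
    frozenset) below the node / branch."""

    tree: Tree
    true_ages: dict[frozenset[str], float]
    true_rates: dict[frozenset[str], float]
    mean_rate: float
    sigma: float
    n_sites: int | None = None


def sim_relaxed_phylogram(
    species_tree: Tree,
    mean_rate: float,
    sigma: float,
    seed: int = 0,
    n_sites: int | None = None,
) -> RelaxedPhylogram:
    if sigma < 0:
        raise SyntheticDataError("sigma must be non-negative")
    if mean_rate <= 0:
        raise SyntheticDataError("mean_rate must be positive")
    rng = np.random.default_rng(seed)
    tree = species_tree.copy()
    sets = tree.leaf_sets()
    true_ages: dict[frozenset[str], float] = {}
    true_rates: dict[frozenset[str], float] = {}
    mu_log = math.log(mean_rate) - 0.5 * sigma * sigma
    for node in tree.preorder():
        if node.age is None:
            raise SyntheticDataError("species tree must carry node ages")
        true_ages[sets[node.id]] = node.age
        if node is tree.root:
            continue
        rate = mean_rate if sigma == 0 else float(rng.lognormal(mu_log, sigma))
        duration = node.parent.age - node.age
        length = rate * duration
        if n_sites is not None:
            length = rng.poisson(length * n_sites) / n_sites
        node.length = length
        true_rates[sets[node.id]] = rate
    for node in tree.postorder():
        node.age = None  # the consumer must not see the truth
    return RelaxedPhylogram(
        tree=tree,
        true_ages=true_ages,
        true_rates=true_rates,
        mean_rate=mean_rate,
        sigma=sigma,
        n_sites=n_sites,
    )


# ---------------------------------------------------------------------------
# Ortholog cluster tables with planted violations
# ---------------------------------------------------------------------------


def sim_cluster_table(
    n_genomes: int,
    n_clusters: int,
    paralog_fraction: float = 0.0,
    dropout_fraction: float = 0.0,
    rbh_violation_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Ortholog cluster and similarity-score tables with planted defects.

    Each cluster independently receives a paralog (two proteins from one
    genome), an occupancy dropout (fewer than half of the genomes) and/or a
    reciprocal-best-hit violation (one member's best hit redirected to a
    protein outside the cluster) with the given probabilities.  Returns
    ``(clusters, scores, truth)`` where ``truth`` has one row per cluster
    with the planted labels and the expected keep decision at a 50%
    occupancy threshold.
    """
    for frac in (paralog_fraction, dropout_fraction, rbh_violation_fraction):
        if not 0.0 <= frac <= 1.0:
            raise SyntheticDataError("fractions must lie in [0, 1]")
    if n_genomes < 4:
        raise SyntheticDataError("need at least 4 genomes to plant violations")
    rng = np.random.default_rng(seed)
    genomes = [f"g{i + 1:03d}" for i in range(n_genomes)]
    low_max = (n_genomes - 1) // 2  # largest genome count strictly below 50%
    high_min = math.ceil(n_genomes / 2)

    cluster_rows: list[tuple[str, str, str]] = []
    score_rows: list[tuple[str, str, float]] = []
    truth_rows = []
    planted: list[dict] = []
    for i in range(n_clusters):
        cid = f"c{i + 1:04d}"
        paralog = rng.random() < paralog_fraction
        dropout = rng.random() < dropout_fraction
        rbh_violation = rng.random() < rbh_violation_fraction
        size = (
            int(rng.integers(1, low_max + 1))
            if dropout
            else int(rng.integers(high_min, n_genomes + 1))
        )
        members = sorted(rng.choice(n_genomes, size=size, replace=False))
        proteins = {genomes[g]: f"{genomes[g]}|{cid}|1" for g in members}
        if paralog:
            g = genomes[int(rng.choice(members))]
            cluster_rows.append((cid, g, f"{g}|{cid}|2"))
        for g, p in proteins.items():
            cluster_rows.append((cid, g, p))
        planted.append(
            {
                "cid": cid,
                "proteins": proteins,
                "rbh_violation": rbh_violation,
                "paralog": paralog,
                "dropout": dropout,
            }
        )

    # in-cluster scores: mutual best hits by construction (symmetric, < 140)
    for info in planted:
        prots = list(info["proteins"].values())
        for a_i in range(len(prots)):
            for b_i in range(a_i + 1, len(prots)):
                s = float(100.0 + rng.random() * 20.0)
                score_rows.append((prots[a_i], prots[b_i], s))
                score_rows.append((prots[b_i], prots[a_i], s))

    # planted RBH violations: redirect one member's best hit in one genome
    # to another cluster's protein with an unbeatable score
    for idx, info in enumerate(planted):
        if not info["rbh_violation"]:
            continue
        done = False
        member_genomes = list(info["proteins"])
        for j in rng.permutation(n_clusters):
            other = planted[int(j)]
            if other["cid"] == info["cid"]:
                continue
            shared = [g for g in member_genomes if g in other["proteins"]]
            if len(shared) < 2:
                continue
            src_g, dst_g = shared[0], shared[1]
            p = info["proteins"][src_g]
            q = other["proteins"][dst_g]  # outside protein in genome dst_g
            score_rows.append((p, q, 150.0))
            done = True
            break
        info["rbh_violation"] = done  # could not plant -> not a violation

    for info in planted:
        keep = not (info["paralog"] or info["dropout"] or info["rbh_violation"])
        truth_rows.append(
            {
                "cluster": info["cid"],
                "single_copy_ok": not info["paralog"],
                "occupancy_ok": not info["dropout"],
                "rbh_ok": not info["rbh_violation"],
                "keep": keep,
            }
        )

    clusters = pd.DataFrame(cluster_rows, columns=["cluster", "genome", "protein"])
    clusters = clusters.sort_values(["cluster", "genome", "protein"]).reset_index(drop=True)
    scores = pd.DataFrame(score_rows, columns=["query", "subject", "score"])
    truth = pd.DataFrame(truth_rows)
    return clusters, scores, truth


# ---------------------------------------------------------------------------
# Homology hit tables with planted decoys
# ---------------------------------------------------------------------------


def sim_hit_table(
    families: list[str],
    genomes: list[str],
    true_counts: pd.DataFrame,
    decoy_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Homology hit table realising ``true_counts`` (genomes x families).

    True hits receive e-values <= 1e-5 and a positive domain flag; decoys
    (Poisson(``decoy_rate``) per genome) receive an e-value above the
    threshold, a negative domain flag, or both, so the downstream filters
    can reject them exactly.
    """
    if decoy_rate < 0:
        raise SyntheticDataError("decoy_rate must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for g in genomes:
        for fam in families:
            k = int(true_counts.loc[g, fam]) if fam in true_counts.columns else 0
            if k < 0:
                raise SyntheticDataError("true counts must be non-negative")
            for j in range(k):
                rows.append(
                    {
                        "family": fam,
                        "genome": g,
                        "protein": f"{g}|{fam}|{j + 1}",
                        "evalue": float(10.0 ** -rng.uniform(5.0, 30.0)),
                        "domain_ok": True,
                    }
                )
        for j in range(rng.poisson(decoy_rate)):
            fam = families[int(rng.integers(len(families)))]
            mode = int(rng.integers(3))
            rows.append(
                {
                    "family": fam,
                    "genome": g,
                    "protein": f"{g}|decoy|{j + 1}",
                    "evalue": float(10.0 ** -rng.uniform(0.0, 4.9))
                    if mode in (0, 2)
                    else float(10.0 ** -rng.uniform(5.0, 30.0)),
                    "domain_ok": mode == 0,
                }
            )
    return pd.DataFrame(
        rows, columns=["family", "genome", "protein", "evalue", "domain_ok"]
    )
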