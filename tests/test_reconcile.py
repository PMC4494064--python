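"""Duplication-loss reconciliation: LCA mapping, event counts, rooting,
weak-branch rearrangement, bootstrap averaging, copy-number bookkeeping."""

import itertools

import numpy as np
import pytest

from _oracles import (
    all_rooted_shapes,
    gene_tree_from_shape,
    reconcile_bruteforce_min_cost,
)
from paleozyme.reconcile import (
    ReconcileError,
    ancestral_copy_numbers,
    bootstrap_average,
    lca_map,
    leafmap_from_prefix,
    rearrange_weak,
    reconcile_dl,
    root_min_dl,
)
from paleozyme.synthetic_data import sim_gene_family, sim_species_tree
from paleozyme.treecore import parse_newick


def _node_by_clade(species):
    sets = species.leaf_sets()
    return {tuple(sorted(sets[n.id])): n.id for n in species.postorder()}


class TestLcaMap:
    lm = {"a1": "A", "b1": "B", "a2": "A", "c1": "C"}

    def test_congruent_tree_maps_isomorphically(self, species3):
        gene = parse_newick("((a1,b1),c1);")
        m = lca_map(gene, species3, self.lm)
        by = _node_by_clade(species3)
        assert m[gene.root.id] == by[("A", "B", "C")]
        assert m[gene.mrca({"a1", "b1"}).id] == by[("A", "B")]

    def test_worked_example(self, species3):
        gene = parse_newick("((a1,b1),(a2,c1));")
        m = lca_map(gene, species3, self.lm)
        by = _node_by_clade(species3)
        assert m[gene.root.id] == by[("A", "B", "C")]
        assert m[gene.mrca({"a1", "b1"}).id] == by[("A", "B")]
        assert m[gene.mrca({"a2", "c1"}).id] == by[("A", "B", "C")]

    def test_parent_image_ancestral_or_equal(self, species4):
        rng = np.random.default_rng(0)
        depth = {}
        for node in species4.preorder():
            depth[node.id] = 0 if node.parent is None else depth[node.parent.id] + 1
        for shape in itertools.islice(all_rooted_shapes(4), 5):
            labels = [f"{g.lower()}{i}" for i, g in enumerate(rng.choice(list("ABCD"), 4))]
            gene = gene_tree_from_shape(shape, labels)
            lm = {lab: lab[0].upper() for lab in labels}
            m = lca_map(gene, species4, lm)
            for node in gene.postorder():
                if node.parent is not None:
                    assert depth[m[node.parent.id]] <= depth[m[node.id]]

    def test_unmapped_genome_rejected(self, species3):
        gene = parse_newick("(x1,b1);")
        with pytest.raises(ReconcileError):
            lca_map(gene, species3, {"x1": "X", "b1": "B"})


class TestReconcileDL:
    def test_congruent_family_no_events(self, species3):
        gene = parse_newick("((a1,b1),c1);")
        res = reconcile_dl(gene, species3, {"a1": "A", "b1": "B", "c1": "C"})
        assert res.cost == 0
        assert set(res.exiting.values()) == {1}

    def test_single_within_lineage_duplication(self):
        species = parse_newick("(A,B);")
        res = reconcile_dl(
            parse_newick("((a1,a2),b1);"), species, {"a1": "A", "a2": "A", "b1": "B"}
        )
        assert (res.n_duplications, res.n_losses) == (1, 0)

    def test_worked_example_counts_and_copies(self, species3):
        gene = parse_newick("((a1,b1),(a2,c1));")
        res = reconcile_dl(
            gene, species3, {"a1": "A", "b1": "B", "a2": "A", "c1": "C"}
        )
        by = _node_by_clade(species3)
        assert (res.n_duplications, res.n_losses) == (1, 2)
        assert res.exiting[by[("A", "B", "C")]] == 2
        assert res.exiting[by[("A", "B")]] == 2
        assert res.exiting[by[("A",)]] == 2
        assert res.exiting[by[("B",)]] == 1
        assert res.exiting[by[("C",)]] == 1

    def test_terminal_branches_excluded_from_default_report(self, species3):
        gene = parse_newick("((a1,a2),(b1,c1));")
        res = reconcile_dl(
            gene, species3, {"a1": "A", "a2": "A", "b1": "B", "c1": "C"}
        )
        table = res.branch_table()
        assert not table["terminal"].any()
        full = res.branch_table(include_terminal=True)
        assert full["terminal"].sum() == 3

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_on_simulated_families(self, dated_tree10, seed):
        truth = sim_gene_family(dated_tree10, 0.004, 0.003, seed=seed + 50)
        res = reconcile_dl(
            truth.gene_tree, dated_tree10, leafmap_from_prefix(truth.gene_tree)
        )
        res.check_conservation()
        # reconciled leaf copies equal observed gene counts
        observed = truth.leaf_counts()
        for leaf in dated_tree10.leaves():
            assert res.exiting[leaf.id] == observed.get(leaf.label, 0)


class TestOracleEquivalence:
    """reconcile_dl's cost equals the brute-force minimum over all
    ancestor-consistent maps (subset here; full sweep in acceptance)."""

    @pytest.mark.parametrize("k", [2, 3])
    def test_exhaustive_small_gene_trees(self, species4, k):
        for shape in all_rooted_shapes(k):
            for genomes in itertools.product("ABCD", repeat=k):
                labels = [f"{g.lower()}{i}" for i, g in enumerate(genomes)]
                gene = gene_tree_from_shape(shape, labels)
                lm = {lab: lab[0].upper() for lab in labels}
                res = reconcile_dl(gene, species4, lm)
                assert res.cost == reconcile_bruteforce_min_cost(gene, species4, lm)


class TestRooting:
    def test_unrooted_congruent_tree_recovers_zero_cost(self, species3):
        lm = {"a1": "A", "b1": "B", "c1": "C"}
        gene = parse_newick("(a1,(b1,c1));")  # mis-rooted congruent tree
        rooted = root_min_dl(gene, species3, lm)
        assert reconcile_dl(rooted, species3, lm).cost == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_rooting_minimum(self, dated_tree10, seed):
        truth = sim_gene_family(dated_tree10, 0.004, 0.003, seed=seed)
        gene = truth.gene_tree
        if gene.n_leaves() < 3:
            pytest.skip("too few surviving copies to reroot")
        lm = leafmap_from_prefix(gene)
        rooted = root_min_dl(gene, dated_tree10, lm)
        best = reconcile_dl(rooted, dated_tree10, lm).cost
        # enumerate every rooting by hand
        universe = gene.leaf_labels
        sets = gene.leaf_sets()
        costs = []
        seen = set()
        for node in gene.postorder():
            if node.parent is None:
                continue
            side = sets[node.id]
            canon = side if min(universe) in side else universe - side
            if canon in seen:
                continue
            seen.add(canon)
            r = gene.rerooted_on_edge(side)
            costs.append(reconcile_dl(r, dated_tree10, lm).cost)
        assert best == min(costs)

    def test_deterministic_across_calls(self, dated_tree10):
        truth = sim_gene_family(dated_tree10, 0.004, 0.002, seed=12)
        lm = leafmap_from_prefix(truth.gene_tree)
        a = root_min_dl(truth.gene_tree, dated_tree10, lm).write_newick(include=())
        b = root_min_dl(truth.gene_tree, dated_tree10, lm).write_newick(include=())
        assert a == b


class TestRearrangeWeak:
    lm = {"a": "A", "b": "B", "c": "C"}

    def test_weak_edge_rearranged_to_congruence(self, species3):
        gene = parse_newick("((a:1,c:1)50:1,b:1);")
        out, res = rearrange_weak(gene, species3, self.lm, 70)
        assert res.cost == 0
        assert out.clade_set() == frozenset({frozenset({"a", "b"})})

    def test_strong_supports_leave_tree_unchanged(self, species3):
        gene = parse_newick("((a:1,c:1)95:1,b:1);")
        out, res = rearrange_weak(gene, species3, self.lm, 70)
        assert out.clade_set() == gene.clade_set()
        assert res.cost == reconcile_dl(gene, species3, self.lm).cost

    def test_threshold_zero_is_identity(self, species3):
        gene = parse_newick("((a:1,c:1)50:1,b:1);")
        out, _ = rearrange_weak(gene, species3, self.lm, 0)
        assert out.clade_set() == gene.clade_set()

    def test_threshold_outside_range_rejected(self, species3):
        with pytest.raises(ReconcileError):
            rearrange_weak(parse_newick("((a,c),b);"), species3, self.lm, 150)

    @pytest.mark.parametrize("seed", range(8))
    def test_never_increases_cost(self, dated_tree10, seed):
        truth = sim_gene_family(dated_tree10, 0.004, 0.003, seed=seed + 200)
        gene = truth.gene_tree.copy()
        rng = np.random.default_rng(seed)
        for node in gene.internal_nodes(include_root=False):
            node.support = float(rng.uniform(20, 100))
        lm = leafmap_from_prefix(gene)
        before = reconcile_dl(gene, dated_tree10, lm).cost
        _, res = rearrange_weak(gene, dated_tree10, lm, 70)
        assert res.cost <= before


class TestEndToEndRecovery:
    def test_mean_branch_duplications_track_simulated_truth(self, dated_tree10):
        """Over 200 simulated families, the mean reconciled duplication
        count per internal branch is a slight underestimate of the
        simulated truth (losses hide duplications): bounded above by
        truth + 3 Monte-Carlo SE, and correlated >= 0.8 across branches."""
        n_fam = 200
        branch_ids = [
            n.id for n in dated_tree10.postorder() if not n.is_leaf()
        ]
        true_sum = {b: 0.0 for b in branch_ids}
        true_sq = {b: 0.0 for b in branch_ids}
        rec_sum = {b: 0.0 for b in branch_ids}
        for seed in range(n_fam):
            truth = sim_gene_family(dated_tree10, 0.002, 0.002, seed=seed + 900)
            res = reconcile_dl(
                truth.gene_tree, dated_tree10, leafmap_from_prefix(truth.gene_tree)
            )
            for b in branch_ids:
                true_sum[b] += truth.duplications[b]
                true_sq[b] += truth.duplications[b] ** 2
                rec_sum[b] += res.duplications[b]
        true_mean, rec_mean = [], []
        for b in branch_ids:
            tm = true_sum[b] / n_fam
            rm = rec_sum[b] / n_fam
            var = true_sq[b] / n_fam - tm * tm
            se = (var / n_fam) ** 0.5
            assert rm <= tm + 3 * se + 1e-9
            true_mean.append(tm)
            rec_mean.append(rm)
        corr = np.corrcoef(true_mean, rec_mean)[0, 1]
        assert corr >= 0.8


class TestCopyNumbersAndAveraging:
    def test_ancestral_copy_numbers_additive_across_families(self, dated_tree10):
        results = []
        for seed in (7, 8):
            truth = sim_gene_family(dated_tree10, 0.004, 0.002, seed=seed)
            results.append(
                reconcile_dl(
                    truth.gene_tree, dated_tree10, leafmap_from_prefix(truth.gene_tree)
                )
            )
        merged = {
            nid: sum(r.exiting[nid] for r in results)
            for nid in results[0].exiting
        }
        for r in results:
            counts = ancestral_copy_numbers(r)
            assert all(counts[n] == r.exiting[n] for n in counts)
        total = ancestral_copy_numbers(results[0])
        assert all(
            merged[n] == total[n] + results[1].exiting[n] for n in merged
        )

    def test_unknown_node_rejected(self, species3):
        res = reconcile_dl(
            parse_newick("((a1,b1),c1);"), species3, {"a1": "A", "b1": "B", "c1": "C"}
        )
        with pytest.raises(ReconcileError):
            ancestral_copy_numbers(res, [999])

    def test_identical_replicates_average_to_single_result(self, species3):
        gene = parse_newick("((a1,b1),(a2,c1));")
        lm = {"a1": "A", "b1": "B", "a2": "A", "c1": "C"}
        single = reconcile_dl(gene, species3, lm)
        avg = bootstrap_average([gene.copy() for _ in range(5)], species3, lm)
        assert avg.n_replicates == 5
        for nid in single.duplications:
            assert avg.mean_duplications[nid] == single.duplications[nid]
            assert avg.mean_copy_numbers[nid] == single.exiting[nid]

    def test_mean_is_arithmetic(self, species3):
        lm = {"a1": "A", "b1": "B", "a2": "A", "a3": "A", "c1": "C"}
        t1 = parse_newick("((a1,b1),(a2,c1));")  # 1 duplication
        t2 = parse_newick("(((a1,a2),(a3,b1)),c1);")  # more duplications
        r1 = reconcile_dl(t1, species3, {k: lm[k] for k in ["a1", "b1", "a2", "c1"]})
        with pytest.raises(ReconcileError):
            bootstrap_average([t1, t2], species3, lm)  # mismatched leaf sets

    def test_bootstrap_vs_rearranged_liberal_conservative(self, dated_tree10):
        """Averaging noisy replicates yields duplication totals at least as
        large on average as reconciling the rearranged tree (the liberal
        vs conservative contrast)."""
        rng = np.random.default_rng(5)
        lib, cons = [], []
        for seed in range(6):
            truth = sim_gene_family(dated_tree10, 0.004, 0.002, seed=seed + 30)
            gene = truth.gene_tree
            if gene.n_leaves() < 4:
                continue
            lm = leafmap_from_prefix(gene)
            # noisy replicates: random NNI-ish perturbations via re-rooting
            reps = []
            sets = gene.leaf_sets()
            sides = [
                sets[n.id]
                for n in gene.postorder()
                if n.parent is not None and 1 < len(sets[n.id]) < gene.n_leaves()
            ]
            for k in range(8):
                side = sides[int(rng.integers(len(sides)))]
                reps.append(gene.rerooted_on_edge(side))
            avg = bootstrap_average(reps, dated_tree10, lm)
            for node in gene.internal_nodes(include_root=False):
                node.support = 100.0
            _, rearranged = rearrange_weak(gene, dated_tree10, lm, 70)
            lib.append(sum(avg.mean_duplications.values()))
            cons.append(rearranged.n_duplications)
        assert sum(lib) >= sum(cons)
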