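"""Likelihood engine against a brute-force oracle; quartet ML; FcLM
regions; RADICAL bookkeeping and fixation points."""

import math

import numpy as np
import pytest

from _oracles import loglik_bruteforce
from paleozyme.phylosignal import (
    PhyloSignalError,
    RadicalCurves,
    RadicalReplicate,
    classify_simplex_point,
    fclm,
    fixation_points,
    nj_tree,
    optimize_quartet,
    poisson_model,
    quartet_topologies,
    radical,
    tree_loglik,
)
from paleozyme.synthetic_data import sim_alignment, sim_species_tree
from paleozyme.treecore import Alignment, parse_newick


class TestTreeLoglik:
    def test_identical_single_site_at_zero_distance(self, aa_model):
        tree = parse_newick("(A:0,B:0);")
        aln = Alignment({"A": "M", "B": "M"})
        assert tree_loglik(tree, aln, aa_model) == pytest.approx(math.log(1 / 20))

    def test_two_taxon_closed_form(self, aa_model):
        t = 0.8
        tree = parse_newick(f"(A:{t / 2},B:{t / 2});")
        aln = Alignment({"A": "A", "B": "R"})
        p_diff = (19 / 20) * (1 - math.exp(-(20 / 19) * t))
        expect = math.log((1 / 20) * (p_diff / 19))
        assert tree_loglik(tree, aln, aa_model) == pytest.approx(expect)

    def test_relabeling_invariance(self, aa_model_gamma):
        tree = parse_newick("((A:0.1,B:0.2):0.05,C:0.3);")
        aln = Alignment({"A": "MKL", "B": "MRL", "C": "QKL"})
        ll = tree_loglik(tree, aln, aa_model_gamma)
        swapped_tree = parse_newick("((C:0.1,B:0.2):0.05,A:0.3);")
        swapped_aln = Alignment({"C": "MKL", "B": "MRL", "A": "QKL"})
        assert tree_loglik(swapped_tree, swapped_aln, aa_model_gamma) == pytest.approx(ll)

    def test_empty_alignment_rejected(self, aa_model):
        tree = parse_newick("(A:0.1,B:0.1);")
        with pytest.raises(Exception):
            tree_loglik(tree, Alignment({"A": "", "B": ""}), aa_model)

    @pytest.mark.parametrize("seed", range(6))
    def test_pruning_matches_explicit_state_sum(self, seed):
        """<=5-leaf, <=3-site instances agree with the brute-force oracle
        (explicit sum over internal-state assignments) to 1e-8."""
        rng = np.random.default_rng(seed)
        n_leaves = int(rng.integers(2, 6))
        model = poisson_model(
            4 if seed % 2 else 6,
            alpha=0.7 if seed % 3 == 0 else None,
            n_categories=3,
        )
        tree = sim_species_tree(n_leaves, 1.0, 1.0, seed=seed) if n_leaves > 2 \
            else parse_newick("(t01:0.3,t02:0.4);")
        for node in tree.postorder():
            if node.parent is not None:
                node.length = float(rng.uniform(0.01, 0.8))
        aln = sim_alignment(tree, int(rng.integers(1, 4)), model, seed=seed + 100)
        got = tree_loglik(tree, aln, model)
        want = loglik_bruteforce(tree, aln, model)
        assert got == pytest.approx(want, abs=1e-8)

    def test_missing_data_matches_oracle(self, aa_model):
        tree = parse_newick("((A:0.2,B:0.3):0.1,C:0.4);")
        aln = Alignment({"A": "M-", "B": "?K", "C": "MK"})
        got = tree_loglik(tree, aln, aa_model)
        want = loglik_bruteforce(tree, aln, aa_model)
        assert got == pytest.approx(want, abs=1e-8)


def test_paml_matrix_loader_roundtrip(tmp_path):
    """A PAML-format exchangeability file (lower triangle + frequencies)
    loads into a valid reversible model."""
    import numpy as np

    from paleozyme.phylosignal import SubstModel, model_from_paml

    rng = np.random.default_rng(0)
    tri = rng.uniform(0.1, 2.0, size=190)
    freqs = rng.dirichlet(np.ones(20))
    lines = []
    k = 0
    for i in range(1, 20):
        row = tri[k : k + i]
        k += i
        lines.append(" ".join(f"{v:.6f}" for v in row))
    lines.append("")
    lines.append(" ".join(f"{v:.8f}" for v in freqs))
    path = tmp_path / "custom.dat"
    path.write_text("\n".join(lines) + "\n")
    model = model_from_paml(path, alpha=0.5)
    assert isinstance(model, SubstModel)
    assert model.frequencies == pytest.approx(freqs, abs=1e-6)
    P = model.transition_matrix(0.3)
    assert P.sum(axis=1) == pytest.approx(np.ones(20))
    # detailed balance: pi_i P_ij = pi_j P_ji for a reversible model
    flux = model.frequencies[:, None] * P
    assert np.allclose(flux, flux.T, atol=1e-10)


class TestQuartetML:
    def test_identical_sequences_tie_all_topologies(self, aa_model):
        aln = Alignment({t: "MKLV" * 5 for t in "ABCD"})
        fits = [
            optimize_quartet(aln, topo, aa_model)
            for topo in quartet_topologies("A", "B", "C", "D")
        ]
        lls = [f.loglik for f in fits]
        assert max(lls) - min(lls) < 1e-6

    def test_generating_topology_wins_on_long_alignment(self, aa_model):
        tree = parse_newick(
            "((A:0.15,B:0.15):0.15,(C:0.15,D:0.15):0.15);"
        )
        aln = sim_alignment(tree, 5000, aa_model, seed=1)
        fits = [
            optimize_quartet(aln, topo, aa_model)
            for topo in quartet_topologies("A", "B", "C", "D")
        ]
        assert fits[0].loglik > fits[1].loglik
        assert fits[0].loglik > fits[2].loglik

    def test_ascent_from_start(self, aa_model):
        tree = parse_newick("((A:0.1,B:0.3):0.1,(C:0.2,D:0.1):0.1);")
        aln = sim_alignment(tree, 300, aa_model, seed=3)
        topo = quartet_topologies("A", "B", "C", "D")[0]
        from paleozyme.phylosignal import _QuartetEngine

        start_ll = _QuartetEngine(aln, aa_model).loglik(topo, np.full(5, 0.1))
        fit = optimize_quartet(aln, topo, aa_model)
        assert fit.loglik >= start_ll - 1e-9
        assert fit.converged


class TestSimplexRegions:
    @pytest.mark.parametrize(
        "p,region",
        [
            ((0.8, 0.1, 0.1), "t1"),
            ((0.2, 0.6, 0.2), "t2"),
            ((0.4, 0.38, 0.22), "e12"),
            ((0.34, 0.33, 0.33), "center"),
            ((0.5, 0.25, 0.25), "center"),  # boundary tie -> less resolved
        ],
    )
    def test_region_assignment(self, p, region):
        assert classify_simplex_point(p) == region

    def test_every_simplex_point_gets_exactly_one_region(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            p = rng.dirichlet([1, 1, 1])
            assert classify_simplex_point(p) in {
                "t1", "t2", "t3", "e12", "e13", "e23", "center"
            }


class TestFcLM:
    def test_single_combination_exhaustive(self, aa_model):
        tree = parse_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        aln = sim_alignment(tree, 200, aa_model, seed=0)
        report = fclm(aln, [["A"], ["B"], ["C"], ["D"]], 50, aa_model, seed=0)
        assert report.n_quartets == 1
        assert sum(report.region_fractions.values()) == pytest.approx(1.0)

    def test_empty_cluster_rejected(self, aa_model):
        tree = parse_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        aln = sim_alignment(tree, 50, aa_model, seed=0)
        with pytest.raises(PhyloSignalError):
            fclm(aln, [["A"], [], ["C"], ["D"]], 10, aa_model)

    def test_planted_signal_beats_noise_in_center(self, aa_model):
        """Near-random 10-site data lands in the centre more often than
        strongly structured data does (monotonicity of resolution)."""
        tree = parse_newick(
            "((A:0.1,B:0.1):0.5,(C:0.1,D:0.1):0.5);"
        )
        strong = sim_alignment(tree, 2000, aa_model, seed=2)
        weak_tree = parse_newick("((A:0.5,B:0.5):0.001,(C:0.5,D:0.5):0.001);")
        weak = sim_alignment(weak_tree, 10, aa_model, seed=3)
        clusters = [["A"], ["B"], ["C"], ["D"]]
        strong_report = fclm(strong, clusters, 1, aa_model, seed=0)
        weak_report = fclm(weak, clusters, 1, aa_model, seed=0)
        assert (
            weak_report.region_fractions["center"]
            >= strong_report.region_fractions["center"]
        )
        assert strong_report.region_fractions["t1"] == pytest.approx(1.0)

    def test_vertex_fraction_monotone_in_internal_branch(self, aa_model):
        """Support for the generating topology does not decrease as the
        internal branch grows (3-point check)."""
        fractions = []
        for internal in (0.01, 0.1, 0.5):
            tree = parse_newick(
                f"((A:0.2,B:0.2):{internal / 2},(C:0.2,D:0.2):{internal / 2});"
            )
            aln = sim_alignment(tree, 1500, aa_model, seed=8)
            rep = fclm(aln, [["A"], ["B"], ["C"], ["D"]], 1, aa_model, seed=0)
            fractions.append(rep.region_fractions["t1"])
        assert fractions == sorted(fractions)


def _toy_genes(seed=0, n_genes=6, n_sites=150):
    tree = sim_species_tree(6, 1.0, 1.0, seed=4)
    for node in tree.postorder():
        if node.parent is not None:
            node.length = node.length * 0.35  # moderate divergence
    model = poisson_model(20)
    return tree, [
        (f"gene{k:02d}", sim_alignment(tree, n_sites, model, seed=seed + k))
        for k in range(n_genes)
    ]


class TestRadical:
    def test_bookkeeping_counts(self):
        _, genes = _toy_genes(n_genes=3)
        curves = radical(genes[:3], n_replicates=2, step=1, seed=0)
        assert curves.step_sizes == [1, 2, 3]
        assert len(curves.replicates) == 2
        assert all(len(r.clades) == 3 for r in curves.replicates)

    def test_fixed_seed_reproduces_gene_orders(self):
        _, genes = _toy_genes()
        a = radical(genes, n_replicates=3, step=2, seed=9)
        b = radical(genes, n_replicates=3, step=2, seed=9)
        assert [r.order for r in a.replicates] == [r.order for r in b.replicates]

    def test_full_concatenation_recovers_generating_clades(self):
        tree, genes = _toy_genes(n_genes=8, n_sites=400)
        curves = radical(genes, n_replicates=2, step=4, seed=1)
        from paleozyme.treecore import nontrivial_splits

        want = nontrivial_splits(tree.clade_set(), tree.leaf_labels)
        for rep in curves.replicates:
            assert want <= rep.clades[curves.step_sizes[-1]]

    def test_estimator_failure_aborts_replicate(self):
        _, genes = _toy_genes(n_genes=3)
        calls = {"n": 0}

        def flaky(aln):
            calls["n"] += 1
            if calls["n"] == 2:
                raise RuntimeError("boom")
            return nj_tree(aln)

        curves = radical(genes[:3], estimator=flaky, n_replicates=2, step=1, seed=0)
        assert len(curves.failures) == 1
        assert len(curves.replicates) == 1


def _curves_fixture(presence):
    """Hand-built curves: presence[replicate][step] = set of clades."""
    steps = sorted(presence[0])
    taxa = ["A", "B", "C", "D", "E"]
    reps = [
        RadicalReplicate(order=[], clades={s: frozenset(p[s]) for s in steps})
        for p in presence
    ]
    return RadicalCurves(
        n_genes=max(steps), step_sizes=steps, taxa=taxa, replicates=reps
    )


class TestFixationPoints:
    clade = frozenset({"A", "B"})

    def test_always_present_fixes_at_first_step(self):
        always = {s: {self.clade} for s in range(1, 11)}
        curves = _curves_fixture([always, always])
        assert fixation_points(curves, [self.clade])[self.clade] == pytest.approx(0.1)

    def test_absent_from_final_tree_is_unfixed(self):
        full = {s: {self.clade} for s in range(1, 11)}
        missing_final = dict(full)
        missing_final[10] = set()
        curves = _curves_fixture([full, missing_final])
        assert fixation_points(curves, [self.clade])[self.clade] == "unfixed"

    def test_stabilisation_at_step_8_of_10(self):
        """Clade flickers through step 7, stable from step 8 -> 0.8."""
        flicker = {
            s: ({self.clade} if (s >= 8 or s % 2 == 0) else set())
            for s in range(1, 11)
        }
        stable = {s: {self.clade} for s in range(1, 11)}
        curves = _curves_fixture([flicker, stable])
        assert fixation_points(curves, [self.clade])[self.clade] == pytest.approx(0.8)

    def test_noisier_estimator_cannot_fix_earlier(self):
        """Fixation is non-increasing as estimator accuracy improves."""
        perfect = {s: {self.clade} for s in range(1, 6)}
        noisy = {s: ({self.clade} if s >= 3 else set()) for s in range(1, 6)}
        f_perfect = fixation_points(
            _curves_fixture([perfect]), [self.clade]
        )[self.clade]
        f_noisy = fixation_points(_curves_fixture([noisy]), [self.clade])[self.clade]
        assert f_perfect <= f_noisy
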