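# paleozyme

Tools for asking *when* a gene family expanded on an organismal timescale:
gene-tree/species-tree reconciliation under duplication–loss parsimony,
ancestral copy-number reconstruction, per-gene phylogenetic-signal
diagnostics, and penalized-likelihood divergence-time estimation — the
inference chain used to place enzyme-family expansions (here, fungal
pectinases: the GH, PL and CE carbohydrate-active enzyme families that
degrade the streptophyte cell-wall polysaccharide pectin) onto a dated
species phylogeny.

The package is aimed at molecular evolution researchers who want each
stage as a tested, scriptable unit rather than a chain of one-off tool
invocations, and who want to validate the whole chain on simulated data
with known truth before trusting it on real genomes.

## What it computes

* **Ortholog filtering / supermatrix** (`ortholog_matrix`): single-copy
  clusters (one protein per genome, ≥50% genome occupancy, redundancy
  removal), reciprocal-best-hit vetting, concatenation with partitions
  and per-taxon occupancy, Dayhoff six-group recoding.
* **Signal diagnostics** (`phylosignal`): Felsenstein pruning likelihood
  with discrete-gamma rates; four-cluster likelihood mapping (FcLM) —
  per-quartet posterior weights p_i ∝ exp(ℓ_i − max ℓ) binned into seven
  simplex regions; random-addition concatenation (RADICAL) with per-clade
  fixation points.
* **Reconciliation** (`reconcile`): LCA mapping, duplication and loss
  counts per species branch (unit costs), parsimony rooting, rearrangement
  of weakly supported edges (<70% by default), bootstrap averaging, and
  ancestral copy numbers obeying `exiting = entering + dup − loss` on
  every branch.
* **Dating** (`chronos`): penalized likelihood
  `Σ_e [x_e log μ_e − μ_e] − λ·Σ (r_e − r_parent(e))²` with μ_e = r_e t_e,
  fixed/min/max clade calibrations honoured by construction, and the
  smoothing parameter λ chosen by leave-one-terminal-out cross-validation.
* **Enzyme survey** (`cazy_survey`): e-value (≤1e-5) and functional-domain
  filtering of homology hits into genome × family copy-number matrices,
  with the 20-family pectinase catalog (nine pectin-specific) as package
  data.
* **Synthetic data** (`synthetic_data`): dated Yule species trees,
  birth–death gene families with a true event ledger, gamma-heterogeneous
  sequence simulation, uncorrelated-lognormal relaxed clocks, and cluster/
  hit tables with planted filter violations.

A `paleozyme` command-line interface wraps each stage
(`simulate`, `orthofilter`, `concat`, `recode`, `fclm`, `radical`,
`reconcile`, `date`, `survey`, `report`) and `paleozyme run config.yaml`
executes the synthetic end-to-end pipeline with a content-hash manifest.

## Worked example

Simulate a dated 8-taxon species tree, evolve a pectinase-like family
along it, reconcile, and date the tree from a relaxed-clock phylogram:

```python
from paleozyme import synthetic_data as sd
from paleozyme.reconcile import reconcile_dl, leafmap_from_prefix
from paleozyme.chronos import Calibration, fit_chronogram

species = sd.sim_species_tree(n_taxa=8, birth_rate=1.0, root_age=800.0, seed=42)
fam = sd.sim_gene_family(species, dup_rate=0.003, loss_rate=0.002,
                         seed=7, family_id="GH28")
res = reconcile_dl(fam.gene_tree, species, leafmap_from_prefix(fam.gene_tree))
print("true events:    D=%d L=%d" % (sum(fam.duplications.values()),
                                     sum(fam.losses.values())))
print("reconciled:     D=%d L=%d" % (res.n_duplications, res.n_losses))
print(res.branch_table().to_string(index=False))

phylo = sd.sim_relaxed_phylogram(species, mean_rate=0.001, sigma=0.2, seed=3)
fit = fit_chronogram(phylo.tree,
                     [Calibration(clade="root", kind="fixed", age=800.0)],
                     lam=3.2)
clade = max((c for c in fit.ages if 1 < len(c) < 8), key=lambda c: fit.ages[c])
print("estimated age: %.1f Ma   true age: %.1f Ma"
      % (fit.ages[clade], phylo.true_ages[clade]))
```

Output:

```
true events:    D=18 L=7
reconciled:     D=13 L=2
                          clade  terminal  virtual_root  duplications  losses  entering  exiting
                        t01|t02     False         False             0       1         1        0
                        t03|t04     False         False             1       0         2        3
                        t05|t06     False         False             0       0         6        6
                    t05|t06|t07     False         False             0       0         6        6
                t05|t06|t07|t08     False         False             4       0         2        6
        t03|t04|t05|t06|t07|t08     False         False             1       0         1        2
t01|t02|t03|t04|t05|t06|t07|t08     False          True             0       0         1        1
estimated age: 462.0 Ma   true age: 448.3 Ma
```

Reading it: the family expanded mostly on the branch into the
`t05…t08` ancestor (4 duplications; copies rise from 2 to 6) and was lost
entirely in the `t01|t02` clade.  The reconciled totals (D=13, L=2) sit
below the simulated truth (D=18, L=7) because a duplication whose
descendants all died leaves no trace — reconciliation is a conservative
(lower-bound) estimator of event counts.  The final two lines show the
penalized-likelihood age estimate for the deepest internal node against
the (hidden) simulated truth, with only the root age calibrated.

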