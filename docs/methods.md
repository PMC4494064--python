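# Methods

`paleozyme` re-implements, as a tested library, the inference chain that
connects enzyme gene families to an organismal phylogeny: ortholog
filtering and supermatrix construction, per-gene phylogenetic-signal
diagnostics, duplication–loss reconciliation with ancestral copy-number
reconstruction, and penalized-likelihood dating under a fixed-age
calibration.  Every stage can be exercised end-to-end on synthetic data
with recorded truth; this note documents the models, the conventions and
the numerical choices.

## Synthetic data model

The generators are pure functions of their parameters and a seed.

**Species trees** are Yule (pure-birth) trees rescaled to a chosen root age
(Ma); leaves have age 0.  Defaults in the pipeline and studies: 10–12 taxa,
root ages 750–887 Ma, matching the depth of the fungal divergences the
method targets.

**Gene families** evolve along the dated species tree by a Gillespie
birth–death process with per-lineage, per-Ma duplication and loss rates,
starting from one ancestral copy at the species root.  Each surviving
lineage speciates at every internal species node.  The default rates
(0.002/0.002 per lineage per Ma) produce mostly small families with
occasional expansions over an 800 Ma tree — the qualitative regime of the
pectinase families surveyed in the source study (a handful of copies per
genome, ancestral copy numbers of order 1–10).  The truth ledger records,
per species branch, the entering and exiting copy counts and the event
counts; families that go globally extinct are resampled (capped at 10,000
attempts).  What pruning removes — duplication followed by total loss —
is invisible to any reconciliation method, so reconciled duplication
counts are a slight underestimate of the ledger; the recovery test asserts
exactly this one-sided relationship.

**Alignments** are simulated root-to-tips under a reversible substitution
model (Poisson/equal-rates by default; arbitrary symmetric
exchangeabilities with stationary frequencies supported) with discrete
gamma rate heterogeneity (mean-per-quantile categories).  No indels are
simulated; gaps only enter supermatrices as missing-taxon fill.

**Relaxed-clock phylograms** draw i.i.d. lognormal branch rates
(uncorrelated clock): arithmetic mean `mean_rate`, log-scale standard
deviation σ; branch length = rate × duration, optionally
Poisson-perturbed at a finite site count.  σ = 0.2 is the default study
condition for dating recovery; 0.001 subs/site/Ma puts tree height near
0.9 expected substitutions, a realistic depth for conserved proteins.

**Cluster and hit tables** carry planted defects with known labels:
paralogous clusters, occupancy dropouts (fewer than half the genomes), and
redirected best hits for the RBH filter; hit tables mix true hits
(e-value ≤ 1e-5, functional domain present) with decoys that violate at
least one of the two filters.  Because the defects are separable by
construction, filter recovery must be exact; real BLAST output is messier
(borderline e-values, partial domains), so exact recovery here validates
the filter logic, not its real-data error rate.

## Ortholog filtering and the supermatrix

A cluster is kept when it has at most one protein per genome and covers at
least 50% of the genomes (inclusive threshold), duplicate-membership
clusters are collapsed, and every member must be the unique reciprocal
best hit of its partners within the cluster (a tied best score with an
outside protein rejects the cluster; a missing comparison marks it
unevaluable rather than silently keeping it).  The protein→genome map used
by the RBH test is taken from the *unfiltered* cluster table: a best hit
may point into a cluster that earlier filters removed.  Concatenation
sorts genes by name, fills missing taxa with `?` (distinct from the
alignment gap `-`), tracks 0-based half-open partitions, and reports
per-taxon occupancy.  Dayhoff recoding collapses the 20 amino acids into
the six classical exchange groups {AGPST}, {DENQ}, {HKR}, {ILMV}, {FWY},
{C} (digits 0–5); ambiguity codes map to missing.

## Likelihood engine and signal diagnostics

`tree_loglik` is Felsenstein pruning over column-compressed site patterns
with per-node scaling, k discrete gamma categories, and transition
matrices from the symmetric eigendecomposition of the scaled rate matrix
(mean rate 1 at stationarity).  It is verified against explicit summation
over all internal-state assignments on small instances (agreement to
1e-8).

**FcLM.**  For each sampled quartet (one taxon per cluster, without
replacement; the whole combination space when small) the three resolutions
are optimised by cyclic Brent line search over the five branch lengths
(deterministic start 0.1, improvement tolerance 1e-6, at most 100 cycles,
non-convergence flagged).  Log-likelihoods map to a simplex point
p_i ∝ exp(ℓ_i − max ℓ).  The seven support regions are a documented
convention (the source analyses do not define them): vertex i when
p_i > 1/2; edge ij when p_i ≤ 1/2, p_j ≤ 1/2 and the remaining weight is
≤ 1/4; centre otherwise, with boundary ties resolved toward the centre.

**RADICAL.**  Genes are concatenated in random orders; a tree is estimated
at each prefix size (step, 2·step, …, G).  The default estimator is
neighbour joining on Poisson-corrected ML distances — deliberately cheap,
since fixation logic is estimator-agnostic and the interface accepts any
`alignment → Tree` callable.  A clade's fixation point is the smallest
step size from which it appears in every estimated tree at every larger
size in every replicate, reported as a fraction of G; absence from any
final-step tree means "unfixed".  Clades are compared as unrooted splits
(canonicalised to the side containing the alphabetically smallest taxon).

## Reconciliation conventions

Reconciliation is duplication–loss parsimony with unit costs via the LCA
map.  A gene node is a duplication when it maps to the same species node
as one of its children; losses are the species edges skipped along each
gene edge (one fewer below a speciation).  Two conventions matter:

* **Single origin at the species root.**  One copy enters a virtual branch
  above the species root; losses are also charged along the path from the
  root to the gene root's image.  This makes the conservation law
  `exiting = entering + duplications − losses` hold on *every* branch and
  gives the virtual root branch the "copies in the ancestor of all taxa"
  semantics needed for ancestral copy-number tables.  Exhaustive
  enumeration over all ancestor-consistent maps confirms the LCA map still
  attains the minimum total cost under this convention.
* **Terminal branches.**  Within-species duplications and losses are
  tallied like any others (the conservation law needs them) but flagged,
  and default reports exclude them.

Unrooted gene trees are rooted on the edge minimising total cost (ties:
fewer duplications, then lexicographically smallest induced bipartition).
Weak-branch rearrangement collapses internal edges with support below the
threshold (default 70 on a 0–100 scale) and re-resolves each polytomy to
minimise whole-tree cost — exhaustively up to 7 child subtrees ((2k−3)!!
resolutions), by greedy best-pair joining above that (flagged heuristic).
A final guard returns the input tree if rearrangement ever costs more, so
the rearranged cost never exceeds the input cost.  Bootstrap averaging
reconciles each replicate tree independently (optionally after
rearrangement) and reports arithmetic means of per-branch duplication
counts and exiting copy numbers — the liberal counterpart to the
conservative rearranged estimate.  Means are presentation-rounded (copy
numbers to one decimal, duplication means to two) only at the report
layer.

## Penalized-likelihood dating

The objective is the continuous-Poisson branch-length likelihood
Σ_e [x_e log μ_e − μ_e − log Γ(x_e+1)] with μ_e = rate_e × duration_e
(x_e = branch length × sites; sites defaults to 1, so x is treated as a
continuous intensity), minus λ times a roughness penalty: squared rate
differences across parent–child branch pairs plus the variance of the
root-children rates.  The penalty acts on raw rates (the classical
additive form); a log-rate option exists.

Ages are parameterised as relative positions inside the interval imposed
by the parent's age and the calibrations, so order constraints and fixed
ages hold by construction; rates are optimised in log space.  Optimisation
is L-BFGS-B with analytic gradients (the age gradient is back-propagated
through the nested interval parameterisation), 5 seeded restarts, and
deliberately strict stopping tolerances — the surface is extremely flat at
small λ, where the per-branch rate/duration product is nearly
unidentifiable.  A fixed or maximum calibration on the root clade is
required; an infeasible calibration set (a minimum above a maximum on one
root-to-tip path) is rejected before optimisation.

**Smoothing selection.**  Leave-one-terminal-out cross-validation removes
one pendant branch from the likelihood and penalty (the attachment node
stays and its age is refitted), predicts the held-out branch's expected
substitutions as x̂ = (fitted rate of the branch entering the attachment
node) × (fitted attachment age), and scores (x − x̂)²/max(x̂, 1e-6).  The
smallest λ attaining the minimal summed score is selected.  Leaves
attached directly to the root are skipped.  CV refits use faster optimiser
settings (`cv_fit_options`: single start, looser ftol) since the score
only needs ~1% accuracy.

**Scale of λ.**  Because the additive penalty compares rates on their
natural scale, its informative range depends on the rate magnitude: for
per-Ma rates of order 1e-3, squared rate differences are ~1e-8 and the
penalty only competes with the likelihood for λ well above 1e3.  The
default cross-validation grid therefore spans 1e-3…1e7 by decades.  The
single-rate (Langley–Fitch) limit at λ → ∞ is checked on a unit-height
tree where rates are O(1) and λ = 1e6 is far into the clock regime.

## Enzyme survey

Hits are screened at an inclusive e-value cutoff (default 1e-5) and,
optionally, for the predicted functional domain; duplicates collapse to
the best e-value.  Copy numbers are counts of distinct surviving proteins
per (genome, family); genomes without hits get explicit zero rows.  A
protein assigned to several families counts once per family and is listed
in a multi-assignment report.  The shipped catalog holds the 20 surveyed
families (GH/PL/CE classes) with nine flagged pectin-specific: GH28,
GH53, GH93, PL1, PL3, PL4, PL11, CE8, CE13.

## Pipeline and reproducibility

`run_pipeline` derives every stage seed from one master seed via named
substreams, writes each artifact with a SHA-256 manifest, and is
bit-identical under a fixed configuration.  The branch report joins, per
species branch, the chronogram's age interval with per-family duplication,
loss and copy-number columns and a compact `GH28:D3`-style annotation
(terminal branches carry counts but no annotation).  The synthetic
pipeline exercises the rearranged-reconciliation path; bootstrap averaging
is reachable through the library and the `reconcile --mode bootstrap`
command on multi-tree Newick input.

## Problem sizes in the shipped studies

The verification studies use sizes chosen to make their statistical
assertions sharp yet cheap: exhaustive reconciliation oracle sweeps over
all ≤4-leaf gene trees on 3–4 taxon species trees plus sampled 5–6 leaf
cases (~1.5k instances); 1,000 simulated families for the conservation
law; 50 replicates of 12-taxon σ=0.2 dating recovery; 16 exhaustive
quartets at 5,000 sites for likelihood mapping; 500 planted cluster cases
for filter recovery.

## Known limitations

* Tree estimation is a pluggable interface; no full ML or Bayesian search
  is included, and the default NJ estimator understates what a full ML
  RADICAL run would fix earlier.
* The sequence simulator has no indels, no codon structure and no
  domain-level realism; filter-recovery results certify logic, not
  real-data error rates.
* Reconciliation assumes a binary species tree and ignores horizontal
  transfer; the loss-attribution convention is self-consistent but other
  tools may report per-branch losses differently.
* The greedy resolution of polytomies with more than 7 children is a
  heuristic (flagged on the result).
* Dating assumes the topology is correct and fixed; only node ages and
  rates are estimated.
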