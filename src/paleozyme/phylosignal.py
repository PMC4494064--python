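"""Per-gene phylogenetic-signal diagnostics.

Two instruments are provided on top of a Felsenstein pruning likelihood
engine with discrete-gamma rate heterogeneity:

* **four-cluster likelihood mapping (FcLM)** -- for quartets drawn with one
  taxon from each of four disjoint clusters, the maximum log-likelihoods of
  the three resolved quartet topologies are normalised to a point in the
  2-simplex and binned into seven support regions (three vertex, three edge,
  one centre);

* **random-addition concatenation (RADICAL)** -- genes are concatenated in
  random orders, a tree is estimated at each concatenation size, and each
  clade's *fixation point* is the smallest size from which the clade is
  recovered in every estimated tree at every larger size across replicates,
  reported as a fraction of the total gene count.

The default RADICAL tree estimator is neighbour joining on Poisson-corrected
maximum-likelihood distances; any ``alignment -> Tree`` callable can be
substituted.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc, logsumexp
from scipy.stats import gamma as gamma_dist

from .treecore import Alignment, Tree, canonical_split, parse_newick

#: amino-acid state order (PAML convention)
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

_MISSING_CHARS = set("-?XBZJU*.")


class PhyloSignalError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Substitution model
# ---------------------------------------------------------------------------


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of ``k`` equal-probability discrete gamma categories
    (shape ``alpha``, mean 1)."""
    if alpha <= 0:
        raise PhyloSignalError("gamma shape must be positive")
    if k < 1:
        raise PhyloSignalError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    bounds = gamma_dist.ppf(np.arange(k + 1) / k, a=alpha, scale=1.0 / alpha)
    bounds[0], bounds[-1] = 0.0, np.inf
    upper = gammainc(alpha + 1.0, alpha * bounds[1:])
    lower = gammainc(alpha + 1.0, alpha * bounds[:-1])
    rates = k * (upper - lower)
    return rates / rates.mean() * 1.0


class SubstModel:
    """Time-reversible substitution model with discrete-gamma rates.

    ``exchangeabilities=None`` gives the Poisson (equal-rates) model.  The
    rate matrix is scaled so that the expected rate at stationarity is one
    substitution per site per unit branch length.
    """

    def __init__(
        self,
        n_states: int = 20,
        exchangeabilities: np.ndarray | None = None,
        frequencies: np.ndarray | None = None,
        alpha: float | None = None,
        n_categories: int = 4,
    ):
        self.n_states = int(n_states)
        if frequencies is None:
            frequencies = np.full(self.n_states, 1.0 / self.n_states)
        frequencies = np.asarray(frequencies, dtype=float)
        if frequencies.shape != (self.n_states,) or not math.isclose(
            frequencies.sum(), 1.0, abs_tol=1e-8
        ):
            raise PhyloSignalError("frequencies must be a simplex of length n_states")
        self.frequencies = frequencies / frequencies.sum()

        if exchangeabilities is None:
            R = np.ones((self.n_states, self.n_states))
        else:
            R = np.asarray(exchangeabilities, dtype=float)
            if R.shape != (self.n_states, self.n_states) or not np.allclose(R, R.T):
                raise PhyloSignalError("exchangeability matrix must be symmetric n x n")
        np.fill_diagonal(R, 0.0)
        self.exchangeabilities = R

        Q = R * self.frequencies[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -(self.frequencies * np.diag(Q)).sum()
        if mean_rate <= 0:
            raise PhyloSignalError("degenerate rate matrix")
        Q /= mean_rate
        self.Q = Q

        # symmetric similarity transform for fast matrix exponentials
        sqrt_pi = np.sqrt(self.frequencies)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        B = (B + B.T) / 2.0
        eigval, eigvec = np.linalg.eigh(B)
        self._eigval = eigval
        self._left = eigvec / sqrt_pi[:, None] * 1.0
        self._right = (eigvec * sqrt_pi[:, None]).T

        if alpha is not None and alpha <= 0:
            raise PhyloSignalError("gamma shape must be positive")
        self.alpha = alpha
        self.n_categories = int(n_categories) if alpha is not None else 1
        self.category_rates = (
            discrete_gamma_rates(alpha, self.n_categories)
            if alpha is not None
            else np.ones(1)
        )

    # -- states --------------------------------------------------------------

    @property
    def symbols(self) -> str:
        if self.n_states == 20:
            return AA_ORDER
        return "0123456789"[: self.n_states]

    def encode(self, seq: str) -> np.ndarray:
        """Integer states; -1 for gap/missing/ambiguous symbols."""
        table = {ch: i for i, ch in enumerate(self.symbols)}
        out = np.empty(len(seq), dtype=np.int64)
        for i, ch in enumerate(seq.upper()):
            if ch in table:
                out[i] = table[ch]
            elif ch in _MISSING_CHARS:
                out[i] = -1
            else:
                raise PhyloSignalError(f"symbol {ch!r} not in model alphabet")
        return out

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt), clipped to non-negative entries."""
        if t < 0:
            raise PhyloSignalError("branch length must be non-negative")
        P = (self._left * np.exp(self._eigval * t)) @ self._right
        return np.clip(P, 0.0, None)


def poisson_model(n_states: int = 20, alpha: float | None = None, n_categories: int = 4) -> SubstModel:
    return SubstModel(n_states=n_states, alpha=alpha, n_categories=n_categories)


def load_paml_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a PAML-format empirical amino-acid matrix (lower triangle of
    exchangeabilities, then stationary frequencies)."""
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            for tok in line.split():
                try:
                    values.append(float(tok))
                except ValueError:
                    pass
    need = 190 + 20
    if len(values) < need:
        raise PhyloSignalError("PAML matrix file truncated")
    tri = values[:190]
    freqs = np.array(values[190:210])
    R = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            R[i, j] = R[j, i] = tri[k]
            k += 1
    return R, freqs / freqs.sum()


def model_from_paml(path, alpha: float | None = None, n_categories: int = 4) -> SubstModel:
    R, freqs = load_paml_matrix(path)
    return SubstModel(20, R, freqs, alpha=alpha, n_categories=n_categories)


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------


def _compress_patterns(
    alignment: Alignment, taxa: Sequence[str], model: SubstModel
) -> tuple[np.ndarray, np.ndarray]:
    """Encode and column-compress an alignment to (patterns, counts).

    ``patterns`` has shape (n_taxa, n_patterns).
    """
    if alignment.n_sites == 0:
        raise PhyloSignalError("empty alignment")
    data = np.stack([model.encode(alignment[t]) for t in taxa])
    patterns, counts = np.unique(data, axis=1, return_counts=True)
    return patterns, counts.astype(float)


def tree_loglik(tree: Tree, alignment: Alignment, model: SubstModel) -> float:
    """Summed per-site log-likelihood by Felsenstein pruning with
    discrete-gamma rate categories.

    Alignment taxa must be a subset of the tree's leaves; tree leaves without
    sequence data contribute as all-missing.
    """
    extra = set(alignment.taxa) - tree.leaf_labels
    if extra:
        raise PhyloSignalError(f"alignment taxa not in tree: {sorted(extra)}")
    leaves = [n.label for n in tree.leaves()]
    present = [t for t in leaves if t in alignment.sequences]
    if not present:
        raise PhyloSignalError("no alignment taxon matches the tree")
    patterns, counts = _compress_patterns(alignment, present, model)
    row = {t: i for i, t in enumerate(present)}
    npat = patterns.shape[1]
    n = model.n_states

    leaf_partials: dict[int, np.ndarray] = {}
    for node in tree.leaves():
        part = np.ones((npat, n))
        if node.label in row:
            states = patterns[row[node.label]]
            known = states >= 0
            part[known] = 0.0
            part[known, states[known]] = 1.0
        leaf_partials[node.id] = part

    per_cat = np.empty((model.n_categories, npat))
    for c, rate in enumerate(model.category_rates):
        partial: dict[int, np.ndarray] = {}
        scaler: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf():
                partial[node.id] = leaf_partials[node.id]
                scaler[node.id] = np.zeros(npat)
                continue
            acc = np.ones((npat, n))
            sc = np.zeros(npat)
            for child in node.children:
                t = child.length if child.length is not None else 0.0
                P = model.transition_matrix(t * rate)
                acc = acc * (partial[child.id] @ P.T)
                sc = sc + scaler[child.id]
            m = acc.max(axis=1)
            safe = m > 0
            acc[safe] /= m[safe, None]
            with np.errstate(divide="ignore"):
                sc = sc + np.where(safe, np.log(np.where(safe, m, 1.0)), -np.inf)
            partial[node.id] = acc
            scaler[node.id] = sc
        site = partial[tree.root.id] @ model.frequencies
        with np.errstate(divide="ignore"):
            per_cat[c] = np.log(site) + scaler[tree.root.id]
    site_ll = logsumexp(per_cat, axis=0) - math.log(model.n_categories)
    return float(np.dot(site_ll, counts))


# ---------------------------------------------------------------------------
# Quartet maximum likelihood
# ---------------------------------------------------------------------------


@dataclass
class QuartetFit:
    topology: tuple[tuple[str, str], tuple[str, str]]
    loglik: float
    lengths: dict[str, float]
    converged: bool


class _QuartetEngine:
    """Pattern-compressed quartet likelihood for one 4-taxon alignment.

    The likelihood is evaluated with the root placed on the internal branch
    (valid for the reversible models used here)."""

    def __init__(self, alignment: Alignment, model: SubstModel):
        if alignment.n_taxa != 4:
            raise PhyloSignalError("quartet optimisation needs exactly 4 sequences")
        self.model = model
        self.taxa = list(alignment.taxa)
        self.patterns, self.counts = _compress_patterns(alignment, self.taxa, model)
        n = model.n_states
        npat = self.patterns.shape[1]
        self.leaf_partials = {}
        for i, t in enumerate(self.taxa):
            part = np.ones((npat, n))
            states = self.patterns[i]
            known = states >= 0
            part[known] = 0.0
            part[known, states[known]] = 1.0
            self.leaf_partials[t] = part

    def loglik(
        self, topology: tuple[tuple[str, str], tuple[str, str]], lengths: np.ndarray
    ) -> float:
        (a, b), (c, d) = topology
        model = self.model
        ta, tb, tc, td, ti = lengths
        per_cat = np.empty((model.n_categories, self.patterns.shape[1]))
        for cat, rate in enumerate(model.category_rates):
            Pa = model.transition_matrix(ta * rate)
            Pb = model.transition_matrix(tb * rate)
            Pc = model.transition_matrix(tc * rate)
            Pd = model.transition_matrix(td * rate)
            Pi = model.transition_matrix(ti * rate)
            left = (self.leaf_partials[a] @ Pa.T) * (self.leaf_partials[b] @ Pb.T)
            right = (self.leaf_partials[c] @ Pc.T) * (self.leaf_partials[d] @ Pd.T)
            site = np.einsum("ps,st,pt->p", left * model.frequencies, Pi, right)
            with np.errstate(divide="ignore"):
                per_cat[cat] = np.log(site)
        site_ll = logsumexp(per_cat, axis=0) - math.log(model.n_categories)
        return float(np.dot(site_ll, self.counts))


def optimize_quartet(
    alignment: Alignment,
    topology: tuple[tuple[str, str], tuple[str, str]],
    model: SubstModel,
    tol: float = 1e-6,
    max_cycles: int = 100,
    start: float = 0.1,
    max_length: float = 20.0,
) -> QuartetFit:
    """Maximise the quartet likelihood over its five branch lengths by
    cyclic one-dimensional (Brent) optimisation from a deterministic start.

    Non-convergence after ``max_cycles`` cycles is flagged on the result, not
    raised.
    """
    engine = _QuartetEngine(alignment, model)
    names = [topology[0][0], topology[0][1], topology[1][0], topology[1][1]]
    if set(names) != set(alignment.taxa):
        raise PhyloSignalError("topology taxa do not match the alignment")
    lengths = np.full(5, start)
    current = engine.loglik(topology, lengths)
    converged = False
    for _ in range(max_cycles):
        for i in range(5):
            def neg(v: float, i=i) -> float:
                trial = lengths.copy()
                trial[i] = v
                return -engine.loglik(topology, trial)

            res = minimize_scalar(
                neg, bounds=(0.0, max_length), method="bounded",
                options={"xatol": 1e-8},
            )
            if -res.fun >= current:
                lengths[i] = float(res.x)
        new = engine.loglik(topology, lengths)
        if new < current - 1e-12:  # safeguard: never accept a worse point
            break
        if new - current < tol:
            current = new
            converged = True
            break
        current = new
    keys = names + ["internal"]
    return QuartetFit(
        topology=topology,
        loglik=current,
        lengths=dict(zip(keys, lengths)),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Four-cluster likelihood mapping
# ---------------------------------------------------------------------------

REGION_NAMES = ("t1", "t2", "t3", "e12", "e13", "e23", "center")


@dataclass
class SimplexPoint:
    """Posterior weights of the three quartet topologies (sum to one)."""

    p: np.ndarray

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (3,) or np.any(self.p < 0) or abs(self.p.sum() - 1) > 1e-9:
            raise PhyloSignalError("simplex point must be a length-3 simplex vector")

    @property
    def region(self) -> str:
        return classify_simplex_point(self.p)


def classify_simplex_point(p: Sequence[float]) -> str:
    """Assign a simplex point to one of seven support regions.

    ``t_i`` when ``p_i > 1/2``; ``e_ij`` when ``p_i <= 1/2, p_j <= 1/2`` and
    the remaining weight is ``<= 1/4``; centre otherwise.  Boundary ties
    (several edge regions matching) resolve toward the centre, the
    less-resolved region.
    """
    p = np.asarray(p, dtype=float)
    for i in range(3):
        if p[i] > 0.5:
            return f"t{i + 1}"
    matches = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        k = 3 - i - j
        if p[i] <= 0.5 and p[j] <= 0.5 and p[k] <= 0.25:
            matches.append(f"e{i + 1}{j + 1}")
    if len(matches) == 1:
        return matches[0]
    return "center"


@dataclass
class FcLMReport:
    n_quartets: int
    region_fractions: dict[str, float]
    points: np.ndarray  # (n_quartets, 3)
    quartets: list[tuple[str, str, str, str]]

    def __post_init__(self):
        total = sum(self.region_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise PhyloSignalError("region fractions must sum to 1")


def quartet_topologies(
    a: str, b: str, c: str, d: str
) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """The three resolutions, in cluster order: (12|34), (13|24), (14|23)."""
    return [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]


def fclm(
    alignment: Alignment,
    clusters: Sequence[Sequence[str]],
    n_quartets: int,
    model: SubstModel,
    seed: int = 0,
) -> FcLMReport:
    """Four-cluster likelihood mapping.

    Quartets take one taxon from each of four disjoint clusters, sampled
    without replacement; when ``n_quartets`` is at least the number of
    combinations, the whole combination space is evaluated.
    """
    if len(clusters) != 4:
        raise PhyloSignalError("FcLM needs exactly four clusters")
    clusters = [list(c) for c in clusters]
    flat: list[str] = [t for c in clusters for t in c]
    if len(set(flat)) != len(flat):
        raise PhyloSignalError("clusters must be disjoint")
    for i, c in enumerate(clusters):
        if not c:
            raise PhyloSignalError(f"cluster {i + 1} is empty")
        absent = [t for t in c if t not in alignment.sequences]
        if absent:
            raise PhyloSignalError(f"cluster taxa missing from alignment: {absent}")

    sizes = [len(c) for c in clusters]
    total = int(np.prod(sizes))
    rng = np.random.default_rng(seed)
    if n_quartets >= total:
        chosen = np.arange(total)
    else:
        chosen = np.sort(rng.choice(total, size=n_quartets, replace=False))
    combos = [
        tuple(clusters[k][idx] for k, idx in enumerate(np.unravel_index(i, sizes)))
        for i in chosen
    ]

    points = np.empty((len(combos), 3))
    region_counts = {name: 0 for name in REGION_NAMES}
    for qi, quartet in enumerate(combos):
        sub = alignment.subset(list(quartet))
        lls = np.array(
            [
                optimize_quartet(sub, topo, model).loglik
                for topo in quartet_topologies(*quartet)
            ]
        )
        w = np.exp(lls - lls.max())
        p = w / w.sum()
        points[qi] = p
        region_counts[classify_simplex_point(p)] += 1

    n = len(combos)
    fractions = {name: region_counts[name] / n for name in REGION_NAMES}
    return FcLMReport(
        n_quartets=n, region_fractions=fractions, points=points, quartets=combos
    )


# ---------------------------------------------------------------------------
# Distances and neighbour joining (default RADICAL estimator)
# ---------------------------------------------------------------------------


def ml_distance(
    seq_a: str, seq_b: str, model: SubstModel, max_distance: float = 10.0
) -> float:
    """Maximum-likelihood pairwise distance under the n-state Poisson model
    (closed form from the observed mismatch proportion)."""
    a = model.encode(seq_a)
    b = model.encode(seq_b)
    both = (a >= 0) & (b >= 0)
    if not both.any():
        return max_distance
    p = float((a[both] != b[both]).mean())
    n = model.n_states
    arg = 1.0 - n * p / (n - 1.0)
    if arg <= 0:
        return max_distance
    return min(-(n - 1.0) / n * math.log(arg), max_distance)


def nj_tree(alignment: Alignment, model: SubstModel | None = None) -> Tree:
    """Neighbour joining on ML pairwise distances (negative branch lengths
    clamped to zero)."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    model = model or poisson_model()
    taxa = alignment.taxa
    if len(taxa) < 3:
        raise PhyloSignalError("neighbour joining needs at least 3 taxa")
    d = np.zeros((len(taxa), len(taxa)))
    for i, j in itertools.combinations(range(len(taxa)), 2):
        d[i, j] = d[j, i] = ml_distance(
            alignment[taxa[i]], alignment[taxa[j]], model
        )
    sk = nj(DistanceMatrix(d, ids=taxa))
    tree = parse_newick(str(sk))
    for node in tree.postorder():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# RADICAL
# ---------------------------------------------------------------------------


@dataclass
class RadicalReplicate:
    order: list[str]
    clades: dict[int, frozenset[frozenset[str]]]  # step size -> clade set


@dataclass
class RadicalCurves:
    n_genes: int
    step_sizes: list[int]
    taxa: list[str]
    replicates: list[RadicalReplicate] = field(default_factory=list)
    failures: list[tuple[int, int, str]] = field(default_factory=list)  # (rep, step, msg)


def radical(
    genes: list[tuple[str, Alignment]],
    estimator: Callable[[Alignment], Tree] | None = None,
    n_replicates: int = 10,
    step: int = 1,
    seed: int = 0,
    model: SubstModel | None = None,
) -> RadicalCurves:
    """Random-addition concatenation analysis.

    Per replicate the gene order is shuffled and a tree is estimated from
    each prefix concatenation of sizes ``step, 2*step, ..., G`` (the full
    concatenation is always included).  A failing estimator aborts the
    replicate, which is recorded under ``failures``.
    """
    from .ortholog_matrix import concat_supermatrix

    if len(genes) < 2:
        raise PhyloSignalError("RADICAL needs at least two genes")
    if step < 1:
        raise PhyloSignalError("step must be >= 1")
    if estimator is None:
        mdl = model or poisson_model()
        estimator = lambda aln: nj_tree(aln, mdl)  # noqa: E731

    G = len(genes)
    taxa = sorted({t for _, aln in genes for t in aln.taxa})
    step_sizes = list(range(step, G + 1, step))
    if step_sizes[-1] != G:
        step_sizes.append(G)

    rng = np.random.default_rng(seed)
    curves = RadicalCurves(n_genes=G, step_sizes=step_sizes, taxa=taxa)
    by_name = dict(genes)
    names = [name for name, _ in genes]
    for rep in range(n_replicates):
        order = [names[i] for i in rng.permutation(G)]
        clades: dict[int, frozenset[frozenset[str]]] = {}
        ok = True
        for s in step_sizes:
            subset = [(name, by_name[name]) for name in sorted(order[:s])]
            sm = concat_supermatrix(subset, taxa)
            try:
                tree = estimator(sm.alignment)
            except Exception as exc:  # estimator contract: report, don't die
                curves.failures.append((rep, s, str(exc)))
                ok = False
                break
            clades[s] = tree.clade_set()
        if ok:
            curves.replicates.append(RadicalReplicate(order=order, clades=clades))
    return curves


def fixation_points(
    curves: RadicalCurves, clades: Sequence[frozenset[str]]
) -> dict[frozenset[str], float | str]:
    """Fixation fraction per clade.

    The raw fixation point ``m`` is the smallest step size such that the
    clade appears in every estimated tree at every step >= ``m`` in every
    replicate; the reported value is ``m / G``.  A clade absent from any
    replicate's final-step tree (or never stabilising) is ``"unfixed"``.
    """
    if not curves.replicates:
        raise PhyloSignalError("no successful RADICAL replicates")
    universe = frozenset(curves.taxa)
    G = curves.n_genes
    out: dict[frozenset[str], float | str] = {}
    for clade in clades:
        canon = canonical_split(clade, universe)
        if any(
            canon not in rep.clades[curves.step_sizes[-1]]
            for rep in curves.replicates
        ):
            out[clade] = "unfixed"
            continue
        bad = [
            s
            for rep in curves.replicates
            for s in curves.step_sizes
            if canon not in rep.clades[s]
        ]
        if not bad:
            m = curves.step_sizes[0]
        else:
            later = [s for s in curves.step_sizes if s > max(bad)]
            m = later[0]
        out[clade] = m / G
    return out
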