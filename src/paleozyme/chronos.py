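"""Penalized-likelihood divergence-time estimation.

Given a phylogram (branch lengths in expected substitutions per site) and at
least one fixed or maximum age calibration, node ages and per-branch
substitution rates are estimated by maximising

    sum_e [ x_e log(mu_e) - mu_e - log Gamma(x_e + 1) ]  -  lambda * P

where ``x_e`` is the branch's (continuous) substitution count, ``mu_e =
rate_e * duration_e`` its Poisson intensity, and ``P`` a roughness penalty:
the squared rate difference across every parent-child branch pair plus the
variance of the root-children rates.  ``lambda`` weighs rate smoothness
against fit and is chosen by leave-one-terminal-out cross-validation.

Ages are parameterised as relative positions inside the interval allowed by
the parent's age and the calibrations, so order constraints hold by
construction; optimisation is bounded quasi-Newton (L-BFGS-B) with analytic
gradients and seeded random restarts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from .treecore import Tree


class ChronosError(ValueError):
    pass


#: Default smoothing grid for cross-validation.  The additive penalty
#: compares rates on their natural scale, so for per-Ma rates of order 1e-3
#: the informative part of the grid lies many decades above 1; the grid
#: spans both regimes.
DEFAULT_LAMBDA_GRID = [10.0**k for k in range(-3, 8)]


@dataclass(frozen=True)
class Calibration:
    """Age constraint on the MRCA of ``clade`` (or ``"root"``), in Ma."""

    clade: frozenset[str] | str
    kind: str  # fixed | min | max
    age: float

    def __post_init__(self):
        if self.kind not in ("fixed", "min", "max"):
            raise ChronosError(f"unknown calibration kind {self.kind!r}")
        if self.age <= 0:
            raise ChronosError("calibration age must be positive")


@dataclass
class FitOptions:
    """Optimiser settings.

    The default stopping tolerances are deliberately strict (the penalized
    likelihood is very flat near its optimum); cross-validation uses faster
    settings since its score only needs ~1% accuracy.
    """

    n_restarts: int = 5
    seed: int = 0
    max_iter: int = 3000
    ftol: float = 1e-16
    gtol: float = 1e-6
    sites: float = 1.0
    log_rate_penalty: bool = False


def cv_fit_options(seed: int = 0, sites: float = 1.0) -> FitOptions:
    """Faster single-start settings used for cross-validation refits."""
    return FitOptions(
        n_restarts=1, seed=seed, max_iter=400, ftol=1e-11, sites=sites
    )


@dataclass
class Chronogram:
    """Dated tree with per-branch rates under a smoothing penalty."""

    tree: Tree  # node ages set; branch lengths are durations (Ma)
    ages: dict[frozenset[str], float]
    rates: dict[frozenset[str], float]
    lam: float
    objective: float
    converged: bool

    def age_of(self, clade) -> float:
        return self.ages[frozenset(clade)]

    def table(self) -> pd.DataFrame:
        rows = [
            {"clade": "|".join(sorted(k)), "age": v, "rate": self.rates.get(k)}
            for k, v in sorted(self.ages.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Problem setup
# ---------------------------------------------------------------------------

_T_FLOOR = 1e-9


class _PLProblem:
    def __init__(
        self,
        phylogram: Tree,
        calibrations,
        lam: float,
        opts: FitOptions,
        exclude_leaf: str | None = None,
    ):
        self.tree = phylogram.copy()
        self.lam = float(lam)
        self.opts = opts
        tree = self.tree
        if tree.n_leaves() < 2:
            raise ChronosError("need at least two leaves")
        self.excluded_id = (
            tree.find_leaf(exclude_leaf).id if exclude_leaf is not None else None
        )

        # resolve calibrations onto nodes
        self.fixed: dict[int, float] = {}
        min_cal: dict[int, float] = {}
        max_cal: dict[int, float] = {}
        for cal in calibrations:
            node = tree.root if cal.clade == "root" else tree.mrca(cal.clade)
            if node.is_leaf():
                raise ChronosError("cannot calibrate a terminal node")
            if cal.kind == "fixed":
                if node.id in (min_cal.keys() | max_cal.keys() | self.fixed.keys()):
                    raise ChronosError("conflicting calibrations on one node")
                self.fixed[node.id] = cal.age
            elif cal.kind == "min":
                if node.id in self.fixed:
                    raise ChronosError("fixed and min calibration on one node")
                min_cal[node.id] = max(min_cal.get(node.id, 0.0), cal.age)
            else:
                if node.id in self.fixed:
                    raise ChronosError("fixed and max calibration on one node")
                max_cal[node.id] = min(max_cal.get(node.id, math.inf), cal.age)

        # lower bound from descendants (min/fixed cals), postorder
        self.low: dict[int, float] = {}
        for node in tree.postorder():
            if node.is_leaf():
                self.low[node.id] = 0.0
                continue
            lo = max((self.low[c.id] for c in node.children), default=0.0)
            lo = max(lo, min_cal.get(node.id, 0.0), self.fixed.get(node.id, 0.0))
            self.low[node.id] = lo
        # own upper bound from max/fixed cals
        self.up_cal: dict[int, float] = {
            n.id: min(max_cal.get(n.id, math.inf), self.fixed.get(n.id, math.inf))
            for n in tree.postorder()
        }
        # feasibility: effective upper bound propagated from ancestors
        eff_up: dict[int, float] = {}
        for node in tree.preorder():
            u = self.up_cal[node.id]
            if node.parent is not None:
                u = min(u, eff_up[node.parent.id])
            eff_up[node.id] = u
            if self.low[node.id] > u + 1e-9:
                raise ChronosError(
                    "infeasible calibration set: a minimum age exceeds a "
                    "maximum age on the same root-to-tip path"
                )
        rid = tree.root.id
        if rid in self.fixed:
            self.root_upper = self.fixed[rid]
        elif math.isfinite(self.up_cal[rid]):
            self.root_upper = self.up_cal[rid]
        else:
            raise ChronosError(
                "ages are not identifiable: place a fixed or max calibration "
                "on the root (or an ancestor-covering clade)"
            )

        # branch bookkeeping (branch = non-root node); an excluded pendant
        # branch contributes neither likelihood nor penalty terms
        self.branch_nodes = [
            n
            for n in tree.postorder()
            if n.parent is not None and n.id != self.excluded_id
        ]
        for n in self.branch_nodes:
            if n.length is None:
                raise ChronosError("phylogram must have branch lengths")
        self.x = np.array([n.length * opts.sites for n in self.branch_nodes])
        self.const = -float(np.sum(gammaln(self.x + 1.0)))
        self.free_nodes = [
            n
            for n in tree.preorder()
            if not n.is_leaf() and n.id not in self.fixed
        ]
        self.n_u = len(self.free_nodes)
        self.n_r = len(self.branch_nodes)
        # penalty pairs: branch -> parent branch (when parent is not root)
        self.pair_child: list[int] = []
        self.pair_parent: list[int] = []
        bindex = {n.id: k for k, n in enumerate(self.branch_nodes)}
        for k, n in enumerate(self.branch_nodes):
            if n.parent.parent is not None:
                self.pair_child.append(k)
                self.pair_parent.append(bindex[n.parent.id])
        self.root_children = [
            bindex[c.id] for c in tree.root.children if c.id in bindex
        ]
        self._bindex = bindex

    # -- decoding ------------------------------------------------------------

    def decode_ages(self, u: np.ndarray):
        """Ages per node id plus, per free node, the interval width and
        whether the upper bound came from the parent's age."""
        ages: dict[int, float] = {}
        width: dict[int, float] = {}
        parent_bound: dict[int, bool] = {}
        ui = {n.id: u[k] for k, n in enumerate(self.free_nodes)}
        for node in self.tree.preorder():
            if node.is_leaf():
                ages[node.id] = 0.0
                continue
            if node.id in self.fixed:
                ages[node.id] = self.fixed[node.id]
                continue
            if node.parent is None:
                U = self.root_upper
                pb = False
            else:
                pa = ages[node.parent.id]
                cal = self.up_cal[node.id]
                U = min(pa, cal)
                pb = pa <= cal
            L = self.low[node.id]
            w = max(U - L, 0.0)
            ages[node.id] = L + ui[node.id] * w
            width[node.id] = w
            parent_bound[node.id] = pb
        return ages, width, parent_bound

    # -- objective -----------------------------------------------------------

    def objective_and_grad(self, params: np.ndarray):
        u = params[: self.n_u]
        logr = params[self.n_u :]
        r = np.exp(logr)
        ages, width, parent_bound = self.decode_ages(u)

        t = np.array(
            [ages[n.parent.id] - ages[n.id] for n in self.branch_nodes]
        )
        t = np.maximum(t, _T_FLOOR)
        mu = r * t
        with np.errstate(divide="ignore", invalid="ignore"):
            loglik = np.where(
                self.x > 0, self.x * np.log(mu) - mu, -mu
            )
        f = float(np.sum(loglik)) + self.const

        pen_r = self.lam if not self.opts.log_rate_penalty else self.lam
        rr = np.log(r) if self.opts.log_rate_penalty else r
        diff = rr[self.pair_child] - rr[self.pair_parent]
        penalty = float(np.sum(diff**2))
        rc = rr[self.root_children]
        m = len(rc)
        rc_mean = rc.mean() if m else 0.0
        penalty += float(np.mean((rc - rc_mean) ** 2)) if m else 0.0
        f -= pen_r * penalty

        # gradients
        dfdmu = np.where(self.x > 0, self.x / mu - 1.0, -1.0)
        dfdt = r * dfdmu
        dfdr = t * dfdmu
        # penalty gradient wrt rr
        dpen = np.zeros(self.n_r)
        np.add.at(dpen, self.pair_child, 2.0 * diff)
        np.add.at(dpen, self.pair_parent, -2.0 * diff)
        if m:
            dpen[self.root_children] += 2.0 * (rc - rc_mean) / m
        if self.opts.log_rate_penalty:
            grad_logr = dfdr * r - pen_r * dpen
        else:
            grad_logr = (dfdr - pen_r * dpen) * r

        g_age: dict[int, float] = {n.id: 0.0 for n in self.tree.postorder()}
        for k, n in enumerate(self.branch_nodes):
            g_age[n.parent.id] += dfdt[k]
            g_age[n.id] -= dfdt[k]
        # chain through the nested interval parameterisation (postorder)
        G: dict[int, float] = {}
        for node in self.tree.postorder():
            if node.is_leaf() or node.id in self.fixed:
                continue
            total = g_age[node.id]
            # age(c) = L_c + u_c * (age(node) - L_c) when the child's upper
            # bound comes from this node's age
            for c in node.children:
                if (
                    not c.is_leaf()
                    and c.id not in self.fixed
                    and parent_bound[c.id]
                ):
                    total += G[c.id] * self._u_of(c.id)
            G[node.id] = total
        grad_u = np.array(
            [G[n.id] * width[n.id] for n in self.free_nodes]
        )
        grad = np.concatenate([grad_u, grad_logr])
        self._last_ages = ages
        return -f, -grad

    def _u_of(self, node_id: int) -> float:
        return self._current_u[self._free_index[node_id]]

    def prepare(self):
        self._free_index = {n.id: k for k, n in enumerate(self.free_nodes)}
        return self

    def set_u(self, u: np.ndarray):
        self._current_u = u


# ---------------------------------------------------------------------------
# Public objective (value only)
# ---------------------------------------------------------------------------


def pl_objective(
    topology: Tree,
    ages: dict[int, float],
    rates: dict[int, float],
    lam: float,
    sites: float = 1.0,
    log_rate_penalty: bool = False,
) -> float:
    """Penalized log-likelihood of explicit ages and rates.

    ``ages`` and ``rates`` are keyed by node id (rates by the branch's child
    node).  A zero duration with a positive substitution count yields
    ``-inf``.
    """
    total = 0.0
    for node in topology.postorder():
        if node.parent is None:
            continue
        t = ages[node.parent.id] - ages[node.id]
        if t < 0:
            raise ChronosError("ages must satisfy age(parent) >= age(child)")
        r = rates[node.id]
        if r <= 0:
            raise ChronosError("rates must be positive")
        x = (node.length or 0.0) * sites
        mu = r * t
        if mu == 0.0:
            if x > 0:
                return -math.inf
            contrib = 0.0
        else:
            contrib = x * math.log(mu) - mu
        total += contrib - float(gammaln(x + 1.0))
    penalty = 0.0
    tr = math.log if log_rate_penalty else (lambda v: v)
    root_rates = []
    for node in topology.postorder():
        if node.parent is None:
            continue
        if node.parent.parent is None:
            root_rates.append(tr(rates[node.id]))
        else:
            penalty += (tr(rates[node.id]) - tr(rates[node.parent.id])) ** 2
    if root_rates:
        arr = np.array(root_rates)
        penalty += float(np.mean((arr - arr.mean()) ** 2))
    return total - lam * penalty


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit_chronogram(
    phylogram: Tree,
    calibrations,
    lam: float,
    opts: FitOptions | None = None,
    exclude_leaf: str | None = None,
) -> Chronogram:
    """Estimate node ages and branch rates by penalized likelihood.

    Requires a calibration set that makes absolute ages identifiable (a
    fixed or max age on the root clade).  Runs ``opts.n_restarts`` seeded
    starts of bounded L-BFGS-B and keeps the best optimum; fixed
    calibrations are honoured exactly by construction.

    ``exclude_leaf`` omits one pendant branch from the likelihood and the
    penalty (the cross-validation device); its attachment node's age is
    still estimated from the rest of the tree.
    """
    opts = opts or FitOptions()
    problem = _PLProblem(
        phylogram, list(calibrations), lam, opts, exclude_leaf=exclude_leaf
    ).prepare()
    rng = np.random.default_rng(opts.seed)

    n_u, n_r = problem.n_u, problem.n_r
    bounds = [(1e-5, 1.0 - 1e-5)] * n_u + [(math.log(1e-10), math.log(1e4))] * n_r

    # deterministic first start: midpoints, global mean rate
    u0 = np.full(n_u, 0.5)
    ages0, _, _ = problem.decode_ages(u0)
    t0 = sum(
        max(ages0[n.parent.id] - ages0[n.id], _T_FLOOR)
        for n in problem.branch_nodes
    )
    r_init = max(float(problem.x.sum()) / t0, 1e-8)
    starts = [np.concatenate([u0, np.full(n_r, math.log(r_init))])]
    for _ in range(max(opts.n_restarts - 1, 0)):
        starts.append(
            np.concatenate(
                [
                    rng.uniform(0.1, 0.9, size=n_u),
                    math.log(r_init) + rng.normal(0.0, 0.5, size=n_r),
                ]
            )
        )

    def fun(p):
        problem.set_u(p[:n_u])
        return problem.objective_and_grad(p)

    best = None
    for x0 in starts:
        res = minimize(
            fun,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": opts.max_iter,
                "maxfun": 10 * opts.max_iter,
                "ftol": opts.ftol,
                "gtol": 1e-12,
                "maxls": 60,
            },
        )
        if best is None or res.fun < best.fun:
            best = res

    problem.set_u(best.x[:n_u])
    neg_f, neg_g = problem.objective_and_grad(best.x)
    ages = problem._last_ages
    rates = np.exp(best.x[n_u:])

    # projected gradient norm (components pushing past an active bound are 0)
    proj = []
    for v, g, (lo, hi) in zip(best.x, -neg_g, bounds):
        if (v <= lo + 1e-12 and g > 0) or (v >= hi - 1e-12 and g < 0):
            proj.append(0.0)
        else:
            proj.append(g)
    gnorm = float(np.max(np.abs(proj))) if proj else 0.0
    converged = bool(best.success) and gnorm < max(opts.gtol, 1e-6) * max(
        1.0, abs(neg_f)
    )

    tree = problem.tree
    for node in tree.postorder():
        node.age = ages[node.id]
    tree.set_lengths_from_ages()
    sets = tree.leaf_sets()
    age_by_clade = {sets[n.id]: ages[n.id] for n in tree.postorder()}
    rate_by_clade = {
        sets[n.id]: float(rates[k]) for k, n in enumerate(problem.branch_nodes)
    }
    chrono = Chronogram(
        tree=tree,
        ages=age_by_clade,
        rates=rate_by_clade,
        lam=lam,
        objective=-neg_f,
        converged=converged,
    )
    _assert_constraints(chrono, problem)
    return chrono


def _assert_constraints(chrono: Chronogram, problem: _PLProblem) -> None:
    tree = chrono.tree
    for node in tree.postorder():
        if node.parent is not None and node.age > node.parent.age + 1e-9:
            raise AssertionError("age order violated")
    for nid, age in problem.fixed.items():
        if abs(tree.node(nid).age - age) > 1e-9:
            raise AssertionError("fixed calibration not honoured")


# ---------------------------------------------------------------------------
# Cross-validation of the smoothing parameter
# ---------------------------------------------------------------------------


def cross_validate(
    phylogram: Tree,
    calibrations,
    lambda_grid,
    opts: FitOptions | None = None,
) -> tuple[pd.DataFrame, float]:
    """Leave-one-terminal-out cross-validation of the smoothing parameter.

    For each leaf, its pendant branch is removed from the likelihood and
    penalty (the attachment node stays, so its age is still fitted) and the
    model refitted; the pruned branch's expected substitutions are
    predicted as the fitted rate of the parent-adjacent branch (the branch
    entering the attachment node) times the pruned duration (the fitted
    attachment age).  The score per leaf is ``(x - x_hat)^2 / max(x_hat,
    1e-6)``; ``CV(lambda)`` sums over leaves, and the smallest lambda
    attaining the minimum is selected.  Leaves attached directly to the
    root are skipped (no parent-adjacent branch exists there).
    """
    lambda_grid = sorted(lambda_grid)
    if not lambda_grid:
        raise ChronosError("lambda grid is empty")
    if phylogram.n_leaves() < 4:
        raise ChronosError("cross-validation needs at least four leaves")
    cv_opts = opts or cv_fit_options()

    folds = []
    sets = phylogram.leaf_sets()
    for leaf in phylogram.leaves():
        if leaf.parent is phylogram.root:
            continue
        folds.append(
            {
                "leaf": leaf.label,
                "x": (leaf.length or 0.0) * cv_opts.sites,
                "parent_clade": sets[leaf.parent.id],
            }
        )
    if not folds:
        raise ChronosError("no usable leaves for cross-validation")

    rows = []
    for lam in lambda_grid:
        score = 0.0
        for fold in folds:
            fit = fit_chronogram(
                phylogram, calibrations, lam, cv_opts, exclude_leaf=fold["leaf"]
            )
            age_p = fit.ages[fold["parent_clade"]]
            rate = fit.rates[fold["parent_clade"]]
            x_hat = rate * age_p
            score += (fold["x"] - x_hat) ** 2 / max(x_hat, 1e-6)
        rows.append({"lambda": lam, "cv_score": score})
    table = pd.DataFrame(rows)
    best_lam = None
    best_score = math.inf
    for row in rows:
        if row["cv_score"] < best_score:
            best_score = row["cv_score"]
            best_lam = row["lambda"]
    return table, float(best_lam)
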