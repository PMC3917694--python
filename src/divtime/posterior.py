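"""The Bayesian dating posterior as a target model for the MCMC engine.

State: a calibrated time-tree (topology + node ages), per-branch effective
rates (relaxed clocks), the base clock rate ``c`` and clock variance
``nu``, one unlinked GTR+Gamma+I substitution model per partition, and the
partition rate multipliers (length-weighted mean one).

Priors: the calibrated uniform tree prior on topology-with-ages; the
clock model's density on branch rates; a lognormal prior on ``c`` (set
empirically from a rough tree-height estimate, or by the user);
Exponential(10) on ``nu``; Exponential(1) on each gamma shape; Uniform(0,1)
on each invariant fraction; flat Dirichlet on base frequencies,
exchangeabilities and multiplier weights.

Proposals: uniform-window node-age slides inside the neighbour-feasible
interval, multiplicative root-age and whole-tree scale moves (the latter
compensating the clock rate and branch rates to preserve branch lengths),
log-scale random walks on c, nu, gamma shapes and branch rates, a
reflected walk on p_inv, Dirichlet-centred re-draws for frequencies,
exchangeabilities and multipliers, and a constrained uncle-swap (NNI-type)
topology move that rejects violations of monophyly constraints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import dirichlet as dirichlet_dist

from .alignment import MultiGeneAlignment, PartitionScheme
from .calibrations import CalibrationSet, TreeAgePrior, sample_node_ages
from .clocks import ClockModel, branch_rates_log_prior, sample_branch_rates
from .likelihood import PatternData, partitioned_log_likelihood
from .mcmc import LognormalPrior, TargetModel
from .substitution import SubstitutionModel
from .trees import TimeTree, random_constrained_topology

__all__ = ["DatingState", "PhyloDatingModel"]


@dataclass
class DatingState:
    tree: TimeTree
    rates: np.ndarray | None  # per-branch effective rates (None for strict)
    c: float
    nu: float
    models: list[SubstitutionModel]
    mult_weights: np.ndarray  # simplex; multiplier_i = weight_i / length_share_i


class PhyloDatingModel(TargetModel):
    """Partitioned relaxed-clock dating model over a fixed taxon set."""

    def __init__(
        self,
        alignment: MultiGeneAlignment,
        scheme: PartitionScheme,
        calibrations: CalibrationSet,
        clock_kind: str = "IGR",
        clock_rate_prior: LognormalPrior | None = None,
        topology: TimeTree | None = None,
        topology_moves: bool = True,
        nu_prior_rate: float = 10.0,
        fixed: frozenset[str] = frozenset(),
    ):
        if topology is not None and topology.taxa != alignment.taxa:
            if set(topology.taxa) != set(alignment.taxa):
                raise ValueError("topology and alignment taxon sets differ")
            # re-order alignment rows to the topology's tip order so tip
            # partials line up with node indices
            order = [alignment.taxa.index(t) for t in topology.taxa]
            alignment = MultiGeneAlignment(
                list(topology.taxa),
                {g: m[order] for g, m in alignment.genes.items()},
            )
        self.alignment = alignment
        self.scheme = scheme
        self.calibrations = calibrations
        self.clock_kind = clock_kind
        self.clock_rate_prior = clock_rate_prior or LognormalPrior(median=0.002, sdlog=1.0)
        self.topology = topology
        self.topology_moves = topology_moves and "topology" not in fixed
        self.nu_prior_rate = nu_prior_rate
        self.fixed = frozenset(fixed)

        self.datas = PatternData.from_alignment(alignment, scheme)
        w = scheme.lengths()
        self.length_share = w / w.sum()
        self.tree_prior = TreeAgePrior(calibrations)
        self._kernels = self._build_kernels()

    # ------------------------------------------------------------------ state
    def clock_of(self, state: DatingState) -> ClockModel:
        return ClockModel(self.clock_kind, c=state.c, nu=state.nu)

    def multipliers(self, state: DatingState) -> np.ndarray:
        return state.mult_weights / self.length_share

    def branch_lengths(self, state: DatingState) -> np.ndarray:
        dur = state.tree.durations()
        if self.clock_kind == "strict" or state.rates is None:
            return state.c * dur
        return state.rates * dur

    def initial_state(self, rng: np.random.Generator) -> DatingState:
        if self.topology is not None:
            tree = self.topology.copy()
        else:
            tree = random_constrained_topology(
                self.alignment.taxa, self.calibrations.constraints, rng
            )
        sample_node_ages(tree, self.calibrations, rng)
        c = self.clock_rate_prior.sample(rng)
        nu = float(rng.exponential(1.0 / self.nu_prior_rate)) if self.clock_kind != "strict" else 0.0
        clock = ClockModel(self.clock_kind, c=c, nu=max(nu, 1e-12))
        rates = None if self.clock_kind == "strict" else sample_branch_rates(clock, tree, rng)
        models = []
        for _ in self.scheme:
            models.append(
                SubstitutionModel(
                    exchangeabilities=rng.dirichlet(np.ones(6)) + 1e-6,
                    freqs=_norm(rng.dirichlet(np.ones(4)) + 1e-6),
                    alpha=float(rng.exponential(1.0)) + 0.05,
                    p_inv=float(rng.uniform(0.0, 0.9)),
                )
            )
        return DatingState(
            tree=tree,
            rates=rates,
            c=c,
            nu=nu if self.clock_kind != "strict" else 0.0,
            models=models,
            mult_weights=self.length_share.copy(),
        )

    def state_from_truth(
        self, tree: TimeTree, clock: ClockModel, rates, models, multipliers
    ) -> DatingState:
        """State at the generating values of a synthetic fixture."""
        m = np.asarray(multipliers, dtype=float)
        return DatingState(
            tree=tree.copy(),
            rates=None if self.clock_kind == "strict" else np.asarray(rates, float).copy(),
            c=clock.c,
            nu=clock.nu,
            models=list(models),
            mult_weights=_norm(m * self.length_share),
        )

    # ------------------------------------------------------------------ target
    def log_prior(self, state: DatingState) -> float:
        tree = state.tree
        lp = self.tree_prior.log_density(tree)
        if not np.isfinite(lp):
            return -math.inf
        if self.clock_kind != "strict":
            if state.nu <= 0:
                return -math.inf
            lp += -self.nu_prior_rate * state.nu + math.log(self.nu_prior_rate)
            lp += branch_rates_log_prior(self.clock_of(state), tree, state.rates)
            if not np.isfinite(lp):
                return -math.inf
        lp += self.clock_rate_prior.log_density(state.c)
        for model in state.models:
            if not (0.0 <= model.p_inv < 1.0):
                return -math.inf
            lp += -model.alpha  # Exponential(1) on the gamma shape
        # flat Dirichlet priors on freqs/exchangeabilities/multiplier weights
        # contribute constants only
        return float(lp)

    def log_likelihood(self, state: DatingState) -> float:
        return partitioned_log_likelihood(
            state.tree,
            self.branch_lengths(state),
            state.models,
            self.multipliers(state),
            self.datas,
        )

    def sample_record(self, state: DatingState) -> dict[str, float]:
        tree = state.tree
        rec = {
            "root_age": float(tree.ages[tree.root]),
            "clock_rate": state.c,
            "clock_var": state.nu,
            "tree_length_subs": float(self.branch_lengths(state).sum()),
            "tree_height_subs": _height_subs(self, state),
        }
        ids = self.tree_prior.resolve(tree)
        if ids is not None:
            for k, node in enumerate(ids):
                rec[f"cal_age_{k}"] = float(tree.ages[node])
        for i, m in enumerate(self.multipliers(state)):
            rec[f"mult_{i}"] = float(m)
        for i, model in enumerate(state.models):
            rec[f"alpha_{i}"] = float(model.alpha)
            rec[f"pinv_{i}"] = float(model.p_inv)
        return rec

    def tree_of(self, state: DatingState) -> TimeTree:
        return state.tree

    # -------------------------------------------------------------- proposals
    def _build_kernels(self):
        kernels = []

        def add(name, weight, lik_changed, fn):
            if name not in self.fixed:
                kernels.append((name, float(weight), lik_changed, fn))

        n_internal = self.alignment.n_taxa - 1
        add("ages", max(4.0, n_internal * 0.8), True, self._propose_age_slide)
        add("root", 6.0, True, self._propose_root_scale)
        # scale_all multiplies all durations by f and divides every rate by f,
        # so branch lengths — and the likelihood — are unchanged
        add("scale_all", 6.0, False, self._propose_scale_all)
        add("c", 4.0, True, self._propose_c)
        if self.clock_kind != "strict":
            add("nu", 3.0, False, self._propose_nu)
            add("rates", max(4.0, n_internal * 0.8), True, self._propose_rate_walk)
            # independence redraw of all rates from the clock prior: the
            # Hastings term cancels the rate-prior ratio exactly, so under
            # prior-only sampling this is a Gibbs update; with data it is a
            # prior-as-proposal independence move
            add("rates_redraw", 2.0, True, self._propose_rates_redraw)
            add("c_rates", 5.0, True, self._propose_c_rates_scale)
        add("alpha", 2.5, True, self._propose_alpha)
        add("pinv", 2.5, True, self._propose_pinv)
        # prior-redraw independence kernels: the Hastings term cancels the
        # parameter's own prior, so prior-only sampling mixes these scalars
        # instantly; with data they act as occasional long-range jumps
        add("scalar_redraw", 2.0, True, self._propose_scalar_redraw)
        add("freqs", 1.5, True, self._propose_freqs)
        add("exch", 1.5, True, self._propose_exch)
        if len(self.scheme) > 1:
            add("mults", 2.5, True, self._propose_mults)
        if self.topology_moves:
            add("topology", 5.0, True, self._propose_nni)
        weights = np.array([k[1] for k in kernels])
        self._kernel_probs = weights / weights.sum()
        return kernels

    def propose(self, state: DatingState, rng: np.random.Generator):
        idx = rng.choice(len(self._kernels), p=self._kernel_probs)
        name, _, lik_changed, fn = self._kernels[int(idx)]
        new, log_hastings = fn(state, rng)
        # scale_all preserves branch lengths for relaxed clocks only
        return new, log_hastings, lik_changed

    def _propose_age_slide(self, state, rng):
        tree = state.tree
        internal = tree.internal_nodes()
        candidates = internal[internal != tree.root]
        if len(candidates) == 0:
            return state, -math.inf
        node = int(rng.choice(candidates))
        lo = float(tree.ages[tree.children[node]].max())
        hi = float(tree.ages[tree.parent[node]])
        if hi <= lo:
            return state, -math.inf
        new_tree = tree.copy()
        new_tree.ages[node] = rng.uniform(lo, hi)
        return replace(state, tree=new_tree), 0.0

    def _propose_root_scale(self, state, rng):
        tree = state.tree
        root = tree.root
        f = math.exp(0.1 * (rng.random() - 0.5))
        new_age = tree.ages[root] * f
        if new_age <= tree.ages[tree.children[root]].max():
            return state, -math.inf
        new_tree = tree.copy()
        new_tree.ages[root] = new_age
        return replace(state, tree=new_tree), math.log(f)

    def _propose_scale_all(self, state, rng):
        tree = state.tree
        f = math.exp(0.2 * (rng.random() - 0.5))
        new_tree = tree.copy()
        internal = tree.internal_nodes()
        new_tree.ages[internal] = tree.ages[internal] * f
        n_up = len(internal)
        n_down = 1  # the clock rate
        new_c = state.c / f
        if state.rates is not None:
            new_rates = state.rates / f
            n_down += new_tree.n_nodes - 1
        else:
            new_rates = None
        log_hastings = (n_up - n_down) * math.log(f)
        return replace(state, tree=new_tree, c=new_c, rates=new_rates), log_hastings

    def _propose_c(self, state, rng):
        f = math.exp(0.6 * (rng.random() - 0.5))
        return replace(state, c=state.c * f), math.log(f)

    def _propose_nu(self, state, rng):
        f = math.exp(1.4 * (rng.random() - 0.5))
        return replace(state, nu=state.nu * f), math.log(f)

    def _propose_rate_walk(self, state, rng):
        tree = state.tree
        nodes = [i for i in range(tree.n_nodes) if i != tree.root]
        node = int(rng.choice(nodes))
        f = math.exp(0.5 * (rng.random() - 0.5))
        new_rates = state.rates.copy()
        new_rates[node] *= f
        return replace(state, rates=new_rates), math.log(f)

    def _propose_scalar_redraw(self, state, rng):
        choices = ["c", "alpha", "pinv"]
        if self.clock_kind != "strict" and "nu" not in self.fixed:
            choices.append("nu")
        choices = [x for x in choices if x not in self.fixed]
        if not choices:
            return state, -math.inf
        which = choices[int(rng.integers(len(choices)))]
        if which in ("c", "nu"):
            # redraw the scalar from its prior together with fresh branch
            # rates from the clock prior, so the rate-prior term cancels too
            if which == "c":
                new_c, new_nu = self.clock_rate_prior.sample(rng), state.nu
                lh = self.clock_rate_prior.log_density(state.c) - self.clock_rate_prior.log_density(new_c)
            else:
                new_c, new_nu = state.c, float(rng.exponential(1.0 / self.nu_prior_rate))
                if new_nu <= 0:
                    return state, -math.inf
                lh = self.nu_prior_rate * (new_nu - state.nu)
            new_rates = state.rates
            if self.clock_kind != "strict" and state.rates is not None and "rates" not in self.fixed:
                old_clock = self.clock_of(state)
                new_clock = ClockModel(self.clock_kind, c=new_c, nu=max(new_nu, 1e-12))
                try:
                    new_rates = sample_branch_rates(new_clock, state.tree, rng)
                except ValueError:
                    return state, -math.inf
                lh += branch_rates_log_prior(old_clock, state.tree, state.rates)
                new_rp = branch_rates_log_prior(new_clock, state.tree, new_rates)
                if not np.isfinite(new_rp):
                    return state, -math.inf
                lh -= new_rp
            return replace(state, c=new_c, nu=new_nu, rates=new_rates), lh
        i = int(rng.integers(len(state.models)))
        old = state.models[i]
        new_models = list(state.models)
        if which == "alpha":
            new_alpha = float(rng.exponential(1.0))
            if new_alpha <= 0:
                return state, -math.inf
            lh = new_alpha - old.alpha  # Exp(1) prior cancels
            new_models[i] = SubstitutionModel(
                old.exchangeabilities, old.freqs, alpha=new_alpha, p_inv=old.p_inv
            )
        else:  # pinv ~ Uniform(0,1)
            lh = 0.0
            new_models[i] = SubstitutionModel(
                old.exchangeabilities, old.freqs, alpha=old.alpha, p_inv=float(rng.random())
            )
        return replace(state, models=new_models), lh

    def _propose_rates_redraw(self, state, rng):
        clock = self.clock_of(state)
        try:
            new_rates = sample_branch_rates(clock, state.tree, rng)
        except ValueError:
            return state, -math.inf
        old_lp = branch_rates_log_prior(clock, state.tree, state.rates)
        new_lp = branch_rates_log_prior(clock, state.tree, new_rates)
        if not np.isfinite(new_lp):
            return state, -math.inf
        return replace(state, rates=new_rates), old_lp - new_lp

    def _propose_c_rates_scale(self, state, rng):
        # scale the base rate and every branch rate together, preserving the
        # rates' configuration relative to c
        f = math.exp(0.6 * (rng.random() - 0.5))
        new_rates = state.rates * f
        log_hastings = (1 + state.tree.n_nodes - 1) * math.log(f)
        return replace(state, c=state.c * f, rates=new_rates), log_hastings

    def _propose_alpha(self, state, rng):
        i = int(rng.integers(len(state.models)))
        f = math.exp(0.9 * (rng.random() - 0.5))
        old = state.models[i]
        new_models = list(state.models)
        new_models[i] = SubstitutionModel(
            old.exchangeabilities, old.freqs, alpha=old.alpha * f, p_inv=old.p_inv
        )
        return replace(state, models=new_models), math.log(f)

    def _propose_pinv(self, state, rng):
        i = int(rng.integers(len(state.models)))
        old = state.models[i]
        x = old.p_inv + 0.2 * (rng.random() - 0.5)
        # reflect into [0, 1)
        x = abs(x)
        if x >= 1.0:
            x = 2.0 - x - 1e-12
        new_models = list(state.models)
        new_models[i] = SubstitutionModel(
            old.exchangeabilities, old.freqs, alpha=old.alpha, p_inv=x
        )
        return replace(state, models=new_models), 0.0

    def _dirichlet_centred(self, x, rng, kappa):
        conc = kappa * np.asarray(x, dtype=float) + 0.5
        new = rng.dirichlet(conc)
        if np.any(new < 1e-8):
            return None, -math.inf
        fwd = dirichlet_dist.logpdf(new, conc)
        rev = dirichlet_dist.logpdf(np.asarray(x, float), kappa * new + 0.5)
        return new, rev - fwd

    def _propose_freqs(self, state, rng):
        i = int(rng.integers(len(state.models)))
        old = state.models[i]
        new, lh = self._dirichlet_centred(old.freqs, rng, 1000.0)
        if new is None:
            return state, -math.inf
        new_models = list(state.models)
        new_models[i] = SubstitutionModel(
            old.exchangeabilities, _norm(new), alpha=old.alpha, p_inv=old.p_inv
        )
        return replace(state, models=new_models), lh

    def _propose_exch(self, state, rng):
        i = int(rng.integers(len(state.models)))
        old = state.models[i]
        x = old.exchangeabilities / old.exchangeabilities.sum()
        new, lh = self._dirichlet_centred(x, rng, 300.0)
        if new is None:
            return state, -math.inf
        new_models = list(state.models)
        new_models[i] = SubstitutionModel(new, old.freqs, alpha=old.alpha, p_inv=old.p_inv)
        return replace(state, models=new_models), lh

    def _propose_mults(self, state, rng):
        new, lh = self._dirichlet_centred(state.mult_weights, rng, 500.0)
        if new is None:
            return state, -math.inf
        return replace(state, mult_weights=new), lh

    def _propose_nni(self, state, rng):
        """Uncle swap: exchange a node with its parent's sibling.

        Selection is uniform over nodes that have a grandparent; that set's
        size is invariant under the move, so the proposal is symmetric.
        """
        tree = state.tree
        candidates = [
            i
            for i in range(tree.n_nodes)
            if tree.parent[i] >= 0 and tree.parent[tree.parent[i]] >= 0
        ]
        x = int(rng.choice(candidates))
        p = int(tree.parent[x])
        g = int(tree.parent[p])
        u = int(tree.children[g][0] if tree.children[g][1] == p else tree.children[g][1])
        if tree.ages[p] <= tree.ages[u]:
            return state, -math.inf
        new_tree = tree.copy()
        gi = 0 if new_tree.children[g][0] == u else 1
        pi = 0 if new_tree.children[p][0] == x else 1
        new_tree.children[g][gi] = x
        new_tree.children[p][pi] = u
        new_tree.parent[x] = g
        new_tree.parent[u] = p
        new_tree.invalidate_topology()
        return replace(state, tree=new_tree), 0.0


def _norm(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x / x.sum()


def _height_subs(model: PhyloDatingModel, state: DatingState) -> float:
    """Tree height in expected substitutions: the tip-averaged root-to-tip
    path (equal to clock-rate x root age under a strict clock; averaging
    avoids the upward bias a max-path definition has under relaxed
    clocks)."""
    tree = state.tree
    blens = model.branch_lengths(state)
    depth = np.zeros(tree.n_nodes)
    for node in tree.preorder():
        p = tree.parent[node]
        if p >= 0:
            depth[node] = depth[p] + blens[node]
    return float(depth[: tree.n_tips].mean())
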