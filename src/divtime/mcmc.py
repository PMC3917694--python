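"""Metropolis-coupled MCMC over a generic target model.

The engine is agnostic of the state's contents: a :class:`TargetModel`
supplies an initial state, log prior, log likelihood, a proposal mixture
(returning a Hastings correction), and a flat record of scalar parameters
for the trace.  The cold chain targets ``likelihood^beta x prior`` (beta=1
for posterior sampling, 0 for prior-only runs, intermediate for power
posteriors in stepping-stone estimation); heated chains raise the whole
target to ``1/(1 + (i-1) T)`` and exchange states via the standard swap
ratio.
"""

from __future__ import annotations

import math
import warnings
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .calibrations import Calibration
from .trees import TimeTree

__all__ = [
    "McmcConfig",
    "Trace",
    "TargetModel",
    "heat",
    "run_mcmc",
    "run_independent",
    "asdsf",
    "effective_sample_size",
    "LognormalPrior",
    "empirical_bayes_clock_prior",
    "ConvergenceWarning",
]

ASDSF_THRESHOLD = 0.01  # recommended topological convergence threshold


class ConvergenceWarning(UserWarning):
    pass


def heat(chain_index: int, temperature: float) -> float:
    """Inverse temperature of chain i >= 1: 1/(1 + (i-1) T); cold chain 1."""
    if chain_index < 1:
        raise ValueError("chain index starts at 1")
    if temperature < 0:
        raise ValueError("temperature constant must be non-negative")
    return 1.0 / (1.0 + (chain_index - 1) * temperature)


@dataclass
class McmcConfig:
    n_generations: int
    sample_every: int = 10
    n_chains: int = 1
    temperature: float = 0.1
    n_runs: int = 2
    burn_in: float = 0.25  # fraction removed per run before pooling
    prior_only: bool = False
    power: float = 1.0  # likelihood power beta
    topology_moves: bool = True

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not (0 < self.sample_every <= self.n_generations):
            raise ValueError("0 < sample_every <= n_generations required")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if not (0 <= self.burn_in < 1):
            raise ValueError("burn_in fraction in [0, 1)")


@dataclass
class Trace:
    """Sampled states of one (or one pooled) MCMC run."""

    params: pd.DataFrame  # one row per sample; includes generation, logL, logP
    trees: list[TimeTree] = field(default_factory=list)
    run_id: int = 0
    final_state: Any = None

    def __post_init__(self):
        if len(self.trees) and len(self.trees) != len(self.params):
            raise ValueError("trees and parameter rows out of step")
        gen = self.params["generation"].to_numpy()
        if len(gen) > 1 and not np.all(np.diff(gen) > 0):
            raise ValueError("generation indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.params)

    def discard_burn_in(self, fraction: float) -> "Trace":
        k = int(math.floor(len(self) * fraction))
        return Trace(
            self.params.iloc[k:].reset_index(drop=True),
            self.trees[k:] if self.trees else [],
            run_id=self.run_id,
        )

    # ----------------------------------------------------------------- files
    def write(self, prefix: str | Path) -> tuple[Path, Path]:
        """Tab-separated parameter log + one-Newick-per-line tree log."""
        prefix = Path(prefix)
        ppath = prefix.with_suffix(".params.tsv")
        tpath = prefix.with_suffix(".trees")
        self.params.to_csv(ppath, sep="\t", index=False)
        with open(tpath, "w") as fh:
            for tree in self.trees:
                fh.write(tree.to_newick() + "\n")
        return ppath, tpath

    @classmethod
    def read(cls, prefix: str | Path, run_id: int = 0) -> "Trace":
        prefix = Path(prefix)
        params = pd.read_csv(prefix.with_suffix(".params.tsv"), sep="\t")
        tpath = prefix.with_suffix(".trees")
        trees = []
        if tpath.exists():
            for line in tpath.read_text().splitlines():
                if line.strip():
                    trees.append(TimeTree.from_newick(line))
        return cls(params, trees, run_id=run_id)


class TargetModel(ABC):
    """Target distribution + proposal mixture for the generic engine."""

    @abstractmethod
    def initial_state(self, rng: np.random.Generator):
        ...

    @abstractmethod
    def log_prior(self, state) -> float:
        ...

    @abstractmethod
    def log_likelihood(self, state) -> float:
        ...

    @abstractmethod
    def propose(self, state, rng: np.random.Generator):
        """Return (new_state, log_hastings, likelihood_changed)."""

    def sample_record(self, state) -> dict[str, float]:
        return {}

    def tree_of(self, state) -> TimeTree | None:
        return None


def run_mcmc(
    model: TargetModel,
    config: McmcConfig,
    seed_or_rng,
    init_state=None,
    run_id: int = 0,
) -> Trace:
    """One Metropolis-coupled run; returns the cold-chain trace.

    The trace's ``final_state`` carries the last cold-chain state so power
    posteriors (stepping stone) can chain runs together.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    beta = 0.0 if config.prior_only else config.power

    def full_eval(state):
        lp = model.log_prior(state)
        if not np.isfinite(lp):
            return lp, -math.inf
        ll = model.log_likelihood(state) if beta > 0 else 0.0
        return lp, ll

    # initialise every chain (auto-retry from the prior on zero density)
    chains = []
    for _ in range(config.n_chains):
        state = init_state
        for attempt in range(100):
            if state is None:
                state = model.initial_state(rng)
            lp, ll = full_eval(state)
            if np.isfinite(lp) and np.isfinite(ll):
                break
            state = None
        else:
            raise RuntimeError("could not find an initial state with finite density")
        chains.append([state, lp, ll])
        init_state = None if init_state is None else chains[0][0]

    heats = [heat(i + 1, config.temperature) for i in range(config.n_chains)]
    records: list[dict] = []
    trees: list[TimeTree] = []
    n_accept = 0
    n_prop = 0

    for gen in range(1, config.n_generations + 1):
        for ci, chain in enumerate(chains):
            state, lp, ll = chain
            new, log_hastings, lik_changed = model.propose(state, rng)
            n_prop += ci == 0
            if not np.isfinite(log_hastings):
                continue
            new_lp = model.log_prior(new)
            if not np.isfinite(new_lp):
                continue
            if beta > 0 and lik_changed:
                new_ll = model.log_likelihood(new)
            else:
                new_ll = ll
            logr = heats[ci] * (beta * (new_ll - ll) + (new_lp - lp)) + log_hastings
            if logr >= 0 or rng.random() < math.exp(max(logr, -745.0)):
                chain[0], chain[1], chain[2] = new, new_lp, new_ll
                n_accept += ci == 0
        if config.n_chains > 1:
            i, j = rng.choice(config.n_chains, size=2, replace=False)
            i, j = int(i), int(j)
            ui = beta * chains[i][2] + chains[i][1]
            uj = beta * chains[j][2] + chains[j][1]
            logr = (heats[i] - heats[j]) * (uj - ui)
            if logr >= 0 or rng.random() < math.exp(max(logr, -745.0)):
                chains[i], chains[j] = chains[j], chains[i]
        if gen % config.sample_every == 0:
            state, lp, ll = chains[0]
            rec = {"generation": gen, "log_likelihood": ll, "log_prior": lp}
            rec.update(model.sample_record(state))
            records.append(rec)
            tree = model.tree_of(state)
            if tree is not None:
                trees.append(tree.copy())

    params = pd.DataFrame.from_records(records)
    trace = Trace(params, trees, run_id=run_id)
    trace.final_state = chains[0][0]
    return trace


def run_independent(model: TargetModel, config: McmcConfig, seed: int) -> list[Trace]:
    """n_runs independent runs with deterministically derived streams."""
    traces = []
    for run in range(config.n_runs):
        rng = np.random.default_rng([int(seed), run])
        traces.append(run_mcmc(model, config, rng, run_id=run))
    if len(traces) >= 2 and traces[0].trees:
        value = asdsf(traces)
        if value > ASDSF_THRESHOLD:
            warnings.warn(
                f"ASDSF {value:.4f} above {ASDSF_THRESHOLD} at termination; "
                "topology may not have converged",
                ConvergenceWarning,
                stacklevel=2,
            )
    return traces


# ------------------------------------------------------------------ diagnostics
def split_frequencies(trace: Trace) -> dict[frozenset[str], float]:
    counts: dict[frozenset[str], int] = {}
    for tree in trace.trees:
        for split in tree.splits():
            counts[split] = counts.get(split, 0) + 1
    n = max(len(trace.trees), 1)
    return {s: c / n for s, c in counts.items()}


def asdsf(traces: list[Trace], min_freq: float = 0.1) -> float:
    """Average standard deviation of split frequencies across runs.

    For every split reaching ``min_freq`` in at least one run, the SD of
    its per-run frequencies (population denominator) enters the average.
    """
    if len(traces) < 2:
        raise ValueError("ASDSF needs at least two independent runs")
    freq_maps = [split_frequencies(t) for t in traces]
    splits = {s for fm in freq_maps for s, f in fm.items() if f >= min_freq}
    if not splits:
        return 0.0
    sds = []
    for s in splits:
        f = np.array([fm.get(s, 0.0) for fm in freq_maps])
        sds.append(float(np.std(f)))  # population (n) denominator
    return float(np.mean(sds))


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.allclose(x, x[0]):
        return float(n)
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * x.var())
    tau = 1.0
    for k in range(1, n // 2):
        if acf[k] <= 0:
            break
        tau += 2.0 * acf[k]
    return float(n / tau)


# -------------------------------------------------------- empirical Bayes prior
@dataclass(frozen=True)
class LognormalPrior:
    """Lognormal prior parameterised by its median and log-scale SD."""

    median: float
    sdlog: float = 1.0

    def log_density(self, x: float) -> float:
        if x <= 0:
            return -math.inf
        z = (math.log(x) - math.log(self.median)) / self.sdlog
        return -math.log(x * self.sdlog * math.sqrt(2 * math.pi)) - 0.5 * z * z

    def sample(self, rng: np.random.Generator) -> float:
        return float(self.median * math.exp(self.sdlog * rng.normal()))

    def quantile(self, q: float) -> float:
        from scipy.stats import norm

        return float(self.median * math.exp(self.sdlog * norm.ppf(q)))


def empirical_bayes_clock_prior(
    tree_height_subs: float, root_calibration: Calibration, sdlog: float = 1.0
) -> LognormalPrior:
    """Weakly informative clock-rate prior from a rough height estimate.

    The median clock rate is the posterior median tree height (expected
    substitutions/site, from an uncalibrated strict-clock run) divided by
    the mean root age under the root calibration; the log-SD of 1 keeps
    the prior broad.
    """
    if tree_height_subs <= 0:
        raise ValueError("tree height in substitutions must be positive")
    if root_calibration.kind != "uniform":
        raise ValueError("root calibration must be a uniform window")
    mean_age = 0.5 * (root_calibration.min_age + root_calibration.max_age)
    return LognormalPrior(median=tree_height_subs / mean_age, sdlog=sdlog)
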