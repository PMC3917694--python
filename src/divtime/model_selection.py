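"""Stepping-stone marginal likelihoods and Bayes-factor comparison.

The marginal likelihood is bridged between posterior (beta = 1) and prior
(beta = 0) through a ladder of power posteriors ``L(theta)^beta p(theta)``.
With samples drawn at the lower power of each rung, each step contributes

    log (1/n) sum_j exp( (beta_k - beta_{k+1}) * logL_j ),

stabilised by log-sum-exp; the run at beta = 1 only warms the sampler up
(the first step is discarded as burn-in).  Beta values are quantiles of a
Beta(shape, 1) distribution, which concentrates rungs near the prior where
the integrand changes fastest.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .mcmc import ConvergenceWarning, McmcConfig, TargetModel, Trace, run_mcmc

__all__ = [
    "SteppingStoneConfig",
    "beta_schedule",
    "stepping_stone_logml",
    "bayes_factor_2ln",
    "interpret_2ln_bf",
]

SS_ASDSF_THRESHOLD = 0.04  # per-step topological convergence threshold


@dataclass
class SteppingStoneConfig:
    n_steps: int = 49  # number of beta values, posterior to prior inclusive
    burn_in_generations: int = 200
    samples_per_step: int = 300
    sample_every: int = 2
    shape: float = 0.4  # Beta(shape, 1) quantile schedule
    n_chains: int = 1
    temperature: float = 0.1
    topology_moves: bool = False

    def __post_init__(self):
        if self.n_steps < 2:
            raise ValueError("need at least 2 steps (posterior and prior)")


def beta_schedule(n_steps: int, shape: float = 0.4) -> np.ndarray:
    """Strictly decreasing beta values from 1 to 0 (Beta(shape,1) quantiles)."""
    if n_steps < 2:
        raise ValueError("need at least 2 beta values")
    if shape <= 0:
        raise ValueError("schedule shape must be positive")
    q = np.linspace(1.0, 0.0, n_steps)
    return q ** (1.0 / shape)


def stepping_stone_logml(
    model: TargetModel,
    ss_config: SteppingStoneConfig,
    seed_or_rng,
    init_state=None,
) -> tuple[float, pd.DataFrame]:
    """Log marginal likelihood plus a per-step report table.

    The report has one row per rung: beta, mean log-likelihood of the
    samples drawn there, the step's log-ml contribution, and the running
    total.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    betas = beta_schedule(ss_config.n_steps, ss_config.shape)
    state = init_state

    def run_at(power: float, n_gens: int, sampling: bool) -> Trace:
        cfg = McmcConfig(
            n_generations=max(n_gens, 1),
            sample_every=ss_config.sample_every if sampling else max(n_gens, 1),
            n_chains=ss_config.n_chains,
            temperature=ss_config.temperature,
            power=power,
            prior_only=False,
            topology_moves=ss_config.topology_moves,
        )
        return run_mcmc(model, cfg, rng, init_state=state)

    # first step: sampling at beta=1 serves only as burn-in
    trace = run_at(1.0, ss_config.burn_in_generations, sampling=False)
    state = trace.final_state

    rows = []
    total = 0.0
    for k in range(len(betas) - 1):
        b_hi, b_lo = betas[k], betas[k + 1]
        trace = run_at(
            b_lo,
            ss_config.burn_in_generations
            + ss_config.samples_per_step * ss_config.sample_every,
            sampling=True,
        )
        state = trace.final_state
        logl = trace.params["log_likelihood"].to_numpy()[-ss_config.samples_per_step :]
        if len(logl) == 0:
            raise RuntimeError(f"no samples at step {k}")
        contrib = float(logsumexp((b_hi - b_lo) * logl) - math.log(len(logl)))
        if not np.isfinite(contrib):
            raise FloatingPointError(f"non-finite contribution at step {k} (beta={b_lo:.4f})")
        if ss_config.topology_moves and trace.trees:
            _check_step_convergence(trace, k)
        total += contrib
        rows.append(
            {
                "step": k,
                "beta": b_lo,
                "mean_logL": float(np.mean(logl)),
                "contribution": contrib,
                "running_logml": total,
            }
        )
    return total, pd.DataFrame(rows)


def _check_step_convergence(trace: Trace, step: int) -> None:
    """Warn when within-step split frequencies look unconverged.

    With a single sampler per rung, the first and second halves of the
    step's tree sample act as pseudo-independent runs; the SD of their
    split frequencies is compared against the per-step threshold.
    """
    from .mcmc import asdsf

    half = len(trace.trees) // 2
    if half < 2:
        return
    a = Trace(trace.params.iloc[:half].reset_index(drop=True), trace.trees[:half])
    b = Trace(trace.params.iloc[half : 2 * half].reset_index(drop=True),
              trace.trees[half : 2 * half])
    value = asdsf([a, b])
    if value > SS_ASDSF_THRESHOLD:
        warnings.warn(
            f"stepping-stone step {step}: split-frequency SD {value:.3f} above "
            f"{SS_ASDSF_THRESHOLD}",
            ConvergenceWarning,
            stacklevel=3,
        )


def bayes_factor_2ln(logml_a: float, logml_b: float) -> float:
    """2 ln Bayes factor of model A over model B."""
    return 2.0 * (logml_a - logml_b)


def interpret_2ln_bf(value: float) -> str:
    """Kass-Raftery evidence bands for 2 ln BF (of A over B)."""
    v = abs(value)
    if v < 2:
        band = "not worth more than a bare mention"
    elif v < 6:
        band = "positive"
    elif v < 10:
        band = "strong"
    else:
        band = "very strong"
    side = "A" if value >= 0 else "B"
    return f"{band} evidence for model {side}"
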