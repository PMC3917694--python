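"""Clock models linking time-trees to substitution branch lengths.

Three models are supported:

* **strict** — every branch evolves at the base rate ``c`` (expected
  substitutions/site/My).
* **IGR** (independent gamma rates, white noise) — the effective branch
  length (substitutions/site) is an independent gamma draw with mean
  ``c * duration`` and variance ``nu * c * duration``; equivalently the
  branch's effective rate has mean ``c`` and variance ``c * nu /
  duration``, so longer branches average over more rate fluctuation and
  vary less.  The variance parameter ``nu`` therefore carries
  substitution units (the convention under which an Exponential(10)
  prior spans near-strict to strongly variable clocks), not absolute
  rate-squared units.
* **TK02** — an autocorrelated lognormal process: each branch's rate is
  lognormal with expectation equal to the parent branch's rate and
  log-variance ``nu * duration``; branches at the root start from ``c``.

Effective branch lengths (substitutions/site) are rate x duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .trees import TimeTree

__all__ = [
    "ClockModel",
    "sample_branch_rates",
    "branch_rates_log_prior",
    "effective_branch_lengths",
]

_KINDS = ("strict", "TK02", "IGR")


@dataclass
class ClockModel:
    kind: str
    c: float  # base clock rate, expected substitutions/site/My
    nu: float = 0.0  # variance parameter (unused for strict)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"clock kind must be one of {_KINDS}")
        if self.c <= 0:
            raise ValueError("base clock rate must be positive")
        if self.nu < 0:
            raise ValueError("clock variance parameter must be non-negative")


def _igr_shape_scale(c: float, nu: float, dur: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # rate ~ gamma with mean c, variance c nu / dur
    # => shape c dur / nu, scale nu / dur
    shape = c * dur / nu
    scale = nu / dur
    return shape, scale


_RATE_FLOOR = 1e-290


def _gamma_draw(rng: np.random.Generator, shape: float, scale: float) -> float:
    """Gamma variate robust to tiny shapes.

    For shape < 0.1 the draw is formed in log space via the boosting
    identity G(k) = G(k+1) * U^(1/k), so values far below the double
    underflow threshold of the direct generator remain representable;
    anything below a hard floor is clamped (the floor's prior mass is
    negligible for every parameter combination the model visits).
    """
    if shape >= 0.1:
        return max(float(rng.gamma(shape, scale)), _RATE_FLOOR)
    g1 = rng.gamma(shape + 1.0)
    logu = math.log(rng.random())
    log_rate = math.log(max(g1, 1e-300)) + math.log(scale) + logu / shape
    if log_rate < math.log(_RATE_FLOOR):
        return _RATE_FLOOR
    return math.exp(log_rate)


def sample_branch_rates(clock: ClockModel, tree: TimeTree, seed_or_rng) -> np.ndarray:
    """Per-branch effective rates, indexed by child node (root entry = c)."""
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator
    ) else seed_or_rng
    n = tree.n_nodes
    rates = np.full(n, clock.c)
    if clock.kind == "strict" or clock.nu == 0.0:
        return rates
    dur = tree.durations()
    if np.any(dur[np.arange(n) != tree.root] <= 0):
        raise ValueError("branch durations must be strictly positive for relaxed clocks")
    if clock.kind == "IGR":
        for node in range(n):
            if node == tree.root:
                continue
            shape, scale = _igr_shape_scale(clock.c, clock.nu, dur[node])
            rates[node] = _gamma_draw(rng, float(shape), float(scale))
    else:  # TK02
        for node in tree.preorder():
            if node == tree.root:
                continue
            parent = tree.parent[node]
            parent_rate = clock.c if parent == tree.root else rates[parent]
            var = clock.nu * dur[node]
            mu = math.log(parent_rate) - var / 2.0
            rates[node] = math.exp(rng.normal(mu, math.sqrt(var)))
    return rates


def branch_rates_log_prior(clock: ClockModel, tree: TimeTree, rates: np.ndarray) -> float:
    """Log prior density of the branch rates under the clock model.

    Strict: 0 if every rate equals ``c``, else -inf.  Non-positive rates
    under a relaxed clock yield -inf rather than an exception.
    """
    root = tree.root
    idx = np.array([i for i in range(tree.n_nodes) if i != root])
    r = np.asarray(rates, dtype=float)[idx]
    if clock.kind == "strict":
        return 0.0 if np.allclose(r, clock.c, rtol=1e-12, atol=0.0) else -math.inf
    if clock.nu <= 0:
        raise ValueError("relaxed clock needs a positive variance parameter")
    if np.any(r <= 0):
        return -math.inf
    dur = tree.durations()[idx]
    if np.any(dur <= 0):
        return -math.inf
    if clock.kind == "IGR":
        shape, scale = _igr_shape_scale(clock.c, clock.nu, dur)
        return float(
            np.sum(
                -gammaln(shape)
                - shape * np.log(scale)
                + (shape - 1.0) * np.log(r)
                - r / scale
            )
        )
    # TK02: lognormal around the parent branch's rate
    total = 0.0
    all_rates = np.asarray(rates, dtype=float)
    for node in range(tree.n_nodes):
        if node == root:
            continue
        parent = tree.parent[node]
        parent_rate = clock.c if parent == root else all_rates[parent]
        if parent_rate <= 0:
            return -math.inf
        t = tree.ages[parent] - tree.ages[node]
        var = clock.nu * t
        x = all_rates[node]
        mu = math.log(parent_rate) - var / 2.0
        total += (
            -math.log(x)
            - 0.5 * math.log(2.0 * math.pi * var)
            - (math.log(x) - mu) ** 2 / (2.0 * var)
        )
    return float(total)


def effective_branch_lengths(
    clock: ClockModel, tree: TimeTree, rates: np.ndarray | None = None
) -> np.ndarray:
    """Substitutions/site per branch: rate x duration (root entry 0)."""
    dur = tree.durations()
    if clock.kind == "strict" or rates is None:
        return clock.c * dur
    return np.asarray(rates, dtype=float) * dur
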