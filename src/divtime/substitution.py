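"""GTR+Gamma+I substitution models.

The general time-reversible rate matrix is parameterised by six
exchangeabilities and four stationary base frequencies and normalised so
that the expected number of substitutions per site per unit branch length
is one.  Among-site rate variation uses a discrete gamma with four
equal-probability categories (category rate = conditional mean of its bin)
plus a proportion of invariant sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

__all__ = ["SubstitutionModel", "discretize_gamma", "jc_model"]

_PAIRS = ["AC", "AG", "AT", "CG", "CT", "GT"]


def discretize_gamma(alpha: float, ncat: int = 4) -> np.ndarray:
    """Equal-probability discrete gamma category rates with mean one.

    The rate of category *k* is the mean of the gamma(alpha, 1/alpha)
    density conditional on the k-th quantile bin (the mean-of-bin rule,
    not the median rule).
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if alpha > 1e6:  # effectively rate-homogeneous
        return np.ones(ncat)
    # bin boundaries of gamma(alpha, scale=1/alpha)
    probs = np.arange(1, ncat) / ncat
    bounds = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    # E[X | a < X < b] * P(a < X < b) = (alpha/alpha) * [P(G(alpha+1) < b') - ...]
    upper = gammainc(alpha + 1.0, alpha * bounds[1:])
    lower = gammainc(alpha + 1.0, alpha * bounds[:-1])
    rates = (upper - lower) * ncat
    rates = rates / rates.mean()  # exact renormalisation against ppf round-off
    return rates


@dataclass
class SubstitutionModel:
    """GTR exchangeabilities + base frequencies + Gamma(4) + invariant sites."""

    exchangeabilities: np.ndarray = field(default_factory=lambda: np.ones(6))
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    alpha: float = 1.0
    p_inv: float = 0.0
    ncat: int = 4
    # instances are treated as immutable after construction, so the
    # eigensystem and category rates are computed once and cached
    _eig: tuple | None = field(default=None, init=False, repr=False, compare=False)
    _cats: np.ndarray | None = field(default=None, init=False, repr=False, compare=False)

    def __post_init__(self):
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.exchangeabilities.shape != (6,) or np.any(self.exchangeabilities <= 0):
            raise ValueError("need 6 positive exchangeabilities (AC, AG, AT, CG, CT, GT)")
        if self.freqs.shape != (4,) or np.any(self.freqs <= 0):
            raise ValueError("need 4 positive base frequencies")
        if not np.isclose(self.freqs.sum(), 1.0, atol=1e-8):
            raise ValueError("base frequencies must sum to 1")
        self.freqs = self.freqs / self.freqs.sum()
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must be in [0, 1)")

    # ------------------------------------------------------------ rate matrix
    def rate_matrix(self) -> np.ndarray:
        """Normalised GTR matrix Q with mean rate 1 (rows sum to zero)."""
        r = self.exchangeabilities
        pi = self.freqs
        Q = np.zeros((4, 4))
        idx = 0
        for i in range(4):
            for j in range(i + 1, 4):
                Q[i, j] = r[idx] * pi[j]
                Q[j, i] = r[idx] * pi[i]
                idx += 1
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -np.dot(pi, np.diag(Q))
        return Q / mu

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigendecomposition of Q via the symmetrised form (reversibility)."""
        if self._eig is not None:
            return self._eig
        Q = self.rate_matrix()
        pi = self.freqs
        d = np.sqrt(pi)
        S = (Q * d[:, None]) / d[None, :]  # diag(sqrt(pi)) Q diag(1/sqrt(pi))
        S = (S + S.T) / 2.0
        evals, U = np.linalg.eigh(S)
        right = U / d[:, None]        # rows scaled: P = right @ diag(e^{lt}) @ left
        left = U.T * d[None, :]
        self._eig = (evals, right, left)
        return self._eig

    def category_rates(self) -> np.ndarray:
        if self._cats is None:
            self._cats = discretize_gamma(self.alpha, self.ncat)
        return self._cats

    def transition_matrices(self, lengths: np.ndarray) -> np.ndarray:
        """P(t) for an array of branch lengths; shape lengths.shape + (4, 4)."""
        evals, right, left = self.eigensystem()
        t = np.asarray(lengths, dtype=float)
        expo = np.exp(t[..., None] * evals)  # (..., 4)
        P = np.einsum("ik,...k,kj->...ij", right, expo, left)
        return np.clip(P, 0.0, None)


def jc_model(alpha: float = np.inf, p_inv: float = 0.0, ncat: int = 4) -> SubstitutionModel:
    """Jukes-Cantor: equal exchangeabilities and frequencies."""
    a = 1e9 if np.isinf(alpha) else alpha
    return SubstitutionModel(np.ones(6), np.full(4, 0.25), alpha=a, p_inv=p_inv, ncat=ncat)
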