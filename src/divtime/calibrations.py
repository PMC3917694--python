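"""Node-age calibrations and the calibrated uniform tree prior.

Calibrations are densities on node ages: a uniform window (used on the
root, e.g. for a vicariance event with both minimum and maximum bounds)
or an offset exponential (a fossil minimum age ``x0`` with rate
``lambda = 1/(mean - x0)``, putting most mass just above the minimum but
allowing arbitrarily older ages).  Each calibration is bound to a clade
via a monophyly constraint.

The tree prior is the uniform prior extended to calibrated clock trees:
given the root age and the calibrated node ages, the remaining internal
node ages are uniform over the order polytope {child younger than parent,
tips at zero}.  The polytope volume is computed exactly by recursive
piecewise-polynomial integration over the tree (in root-age-scaled
coordinates, where all polynomial coefficients stay positive and the
computation is numerically benign), so the density is properly normalised
conditional on the calibrated ages.  The same recursion yields an exact
sequential (inverse-CDF) sampler for the free node ages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .trees import TimeTree

__all__ = [
    "Calibration",
    "CalibrationSet",
    "calibration_log_density",
    "tree_age_log_prior",
    "TreeAgePrior",
    "sample_node_ages",
]


# --------------------------------------------------------------- calibrations
@dataclass(frozen=True)
class Calibration:
    """A density on one node age, attached to a clade by taxon set."""

    kind: str  # "uniform" | "offset_exponential"
    clade: frozenset[str] = frozenset()
    min_age: float = 0.0  # uniform lower bound
    max_age: float = 0.0  # uniform upper bound
    offset: float = 0.0  # offset-exponential hard minimum x0
    mean: float = 0.0  # mean of the full offset-exponential distribution

    def __post_init__(self):
        if self.kind == "uniform":
            if self.max_age < self.min_age:
                raise ValueError("uniform calibration needs max_age >= min_age")
        elif self.kind == "offset_exponential":
            if self.mean <= self.offset:
                raise ValueError("offset-exponential mean must exceed the offset")
        else:
            raise ValueError(f"unknown calibration kind {self.kind!r}")

    @property
    def rate(self) -> float:
        """Exponential rate lambda = 1/(mean - offset)."""
        return 1.0 / (self.mean - self.offset)

    def log_density(self, age: float) -> float:
        return calibration_log_density(self, age)

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "uniform":
            if self.max_age == self.min_age:
                return self.min_age
            return float(rng.uniform(self.min_age, self.max_age))
        return float(self.offset + rng.exponential(1.0 / self.rate))

    @staticmethod
    def uniform(min_age: float, max_age: float, clade=()) -> "Calibration":
        return Calibration("uniform", frozenset(clade), min_age=min_age, max_age=max_age)

    @staticmethod
    def offset_exponential(offset: float, mean: float, clade=()) -> "Calibration":
        return Calibration("offset_exponential", frozenset(clade), offset=offset, mean=mean)


def calibration_log_density(cal: Calibration, age: float) -> float:
    """Log density of a calibration at ``age`` (-inf outside support)."""
    if not np.isfinite(age):
        return -math.inf
    if cal.kind == "uniform":
        if cal.max_age == cal.min_age:  # point calibration
            return 0.0 if age == cal.min_age else -math.inf
        if cal.min_age <= age <= cal.max_age:
            return -math.log(cal.max_age - cal.min_age)
        return -math.inf
    lam = cal.rate
    if age < cal.offset:
        return -math.inf
    return math.log(lam) - lam * (age - cal.offset)


@dataclass
class CalibrationSet:
    """Root window + offset-exponential node calibrations + constraints.

    Every calibration's clade is implicitly a monophyly constraint;
    ``extra_constraints`` adds uncalibrated ones (e.g. a rooting
    constraint separating one taxon from all others).
    """

    root: Calibration
    nodes: list[Calibration] = field(default_factory=list)
    extra_constraints: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self):
        if self.root.kind != "uniform":
            raise ValueError("root calibration must be a uniform window")
        clades = [c.clade for c in self.nodes if c.clade] + list(self.extra_constraints)
        for i, a in enumerate(clades):
            for b in clades[i + 1 :]:
                if a & b and not (a <= b or b <= a):
                    raise ValueError(
                        f"calibration clades overlap without nesting: {sorted(a)[:3]}... "
                        f"vs {sorted(b)[:3]}..."
                    )

    @property
    def constraints(self) -> list[frozenset[str]]:
        return [c.clade for c in self.nodes if c.clade] + list(self.extra_constraints)


# ----------------------------------------------- piecewise polynomial helpers
class _PiecePoly:
    """Piecewise polynomial on [0, 1] with non-negative coefficients.

    Breakpoints partition [0, 1]; each segment stores ascending-power
    coefficients in the global coordinate.  Only the operations needed by
    the volume recursion are provided: product, running integral from 0,
    and evaluation.
    """

    __slots__ = ("breaks", "coeffs")

    def __init__(self, breaks: np.ndarray, coeffs: list[np.ndarray]):
        self.breaks = breaks  # (m+1,) with breaks[0]=0, breaks[-1]=1
        self.coeffs = coeffs  # m arrays

    @staticmethod
    def const(value: float) -> "_PiecePoly":
        return _PiecePoly(np.array([0.0, 1.0]), [np.array([value])])

    @staticmethod
    def step(at: float, value: float) -> "_PiecePoly":
        """0 on [0, at), value on [at, 1]."""
        if at <= 0.0:
            return _PiecePoly.const(value)
        if at >= 1.0:
            return _PiecePoly.const(0.0)
        return _PiecePoly(np.array([0.0, at, 1.0]), [np.array([0.0]), np.array([value])])

    def __mul__(self, other: "_PiecePoly") -> "_PiecePoly":
        breaks = np.union1d(self.breaks, other.breaks)
        coeffs = []
        for lo, hi in zip(breaks[:-1], breaks[1:]):
            mid = 0.5 * (lo + hi)
            a = self._segment(mid)
            b = other._segment(mid)
            coeffs.append(np.convolve(a, b))
        return _PiecePoly(breaks, coeffs)

    def _segment(self, t: float) -> np.ndarray:
        k = int(np.searchsorted(self.breaks, t, side="right") - 1)
        k = min(max(k, 0), len(self.coeffs) - 1)
        return self.coeffs[k]

    def integral(self) -> "_PiecePoly":
        """F(t) = int_0^t f(s) ds, continuous across breakpoints."""
        coeffs = []
        acc = 0.0
        for (lo, hi), c in zip(zip(self.breaks[:-1], self.breaks[1:]), self.coeffs):
            anti = np.concatenate([[0.0], c / np.arange(1, len(c) + 1)])
            shift = acc - _polyval(anti, lo)
            anti = anti.copy()
            anti[0] += shift
            coeffs.append(anti)
            acc = _polyval(anti, hi)
        return _PiecePoly(self.breaks.copy(), coeffs)

    def __call__(self, t: float) -> float:
        return _polyval(self._segment(t), t)


def _polyval(coeffs: np.ndarray, t: float) -> float:
    out = 0.0
    for c in coeffs[::-1]:
        out = out * t + c
    return float(out)


# ------------------------------------------------------------- the tree prior
class TreeAgePrior:
    """Calibrated uniform tree prior with per-topology caching.

    Resolution of calibration clades to node ids and the feasible-region
    volume are cached on the tree's topology version and on the tuple of
    (root age, calibrated ages), since free-node moves leave both
    unchanged.
    """

    def __init__(self, cals: CalibrationSet):
        self.cals = cals
        self._resolve_cache: tuple[int, list[int]] | None = None
        self._vol_cache: dict[tuple, float] = {}

    def resolve(self, tree: TimeTree) -> list[int] | None:
        """Node id per node calibration, or None if a clade is absent."""
        if self._resolve_cache is not None and self._resolve_cache[0] == tree.topology_version:
            return self._resolve_cache[1]
        taxon_sets = tree.clade_taxon_sets()
        lookup = {tips: node for node, tips in taxon_sets.items()}
        all_constraints = {c.clade for c in self.cals.nodes} | set(self.cals.extra_constraints)
        for clade in all_constraints:
            if clade and clade not in lookup:
                return None
        ids = [lookup[c.clade] for c in self.cals.nodes]
        self._resolve_cache = (tree.topology_version, ids)
        return ids

    def log_density(self, tree: TimeTree) -> float:
        ids = self.resolve(tree)
        if ids is None:
            return -math.inf
        has_parent = tree.parent >= 0
        if np.any(tree.ages[tree.parent[has_parent]] <= tree.ages[has_parent]):
            return -math.inf  # age-order violation
        root = tree.root
        root_age = float(tree.ages[root])
        total = calibration_log_density(self.cals.root, root_age)
        fixed: dict[int, float] = {}
        for cal, node in zip(self.cals.nodes, ids):
            if node == root:
                return -math.inf
            age = float(tree.ages[node])
            total += calibration_log_density(cal, age)
            fixed[node] = age
        if not np.isfinite(total):
            return -math.inf
        logvol = self._log_volume(tree, fixed, root_age)
        if not np.isfinite(logvol):
            return -math.inf
        return total - logvol

    def _log_volume(self, tree: TimeTree, fixed: dict[int, float], root_age: float) -> float:
        key = (tree.topology_version, tuple(sorted(fixed.items())), root_age)
        if key in self._vol_cache:
            return self._vol_cache[key]
        logvol = log_free_age_volume(tree, fixed, root_age)
        if len(self._vol_cache) > 16:
            self._vol_cache.clear()
        self._vol_cache[key] = logvol
        return logvol


def _volume_functions(
    tree: TimeTree, fixed: dict[int, float], root_age: float
) -> tuple[dict[int, _PiecePoly], int]:
    """Per-node scaled volume functions V_v(t) and the free-node count.

    ``V_v(t)`` is the volume (in root-age-scaled coordinates) of feasible
    free ages in the subtree rooted at v, as a function of v's parent age.
    Tips give 1; a fixed node at scaled age a gives a step at a; a free
    node integrates the product of its children's functions.
    """
    scale = root_age
    funcs: dict[int, _PiecePoly] = {}
    n_free = 0
    root = tree.root
    for node in tree.postorder():
        if node == root:
            continue
        if tree.is_tip(node):
            funcs[node] = _PiecePoly.const(1.0)
        elif node in fixed:
            a = fixed[node] / scale
            if not (0.0 < a < 1.0 + 1e-12):
                funcs[node] = _PiecePoly.const(0.0)
                continue
            val = 1.0
            for ch in tree.children[node]:
                val *= funcs[ch](min(a, 1.0))
            funcs[node] = _PiecePoly.step(min(a, 1.0), val)
        else:
            n_free += 1
            prod = funcs[tree.children[node][0]] * funcs[tree.children[node][1]]
            funcs[node] = prod.integral()
    return funcs, n_free


def log_free_age_volume(tree: TimeTree, fixed: dict[int, float], root_age: float) -> float:
    """Log volume of the free internal ages' feasible region (My^n_free)."""
    funcs, n_free = _volume_functions(tree, fixed, root_age)
    top = 1.0
    for ch in tree.children[tree.root]:
        top *= funcs[ch](1.0)
    if top <= 0.0:
        return -math.inf
    return math.log(top) + n_free * math.log(root_age)


def tree_age_log_prior(tree: TimeTree, cals: CalibrationSet) -> float:
    """Log density of the calibrated uniform tree prior at this tree.

    Returns -inf when a monophyly constraint is violated, when ages fall
    outside calibration supports, or when the age configuration is
    order-infeasible.
    """
    return TreeAgePrior(cals).log_density(tree)


# ------------------------------------------------------------------ sampling
def sample_node_ages(
    tree: TimeTree,
    cals: CalibrationSet,
    rng: np.random.Generator,
    max_tries: int = 100_000,
) -> None:
    """Draw node ages in place from the calibrated uniform tree prior.

    Root and calibrated ages are drawn from their calibration densities
    (with rejection to enforce nesting order); the free internal ages are
    then drawn exactly by sequential inverse-CDF sampling using the same
    piecewise-polynomial subtree volumes that normalise the prior.
    """
    prior = TreeAgePrior(cals)
    ids = prior.resolve(tree)
    if ids is None:
        raise ValueError("tree does not satisfy the calibration monophyly constraints")
    root = tree.root

    # ancestor relations among calibrated nodes (and root)
    def ancestors(node: int) -> list[int]:
        out = []
        p = tree.parent[node]
        while p >= 0:
            out.append(int(p))
            p = tree.parent[p]
        return out

    anc = {node: set(ancestors(node)) for node in ids}
    for _ in range(max_tries):
        root_age = cals.root.sample(rng)
        fixed = {node: cal.sample(rng) for cal, node in zip(cals.nodes, ids)}
        ok = True
        for node, age in fixed.items():
            if age >= root_age:
                ok = False
                break
            for other in fixed:
                if other in anc[node] and fixed[other] <= age:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            funcs, _ = _volume_functions(tree, fixed, root_age)
            feas = 1.0
            for ch in tree.children[root]:
                feas *= funcs[ch](1.0)
            if feas > 0.0:
                break
    else:
        raise ValueError("could not draw feasible calibrated ages; check calibrations")

    ages = tree.ages
    ages[:] = 0.0
    ages[root] = root_age
    for node, age in fixed.items():
        ages[node] = age
    scale = root_age
    for node in tree.preorder():
        if node == root or tree.is_tip(node) or node in fixed:
            continue
        tp = ages[tree.parent[node]] / scale
        G = funcs[node]  # running integral of the children product
        total = G(tp)
        if total <= 0.0:
            raise ValueError("zero feasible volume during sequential sampling")
        target = rng.uniform() * total
        lo = 0.0
        age = brentq(lambda s: G(s) - target, lo, tp, xtol=1e-12 * scale + 1e-15)
        ages[node] = float(age * scale)
    tree.validate()
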