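"""Synthetic data generation: calibrated time-trees, clock-varying branch
rates, and partitioned alignments.

The generator emulates the structure of a multi-locus passerine dating
study: seven nuclear genes (four protein-coding, partitioned into codon
positions 1+2 vs 3; three introns), a root age calibrated by a uniform
vicariance window, five fossil clades with offset-exponential minima, a
rooting constraint separating one taxon from all others, and relaxed-clock
rate variation across branches.  Everything is deterministic given a seed,
so downstream stages (likelihood, MCMC, model selection, gene evaluation)
are testable without any external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .alignment import MultiGeneAlignment, PartitionScheme, build_partition_scheme
from .calibrations import Calibration, CalibrationSet, sample_node_ages
from .clocks import ClockModel, effective_branch_lengths, sample_branch_rates
from .substitution import SubstitutionModel
from .trees import TimeTree, random_constrained_topology

__all__ = [
    "FixtureSpec",
    "sample_calibrated_tree",
    "simulate_alignment",
    "make_passerine_fixture",
    "PasserineFixture",
    "write_fixture",
]

#: the seven-gene template: (name, length, coding?)
GENE_TEMPLATE = [
    ("MOS", 622, True),
    ("MYC", 504, True),
    ("GAPDH", 419, False),
    ("MB", 800, False),
    ("ODC1", 749, False),
    ("RAG1", 2947, True),
    ("RAG2", 1152, True),
]

#: fossil calibration template: (clade label, hard minimum age in My)
FOSSIL_TEMPLATE = [
    ("Meliphagidae", 10.4),
    ("Orthonychidae", 16.3),
    ("Cracticidae", 16.3),
    ("Oriolidae", 16.3),
    ("Certhioidea", 18.0),
]

FOSSIL_MEAN = 58.0  # mean of every offset-exponential fossil prior (My)
ROOT_WINDOW = (52.0, 85.0)  # vicariance window on the root age (My)


@dataclass
class FixtureSpec:
    """Everything needed to simulate one multi-gene data set."""

    n_taxa: int
    gene_names: list[str]
    gene_lengths: list[int]
    coding_flags: list[bool]
    clock: ClockModel
    calibrations: CalibrationSet
    models: list[SubstitutionModel]  # one per partition of the scheme
    multipliers: np.ndarray  # per partition, length-weighted mean 1
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if any(l <= 0 for l in self.gene_lengths):
            raise ValueError("gene lengths must be positive")
        self.multipliers = np.asarray(self.multipliers, dtype=float)
        if np.any(self.multipliers <= 0):
            raise ValueError("partition multipliers must be positive")
        w = self.scheme.lengths()
        mean = float(np.dot(w, self.multipliers) / w.sum())
        if abs(mean - 1.0) > 1e-8:
            raise ValueError("multipliers must have length-weighted mean 1")
        if len(self.models) != len(self.scheme):
            raise ValueError("need one substitution model per partition")

    @property
    def scheme(self) -> PartitionScheme:
        return build_partition_scheme(self.gene_names, self.gene_lengths, self.coding_flags)


def sample_calibrated_tree(
    calibrations: CalibrationSet,
    n_taxa: int,
    seed_or_rng,
    taxa: list[str] | None = None,
    topology: TimeTree | None = None,
) -> TimeTree:
    """Draw a rooted binary time-tree from the calibrated uniform tree prior.

    Topology is a random resolved rooted topology honoring the calibration
    (monophyly) clades unless a fixed one is supplied; node ages are then
    drawn exactly from the calibrated prior (root within its window, every
    calibrated node above its offset, children younger than parents).
    """
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(
        seed_or_rng
    )
    if topology is None:
        if taxa is None:
            constrained = sorted({t for c in calibrations.constraints for t in c})
            if n_taxa < max(len(constrained), 3):
                raise ValueError("n_taxa smaller than the constrained taxon set")
            filler = [f"taxon{i + 1}" for i in range(n_taxa) if f"taxon{i + 1}" not in constrained]
            taxa = constrained + filler[: n_taxa - len(constrained)]
        tree = random_constrained_topology(taxa, calibrations.constraints, rng)
    else:
        tree = topology.copy()
    sample_node_ages(tree, calibrations, rng)
    return tree


def simulate_alignment(
    tree: TimeTree,
    rates: np.ndarray,
    spec: FixtureSpec,
    rng: np.random.Generator | None = None,
) -> MultiGeneAlignment:
    """Forward simulation of the partitioned alignment along the tree.

    Per site, with probability ``p_inv`` the site is invariant (every taxon
    copies the root state); otherwise one of the equal-probability gamma
    categories is drawn and substitutions accrue at rate x duration x
    partition multiplier x category rate.  Root states come from the
    stationary frequencies.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    scheme = spec.scheme
    blens = effective_branch_lengths(spec.clock, tree, rates)
    n = tree.n_tips
    bases = np.array(list("ACGT"))
    gene_mats = {
        g: np.empty((n, L), dtype="<U1") for g, L in zip(spec.gene_names, spec.gene_lengths)
    }
    for part, model, mult in zip(scheme, spec.models, spec.multipliers):
        L = len(part.sites)
        cat_rates = model.category_rates()
        # per-site rate: 0 for invariant sites, else the category rate
        invariant = rng.random(L) < model.p_inv
        cats = rng.integers(0, model.ncat, size=L)
        site_rate = np.where(invariant, 0.0, cat_rates[cats])
        states = np.empty((tree.n_nodes, L), dtype=np.int64)
        root = tree.root
        states[root] = rng.choice(4, size=L, p=model.freqs)
        for node in tree.preorder():
            if node == root:
                continue
            lengths = blens[node] * mult * site_rate  # (L,)
            P = model.transition_matrices(lengths)  # (L, 4, 4)
            probs = P[np.arange(L), states[tree.parent[node]]]  # (L, 4)
            u = rng.random(L)
            states[node] = np.minimum((u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1), 3)
        chars = bases[states[:n]]
        gene_mats[part.gene][:, list(part.sites)] = chars
    return MultiGeneAlignment(tree.taxa, gene_mats)


# ------------------------------------------------------------ the 7-gene kit
def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def default_calibrations(taxa_by_clade: dict[str, list[str]], all_taxa: list[str]) -> CalibrationSet:
    """Root vicariance window + five offset-exponential fossil calibrations."""
    nodes = [
        Calibration.offset_exponential(offset, FOSSIL_MEAN, clade=taxa_by_clade[label])
        for label, offset in FOSSIL_TEMPLATE
    ]
    rooting = frozenset(t for t in all_taxa if t != "Acanthisitta")
    return CalibrationSet(
        root=Calibration.uniform(*ROOT_WINDOW, clade=all_taxa),
        nodes=nodes,
        extra_constraints=[rooting],
    )


def _default_models(scheme: PartitionScheme) -> tuple[list[SubstitutionModel], np.ndarray]:
    """Plausible nuclear-gene substitution parameters per partition."""
    models, mults = [], []
    for part in scheme:
        if part.name.endswith("_pos12"):
            models.append(
                SubstitutionModel(
                    np.array([1.0, 4.0, 1.0, 1.0, 4.0, 1.0]),
                    np.array([0.28, 0.22, 0.22, 0.28]),
                    alpha=0.5,
                    p_inv=0.4,
                )
            )
            mults.append(0.45)
        elif part.name.endswith("_pos3"):
            models.append(
                SubstitutionModel(
                    np.array([1.0, 6.0, 1.0, 1.0, 6.0, 1.0]),
                    np.array([0.22, 0.28, 0.28, 0.22]),
                    alpha=2.0,
                    p_inv=0.02,
                )
            )
            mults.append(2.6)
        else:  # intron
            models.append(
                SubstitutionModel(
                    np.array([1.0, 3.5, 0.8, 1.2, 3.5, 1.0]),
                    np.array([0.30, 0.20, 0.20, 0.30]),
                    alpha=1.5,
                    p_inv=0.1,
                )
            )
            mults.append(1.25)
    mults = np.array(mults)
    w = scheme.lengths()
    mults = mults / (np.dot(w, mults) / w.sum())
    return models, mults


class PasserineFixture(NamedTuple):
    alignment: MultiGeneAlignment
    tree: TimeTree
    clock: ClockModel
    calibrations: CalibrationSet
    spec: FixtureSpec
    rates: np.ndarray


def make_passerine_fixture(
    scale: float,
    seed: int,
    n_taxa: int = 55,
    clock: ClockModel | None = None,
) -> PasserineFixture:
    """Simulate the seven-gene study bundle at a given length scale.

    ``scale`` multiplies the gene lengths (622, 504, 419, 800, 749, 2947,
    1152 bp; rounded half-up), so scale=1 gives 7,193 sites.  The bundle
    contains the alignment, the true generating tree, the clock model, the
    calibration set (root Uniform(52, 85) plus five offset-exponential
    fossils), the simulation spec, and the true branch rates.
    """
    if not (0 < scale <= 1):
        raise ValueError("scale must be in (0, 1]")
    if n_taxa < 12:
        raise ValueError("the seven-gene fixture needs at least 12 taxa")
    rng = np.random.default_rng(seed)
    clock = clock if clock is not None else ClockModel("IGR", c=0.002, nu=1.5e-3)

    gene_names = [g for g, _, _ in GENE_TEMPLATE]
    gene_lengths = [_round_half_up(scale * L) for _, L, _ in GENE_TEMPLATE]
    coding = [c for _, _, c in GENE_TEMPLATE]

    # taxa: one rooting taxon + five fossil clades + free taxa
    n_rest = n_taxa - 1
    base_sizes = np.array([3, 2, 3, 3, 4], dtype=float) * (n_rest / 24.0)
    sizes = np.maximum(2, np.round(base_sizes).astype(int))
    while sizes.sum() > n_rest - 1:
        sizes[int(np.argmax(sizes))] -= 1
    taxa_by_clade = {}
    taxa = ["Acanthisitta"]
    for (label, _), size in zip(FOSSIL_TEMPLATE, sizes):
        members = [f"{label}_{i + 1}" for i in range(size)]
        taxa_by_clade[label] = members
        taxa.extend(members)
    taxa.extend(f"taxon{i + 1}" for i in range(n_taxa - len(taxa)))
    cals = default_calibrations(taxa_by_clade, taxa)

    scheme = build_partition_scheme(gene_names, gene_lengths, coding)
    models, mults = _default_models(scheme)
    spec = FixtureSpec(
        n_taxa=n_taxa,
        gene_names=gene_names,
        gene_lengths=gene_lengths,
        coding_flags=coding,
        clock=clock,
        calibrations=cals,
        models=models,
        multipliers=mults,
        seed=seed,
    )
    tree = sample_calibrated_tree(cals, n_taxa, rng, taxa=taxa)
    rates = sample_branch_rates(clock, tree, rng)
    aln = simulate_alignment(tree, rates, spec, rng=rng)
    return PasserineFixture(aln, tree, clock, cals, spec, rates)


def write_fixture(fixture: PasserineFixture, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle: per-gene FASTAs, a NEXUS with charsets, the true
    tree (Newick, branch lengths in My), and a YAML calibration config."""
    from .configio import calibration_set_to_yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for gene in fixture.alignment.gene_names:
        p = outdir / f"{gene}.fasta"
        fixture.alignment.to_fasta(p, gene=gene)
        paths[f"fasta:{gene}"] = p
    nex = outdir / "alignment.nex"
    fixture.alignment.to_nexus(nex)
    paths["nexus"] = nex
    tre = outdir / "true_tree.nwk"
    tre.write_text(fixture.tree.to_newick() + "\n")
    paths["tree"] = tre
    cal = outdir / "calibrations.yaml"
    cal.write_text(calibration_set_to_yaml(fixture.calibrations))
    paths["calibrations"] = cal
    return paths
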