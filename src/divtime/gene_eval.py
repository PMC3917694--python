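"""Per-gene divergence-time performance: congruence, precision, interval
overlap, saturation, and rate-based root-age back-calculation.

Single-gene dating runs are compared with the combined analysis node by
node, matching nodes across analyses by taxon clade.  Congruence is
Kendall's tau-b between median ages over the shared nodes; precision is
the mean 95% credibility-interval width; interval overlap is measured
pairwise (Jaccard on intervals) and jointly (existence of a common
intersection); saturation pairs uncorrected p-distances with MRCA ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .alignment import MultiGeneAlignment, UndefinedDistanceError, p_distance
from .summaries import NodeAgeSummary
from .trees import TimeTree

__all__ = [
    "GeneComparison",
    "RateEstimate",
    "compare_gene",
    "kendall_tau",
    "ci_width_table",
    "kruskal_wallis",
    "ci_overlap",
    "saturation_table",
    "rate_based_root_age",
]

Summaries = dict[frozenset[str], NodeAgeSummary]


@dataclass
class GeneComparison:
    """Node-by-node comparison of one gene against the combined analysis."""

    gene: str
    matched: list[frozenset[str]]
    missing: list[frozenset[str]]  # combined nodes unrecovered by the gene
    gene_summaries: Summaries = field(default_factory=dict)
    combined_summaries: Summaries = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for split in self.matched:
            g, c = self.gene_summaries[split], self.combined_summaries[split]
            rows.append(
                {
                    "clade": "|".join(sorted(split)),
                    "gene_median": g.median,
                    "gene_ci_lower": g.lower,
                    "gene_ci_upper": g.upper,
                    "combined_median": c.median,
                    "combined_ci_lower": c.lower,
                    "combined_ci_upper": c.upper,
                }
            )
        for split in self.missing:
            c = self.combined_summaries[split]
            rows.append(
                {
                    "clade": "|".join(sorted(split)),
                    "gene_median": np.nan,
                    "gene_ci_lower": np.nan,
                    "gene_ci_upper": np.nan,
                    "combined_median": c.median,
                    "combined_ci_lower": c.lower,
                    "combined_ci_upper": c.upper,
                }
            )
        return pd.DataFrame(rows)

    def medians(self) -> tuple[np.ndarray, np.ndarray]:
        g = np.array([self.gene_summaries[s].median for s in self.matched])
        c = np.array([self.combined_summaries[s].median for s in self.matched])
        return g, c


def compare_gene(gene: str, gene_summaries: Summaries, combined_summaries: Summaries) -> GeneComparison:
    matched = [s for s in combined_summaries if s in gene_summaries]
    missing = [s for s in combined_summaries if s not in gene_summaries]
    return GeneComparison(gene, matched, missing, dict(gene_summaries), dict(combined_summaries))


@dataclass(frozen=True)
class RateEstimate:
    """An externally estimated substitution rate (subs/site/My)."""

    gene: str
    rate: float
    interval: tuple[float, float] | None = None
    provenance: str = ""

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be positive")


def kendall_tau(gene_medians, combined_medians) -> tuple[float, float]:
    """Kendall's tau-b (tie-corrected) and its two-sided p-value.

    Exact enumeration p-value for n <= 10 without ties, normal
    approximation otherwise.
    """
    x = np.asarray(gene_medians, float)
    y = np.asarray(combined_medians, float)
    if len(x) < 2 or len(x) != len(y):
        raise ValueError("need >= 2 matched nodes")
    has_ties = len(np.unique(x)) < len(x) or len(np.unique(y)) < len(y)
    method = "exact" if (len(x) <= 10 and not has_ties) else "asymptotic"
    res = stats.kendalltau(x, y, variant="b", method=method)
    return float(res.statistic), float(res.pvalue)


def ci_width_table(per_gene: dict[str, Summaries]) -> pd.DataFrame:
    """Long table of CI widths per gene per node; missing nodes excluded."""
    rows = []
    for gene, summaries in per_gene.items():
        for split, s in summaries.items():
            rows.append(
                {"gene": gene, "clade": "|".join(sorted(split)), "width": s.width}
            )
    return pd.DataFrame(rows)


def mean_ci_widths(per_gene: dict[str, Summaries]) -> pd.Series:
    table = ci_width_table(per_gene)
    return table.groupby("gene")["width"].mean()


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Rank-based H with tie correction; chi-square p on k-1 df.

    All-identical observations give H = 0 (and p = 1) by convention.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def ci_overlap(intervals: list[tuple[float, float]]) -> tuple[np.ndarray, bool]:
    """Pairwise interval overlap (|intersection| / |union|) and a joint flag.

    The joint flag is True when all intervals share a common intersection.
    """
    if len(intervals) < 2:
        raise ValueError("need >= 2 intervals")
    k = len(intervals)
    overlap = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            (a1, b1), (a2, b2) = intervals[i], intervals[j]
            inter = max(0.0, min(b1, b2) - max(a1, a2))
            union = max(b1, b2) - min(a1, a2)
            val = inter / union if union > 0 else 1.0
            overlap[i, j] = overlap[j, i] = val
    lo = max(a for a, _ in intervals)
    hi = min(b for _, b in intervals)
    return overlap, bool(hi > lo)


def saturation_table(aln: MultiGeneAlignment, chronogram: TimeTree) -> pd.DataFrame:
    """Per gene, (MRCA age, p-distance) for every taxon pair.

    Ages come from the chronogram's node ages (for a consensus, median
    ages); pairs lacking comparable sites or chronogram coverage are
    skipped.
    """
    tree_taxa = set(chronogram.taxa)
    taxa = [t for t in aln.taxa if t in tree_taxa]
    rows = []
    for gi, gene in enumerate(aln.gene_names):
        mat = aln.genes[gene]
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                a, b = taxa[i], taxa[j]
                mrca = chronogram.mrca([a, b])
                age = float(chronogram.ages[mrca])
                try:
                    dist = p_distance(mat, aln.taxa.index(a), aln.taxa.index(b))
                except UndefinedDistanceError:
                    continue
                rows.append({"gene": gene, "taxon_a": a, "taxon_b": b,
                             "mrca_age": age, "p_distance": dist})
    return pd.DataFrame(rows)


def rate_based_root_age(
    tree_height_subs: float, gene_multiplier: float, rate: RateEstimate
) -> tuple[float, tuple[float, float] | None]:
    """Root age from an external gene-specific rate.

    age = (tree height in substitutions x gene rate multiplier) / rate,
    with the interval propagated from the rate interval's endpoints.
    """
    if tree_height_subs <= 0 or gene_multiplier <= 0:
        raise ValueError("height and multiplier must be positive")
    if rate.rate <= 0:
        raise ValueError("rate must be positive")
    height = tree_height_subs * gene_multiplier
    age = height / rate.rate
    interval = None
    if rate.interval is not None:
        lo_r, hi_r = rate.interval
        if lo_r <= 0:
            raise ValueError("rate interval must be positive")
        interval = (height / hi_r, height / lo_r)
    return age, interval
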