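"""Posterior summaries: pooled runs, consensus topology, node-age tables,
and annotated chronograms.

Nodes are identified across samples by their taxon clade (the tip set
below the node), which is robust to topology variation between samples.
Credibility intervals are central (equal-tailed) 2.5-97.5 percentile
intervals with linear interpolation between order statistics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mcmc import Trace
from .trees import TimeTree

__all__ = [
    "NodeAgeSummary",
    "ConsensusTree",
    "concat_runs",
    "majority_consensus",
    "node_age_summary",
    "summarize_node_ages",
    "write_chronogram",
    "read_chronogram",
]


@dataclass(frozen=True)
class NodeAgeSummary:
    split: frozenset[str]
    pp: float  # posterior probability of the clade
    mean: float
    median: float
    lower: float  # 2.5 percentile
    upper: float  # 97.5 percentile

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def __post_init__(self):
        if not (self.lower <= self.median <= self.upper):
            raise ValueError("CI bounds must bracket the median")
        if not (0.0 < self.pp <= 1.0):
            raise ValueError("posterior probability must be in (0, 1]")


def concat_runs(traces: list[Trace], burn_in: float = 0.25) -> Trace:
    """Remove per-run burn-in and pool samples; provenance kept in run_id."""
    if not traces:
        raise ValueError("need at least one trace")
    taxa = None
    frames, trees = [], []
    offset = 0
    for trace in traces:
        if trace.trees:
            t0 = frozenset(trace.trees[0].taxa)
            if taxa is None:
                taxa = t0
            elif taxa != t0:
                raise ValueError("traces have incompatible taxon sets")
        kept = trace.discard_burn_in(burn_in)
        frame = kept.params.copy()
        frame["run_id"] = trace.run_id
        frame["generation"] = frame["generation"] + offset
        offset = float(frame["generation"].iloc[-1]) if len(frame) else offset
        frames.append(frame)
        trees.extend(kept.trees)
    pooled = pd.concat(frames, ignore_index=True)
    return Trace(pooled, trees, run_id=-1)


def _split_ages(trees: list[TimeTree]) -> dict[frozenset[str], list[float]]:
    ages: dict[frozenset[str], list[float]] = {}
    for tree in trees:
        for node, tips in tree.clade_taxon_sets().items():
            if len(tips) > 1:  # internal clades incl. root
                ages.setdefault(tips, []).append(float(tree.ages[node]))
    return ages


def majority_consensus(trees: list[TimeTree]) -> "ConsensusTree":
    """Majority-rule consensus: clades with frequency > 0.5, PP = frequency.

    Splits below the threshold are not added, so the consensus may contain
    polytomies.
    """
    if not trees:
        raise ValueError("need at least one sampled tree")
    n = len(trees)
    ages = _split_ages(trees)
    taxa = sorted(trees[0].taxa)
    all_taxa = frozenset(taxa)
    clades: dict[frozenset[str], float] = {}
    for split, values in ages.items():
        freq = len(values) / n
        if freq > 0.5 or split == all_taxa:
            clades[split] = min(freq, 1.0)
    summaries = {
        split: _summary_from_ages(split, np.array(ages[split]), clades[split])
        for split in clades
    }
    return ConsensusTree(taxa, clades, summaries)


def _summary_from_ages(split, values: np.ndarray, pp: float) -> NodeAgeSummary:
    lower, upper = np.percentile(values, [2.5, 97.5])  # linear interpolation
    return NodeAgeSummary(
        split=split,
        pp=pp,
        mean=float(values.mean()),
        median=float(np.median(values)),
        lower=float(lower),
        upper=float(upper),
    )


def node_age_summary(trace: Trace, split: frozenset[str] | set[str]) -> NodeAgeSummary:
    """Age summary for one clade, over the samples that contain it.

    Raises KeyError when the clade never occurs — downstream gene
    evaluation uses that signal to detect unrecovered nodes.
    """
    split = frozenset(split)
    ages = _split_ages(trace.trees).get(split)
    if not ages:
        raise KeyError(f"clade not present in any sampled tree: {sorted(split)}")
    return _summary_from_ages(split, np.array(ages), pp=len(ages) / len(trace.trees))


def summarize_node_ages(trace: Trace, min_pp: float = 0.0) -> dict[frozenset[str], NodeAgeSummary]:
    ages = _split_ages(trace.trees)
    n = len(trace.trees)
    out = {}
    for split, values in ages.items():
        pp = len(values) / n
        if pp >= min_pp:
            out[split] = _summary_from_ages(split, np.array(values), pp)
    return out


class ConsensusTree:
    """Majority-rule consensus topology with per-clade age summaries."""

    def __init__(
        self,
        taxa: list[str],
        clades: dict[frozenset[str], float],
        summaries: dict[frozenset[str], NodeAgeSummary],
    ):
        self.taxa = list(taxa)
        self.clades = dict(clades)
        self.summaries = dict(summaries)
        for a in clades:
            for b in clades:
                if a & b and not (a <= b or b <= a):
                    raise ValueError("majority clades must be pairwise compatible")

    def node_table(self) -> pd.DataFrame:
        rows = []
        for split, s in sorted(self.summaries.items(), key=lambda kv: -len(kv[0])):
            rows.append(
                {
                    "clade": "|".join(sorted(split)),
                    "n_taxa": len(split),
                    "pp": self.clades.get(split, np.nan),
                    "mean": s.mean,
                    "median": s.median,
                    "ci_lower": s.lower,
                    "ci_upper": s.upper,
                    "ci_width": s.width,
                }
            )
        return pd.DataFrame(rows)

    # --------------------------------------------------------------- newick
    def _nested(self):
        """Containment forest of the majority clades."""
        clades = sorted(self.clades, key=len, reverse=True)
        root = frozenset(self.taxa)
        if root not in self.clades:
            clades = [root] + clades

        def children_of(parent):
            inner = [c for c in clades if c < parent]
            maximal = [c for c in inner if not any(c < d for d in inner)]
            covered = set().union(*maximal) if maximal else set()
            singles = [frozenset((t,)) for t in sorted(parent - covered)]
            return sorted(maximal, key=lambda s: sorted(s)) + singles

        return children_of

    def to_newick(self, annotate: bool = True) -> str:
        children_of = self._nested()
        root = frozenset(self.taxa)

        def age_of(split):
            s = self.summaries.get(split)
            return s.median if s else 0.0

        def rec(split, parent_age):
            if len(split) == 1:
                (taxon,) = split
                label, age = taxon, 0.0
            else:
                kids = children_of(split)
                age = age_of(split)
                label = "(" + ",".join(rec(k, age) for k in kids) + ")"
                if annotate and split in self.summaries:
                    s = self.summaries[split]
                    label += (
                        f"[&pp={self.clades.get(split, 1.0):.6g},median={s.median:.10g},"
                        f"mean={s.mean:.10g},ci_lower={s.lower:.10g},ci_upper={s.upper:.10g}]"
                    )
            if parent_age is not None:
                label += f":{max(parent_age - age, 0.0):.10g}"
            return label

        return rec(root, None) + ";"


def write_chronogram(consensus: ConsensusTree, path: str | Path) -> None:
    """NEXUS trees block; node comments carry PP, median age and CI bounds;
    branch lengths are in My."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#NEXUS\nbegin trees;\n")
        fh.write("  tree consensus = [&R] " + consensus.to_newick() + "\n")
        fh.write("end;\n")


_ANNOT = re.compile(r"\[&([^\]]*)\]")


def read_chronogram(path: str | Path) -> ConsensusTree:
    """Round-trip reader for the annotated NEXUS chronogram."""
    text = Path(path).read_text()
    m = re.search(r"tree\s+\S+\s*=\s*(?:\[&R\]\s*)?(\(.*;)", text, re.S)
    if not m:
        raise ValueError(f"no tree found in {path}")
    newick = m.group(1).strip()
    return _parse_annotated_newick(newick)


def _parse_annotated_newick(newick: str) -> ConsensusTree:
    pos = 0

    def parse_clade():
        nonlocal pos
        tips: set[str] = set()
        children = []
        if newick[pos] == "(":
            pos += 1
            while True:
                sub = parse_clade()
                children.append(sub)
                tips |= sub[0]
                if newick[pos] == ",":
                    pos += 1
                    continue
                if newick[pos] == ")":
                    pos += 1
                    break
        else:
            m = re.match(r"[^,():;\[\]]+", newick[pos:])
            name = m.group(0)
            pos += len(name)
            tips = {name.strip("'")}
        annot = {}
        m = _ANNOT.match(newick[pos:])
        if m:
            for kv in m.group(1).split(","):
                k, v = kv.split("=")
                annot[k] = float(v)
            pos += m.end()
        if pos < len(newick) and newick[pos] == ":":
            m = re.match(r":[-+0-9.eE]+", newick[pos:])
            pos += m.end()
        return frozenset(tips), annot, children

    tips, annot, children = parse_clade()
    taxa = sorted(tips)

    clades: dict[frozenset[str], float] = {}
    summaries: dict[frozenset[str], NodeAgeSummary] = {}

    def walk(node):
        split, annot, children = node
        if len(split) > 1 and annot:
            clades[split] = annot.get("pp", 1.0)
            summaries[split] = NodeAgeSummary(
                split=split,
                pp=annot.get("pp", 1.0),
                mean=annot["mean"],
                median=annot["median"],
                lower=annot["ci_lower"],
                upper=annot["ci_upper"],
            )
        elif len(split) > 1:
            clades[split] = 1.0
        for ch in children:
            walk(ch)

    walk((tips, annot, children))
    return ConsensusTree(taxa, clades, summaries)
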