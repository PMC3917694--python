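"""Multi-gene nucleotide alignments, partition schemes, and descriptive stats.

Alignments hold one character matrix per gene over a shared, ordered taxon
set.  Characters are IUPAC nucleotide codes plus gap ``-`` and missing ``?``;
both gap and missing are treated as fully ambiguous for likelihood purposes
but preserved distinctly for round-tripping.  Partition schemes implement
the by-gene, by-codon-position layout used for protein-coding genes
(positions 1+2 combined versus position 3) with one partition per intron.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Nexus import Nexus

__all__ = [
    "IUPAC_STATES",
    "MultiGeneAlignment",
    "Partition",
    "PartitionScheme",
    "build_partition_scheme",
    "count_parsimony_informative",
    "p_distance",
    "UndefinedDistanceError",
    "AlignmentFormatError",
]

#: map from IUPAC code to the set of compatible unambiguous states
IUPAC_STATES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"), "-": frozenset("ACGT"), "?": frozenset("ACGT"),
}

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class AlignmentFormatError(ValueError):
    """Malformed alignment input (ragged rows, duplicate taxa, ...)."""


class UndefinedDistanceError(ValueError):
    """No pairwise-complete unambiguous site exists for the requested pair."""


@dataclass
class MultiGeneAlignment:
    """Taxa x sites with gene structure; all genes share the taxon set."""

    taxa: list[str]
    genes: dict[str, np.ndarray]  # gene name -> (n_taxa, length) array of single chars

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentFormatError("duplicate taxon label")
        n = len(self.taxa)
        for name, mat in self.genes.items():
            mat = np.asarray(mat, dtype="<U1")
            if mat.ndim != 2 or mat.shape[0] != n:
                raise AlignmentFormatError(f"gene {name}: matrix shape {mat.shape} != ({n}, L)")
            self.genes[name] = np.char.upper(mat)

    # ------------------------------------------------------------- structure
    @property
    def gene_names(self) -> list[str]:
        return list(self.genes)

    @property
    def gene_lengths(self) -> list[int]:
        return [m.shape[1] for m in self.genes.values()]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return int(sum(self.gene_lengths))

    def gene_offsets(self) -> dict[str, int]:
        """0-based start of each gene in the concatenated matrix."""
        out, pos = {}, 0
        for name, mat in self.genes.items():
            out[name] = pos
            pos += mat.shape[1]
        return out

    def concatenated(self) -> np.ndarray:
        return np.concatenate(list(self.genes.values()), axis=1)

    def subset_genes(self, names: list[str]) -> "MultiGeneAlignment":
        return MultiGeneAlignment(self.taxa, {n: self.genes[n].copy() for n in names})

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_gene_fastas(cls, paths: dict[str, str | Path]) -> "MultiGeneAlignment":
        """One FASTA per gene; taxa missing from a gene are filled with '?'."""
        per_gene: dict[str, dict[str, str]] = {}
        taxa_order: list[str] = []
        for gene, path in paths.items():
            seqs: dict[str, str] = {}
            for rec in SeqIO.parse(str(path), "fasta"):
                if rec.id in seqs:
                    raise AlignmentFormatError(f"duplicate taxon {rec.id} in {path}")
                seqs[rec.id] = str(rec.seq).upper()
                if rec.id not in taxa_order:
                    taxa_order.append(rec.id)
            lengths = {len(s) for s in seqs.values()}
            if len(lengths) > 1:
                bad = [t for t, s in seqs.items() if len(s) != max(lengths)]
                raise AlignmentFormatError(f"ragged alignment in gene {gene}: taxa {bad}")
            per_gene[gene] = seqs
        genes = {}
        for gene, seqs in per_gene.items():
            length = len(next(iter(seqs.values())))
            rows = [list(seqs.get(t, "?" * length)) for t in taxa_order]
            genes[gene] = np.array(rows, dtype="<U1")
        return cls(taxa_order, genes)

    @classmethod
    def from_fasta(cls, path: str | Path, gene_name: str = "gene1") -> "MultiGeneAlignment":
        return cls.from_gene_fastas({gene_name: path})

    @classmethod
    def from_nexus(cls, path: str | Path) -> "MultiGeneAlignment":
        """NEXUS data matrix with charset lines defining the genes."""
        nex = Nexus.Nexus(str(path))
        taxa = list(nex.taxlabels)
        full = np.array([list(str(nex.matrix[t]).upper()) for t in taxa], dtype="<U1")
        charsets = {k: v for k, v in nex.charsets.items()}
        genes: dict[str, np.ndarray] = {}
        if charsets:
            for name in charsets:
                cols = np.array(sorted(charsets[name]), dtype=int)
                genes[name] = full[:, cols]
            covered = sorted({c for v in charsets.values() for c in v})
            if covered != list(range(full.shape[1])):
                raise AlignmentFormatError("charsets do not tile the matrix")
        else:
            genes["gene1"] = full
        return cls(taxa, genes)

    def to_fasta(self, path: str | Path, gene: str | None = None, wrap: int = 70) -> None:
        mat = self.concatenated() if gene is None else self.genes[gene]
        with open(path, "w") as fh:
            for i, taxon in enumerate(self.taxa):
                fh.write(f">{taxon}\n")
                seq = "".join(mat[i])
                for k in range(0, len(seq), wrap):
                    fh.write(seq[k : k + wrap] + "\n")

    def to_nexus(self, path: str | Path) -> None:
        """Concatenated data block plus a sets block with per-gene charsets."""
        mat = self.concatenated()
        n, L = mat.shape
        pad = max(len(t) for t in self.taxa) + 2
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nbegin data;\n")
            fh.write(f"  dimensions ntax={n} nchar={L};\n")
            fh.write("  format datatype=dna missing=? gap=-;\n  matrix\n")
            for i, taxon in enumerate(self.taxa):
                name = f"'{taxon}'" if " " in taxon else taxon
                fh.write(f"  {name.ljust(pad)}{''.join(mat[i])}\n")
            fh.write("  ;\nend;\n\nbegin sets;\n")
            pos = 1
            for gene, length in zip(self.gene_names, self.gene_lengths):
                fh.write(f"  charset {gene} = {pos}-{pos + length - 1};\n")
                pos += length
            fh.write("end;\n")


# ---------------------------------------------------------------- partitions
@dataclass(frozen=True)
class Partition:
    pid: int
    gene: str
    name: str
    sites: tuple[int, ...]  # 0-based indices within the gene


@dataclass
class PartitionScheme:
    partitions: list[Partition] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.partitions)

    def __iter__(self):
        return iter(self.partitions)

    def lengths(self) -> np.ndarray:
        return np.array([len(p.sites) for p in self.partitions], dtype=float)

    def check_covers(self, gene_lengths: dict[str, int]) -> None:
        """Partitions must be a set-partition of every gene's sites."""
        by_gene: dict[str, list[int]] = {}
        for p in self.partitions:
            by_gene.setdefault(p.gene, []).extend(p.sites)
        for gene, length in gene_lengths.items():
            got = sorted(by_gene.get(gene, []))
            if got != list(range(length)):
                raise ValueError(f"partitions do not tile gene {gene}")


def build_partition_scheme(
    genes: list[str],
    gene_lengths: list[int],
    coding_flags: list[bool],
    reading_frames: dict[str, int] | None = None,
) -> PartitionScheme:
    """By-gene / by-codon-position scheme.

    Coding genes contribute two partitions (codon positions 1+2, and 3);
    non-coding genes one.  ``reading_frames[gene]`` gives the codon position
    (1, 2 or 3) of the gene's first site; it defaults to 1 but must be
    supplied explicitly for coding genes if ``reading_frames`` is passed.
    """
    reading_frames = dict(reading_frames or {})
    parts: list[Partition] = []
    pid = 0
    for gene, length, coding in zip(genes, gene_lengths, coding_flags):
        if not coding:
            parts.append(Partition(pid, gene, gene, tuple(range(length))))
            pid += 1
            continue
        frame = reading_frames.get(gene, 1)
        if frame not in (1, 2, 3):
            raise ValueError(f"coding gene {gene}: reading frame must be 1, 2 or 3")
        codon_pos = (np.arange(length) + (frame - 1)) % 3 + 1
        pos12 = tuple(np.flatnonzero(codon_pos != 3))
        pos3 = tuple(np.flatnonzero(codon_pos == 3))
        parts.append(Partition(pid, gene, f"{gene}_pos12", tuple(int(i) for i in pos12)))
        parts.append(Partition(pid + 1, gene, f"{gene}_pos3", tuple(int(i) for i in pos3)))
        pid += 2
    return PartitionScheme(parts)


# ---------------------------------------------------------------- statistics
def count_parsimony_informative(matrix: np.ndarray) -> int:
    """Sites with >= 2 distinct unambiguous states each in >= 2 sequences."""
    matrix = np.char.upper(np.asarray(matrix, dtype="<U1"))
    count = 0
    for col in matrix.T:
        tallies: dict[str, int] = {}
        for ch in col:
            if ch in _BASE_INDEX:
                tallies[ch] = tallies.get(ch, 0) + 1
        if sum(1 for v in tallies.values() if v >= 2) >= 2:
            count += 1
    return count


def p_distance(matrix: np.ndarray, taxon_a: int, taxon_b: int) -> float:
    """Uncorrected proportion of differing sites over pairwise-complete,
    unambiguous columns."""
    matrix = np.char.upper(np.asarray(matrix, dtype="<U1"))
    a, b = matrix[taxon_a], matrix[taxon_b]
    ok = np.isin(a, list(_BASES)) & np.isin(b, list(_BASES))
    n = int(ok.sum())
    if n == 0:
        raise UndefinedDistanceError("no pairwise-complete unambiguous sites")
    return float(np.sum(a[ok] != b[ok]) / n)


def encode_matrix(matrix: np.ndarray) -> np.ndarray:
    """Encode characters as tip partial-likelihood indicators (n, L, 4).

    Each cell is a 0/1 vector over ACGT marking compatible states; ambiguity
    codes and gaps/missing get multiple ones (standard partial-likelihood
    treatment of uncertainty at the tips).
    """
    matrix = np.char.upper(np.asarray(matrix, dtype="<U1"))
    n, L = matrix.shape
    out = np.zeros((n, L, 4))
    for code, states in IUPAC_STATES.items():
        mask = matrix == code
        if not mask.any():
            continue
        vec = np.zeros(4)
        for s in states:
            vec[_BASE_INDEX[s]] = 1.0
        out[mask] = vec
    unknown = out.sum(axis=2) == 0
    if unknown.any():
        i, j = np.argwhere(unknown)[0]
        raise AlignmentFormatError(f"unknown character {matrix[i, j]!r} at taxon {i}, site {j}")
    return out
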