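"""Core domain types and sequence primitives.

Coordinates are 0-based half-open everywhere inside the toolkit; report
writers convert to 1-based inclusive (GFF3 convention) at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import ValidationError

DNA_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, where: str = "sequence") -> str:
    """Uppercase *seq* and reject characters outside {A,C,G,T,N}."""
    seq = seq.upper()
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValidationError(f"non-IUPAC characters {sorted(bad)} in {where}")
    return seq


@dataclass(frozen=True)
class Contig:
    """One contig of an assembly; sequence is uppercased at ingest."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_dna(self.sequence, self.contig_id))

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeAssembly:
    """All contigs of one strain, the unit of analysis.

    ``taxon_id`` and ``strain_id`` feed the prophage designation
    ``prophi{taxon}.{strain}-{index}``.
    """

    taxon_id: str
    strain_id: str
    contigs: list[Contig]
    species_label: str = ""

    def __post_init__(self) -> None:
        ids = [c.contig_id for c in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate contig_id within assembly")
        if not self.contigs:
            raise ValidationError("assembly must contain at least one contig")
        self._by_id = {c.contig_id: c for c in self.contigs}

    @property
    def contig_count(self) -> int:
        return len(self.contigs)

    @property
    def genome_id(self) -> str:
        return f"{self.taxon_id}.{self.strain_id}"

    def contig(self, contig_id: str) -> Contig:
        try:
            return self._by_id[contig_id]
        except KeyError:
            raise LookupError(f"unknown contig {contig_id!r} in {self.genome_id}")


@dataclass(frozen=True)
class GeneFeature:
    """A protein-coding gene with its ordinal rank along its contig."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein: str
    rank: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"bad interval [{self.start},{self.end}) for gene {self.gene_id}"
            )
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not self.protein:
            raise ValidationError(f"empty protein for gene {self.gene_id}")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class RnaFeature:
    """A tRNA or tmRNA gene (attachment sites frequently overlap these)."""

    feature_id: str
    contig_id: str
    start: int
    end: int
    kind: str  # "tRNA" or "tmRNA"
    isotype: str = ""  # e.g. "tRNA-Arg (TCT)" for tRNAs


@dataclass
class ProphageCall:
    """A located prophage, intact or spliced or omitted by QC."""

    designation: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    sequence: str
    status: str = "intact"  # intact | spliced_partial | omitted
    cluster_label: Optional[str] = None
    core_att: Optional[object] = None  # att.AttCore when found
    omission_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in ("intact", "spliced_partial", "omitted"):
            raise ValidationError(f"bad prophage status {self.status!r}")
        if len(self.sequence) != self.end - self.start:
            raise ValidationError(
                f"{self.designation}: sequence length {len(self.sequence)} != "
                f"interval length {self.end - self.start}"
            )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def make_designation(taxon_id: str, strain_id: str, index: int) -> str:
    """Prophage designation ``prophi{taxon}.{strain}-{index}`` (index ≥ 1).

    Example: taxon 1761, strain 28 carries prophi1761.28-1, prophi1761.28-2.
    """
    if index < 1:
        raise ValidationError(f"prophage index must be >= 1, got {index}")
    return f"prophi{taxon_id}.{strain_id}-{index}"


def extract_subsequence(
    assembly: GenomeAssembly, contig_id: str, interval: tuple[int, int], strand: str = "+"
) -> str:
    """Slice ``[start, end)`` from a contig; reverse complement on ``-``."""
    contig = assembly.contig(contig_id)
    start, end = interval
    if start >= end:
        raise ValidationError(f"empty or inverted interval [{start},{end})")
    if start < 0 or end > contig.length:
        raise IndexError(
            f"interval [{start},{end}) outside contig {contig_id} (len {contig.length})"
        )
    sub = contig.sequence[start:end]
    if strand == "-":
        return reverse_complement(sub)
    if strand != "+":
        raise ValidationError(f"bad strand {strand!r}")
    return sub


def rank_genes(genes: Iterable[GeneFeature]) -> list[GeneFeature]:
    """Sort genes of one contig by start and assign consecutive ranks."""
    ordered = sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))
    return [
        GeneFeature(g.gene_id, g.contig_id, g.start, g.end, g.strand, g.protein, i)
        for i, g in enumerate(ordered)
    ]


# ---------------------------------------------------------------------------
# Naive ORF calling (fixtures / de novo annotation of spliced sequences)
# ---------------------------------------------------------------------------

# standard genetic code, DNA codons
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(dna: str) -> str:
    """Translate a DNA string codon-by-codon; stops become ``*``."""
    return "".join(
        _CODON_TABLE.get(dna[i : i + 3], "X") for i in range(0, len(dna) - 2, 3)
    )


def find_orfs(sequence: str, min_aa: int = 80) -> list[GeneFeature]:
    """Call ORFs (ATG..stop, both strands) of at least *min_aa* residues.

    A deliberately simple caller for synthetic sequences and spliced
    reconstructions: in each frame, the first ATG after the previous stop
    opens an ORF that runs to the next stop codon.  Real genomes deserve a
    real gene caller; this one exists so the toolkit's validators can run
    on sequences that have no annotation yet.
    """
    sequence = sequence.upper()
    found: list[tuple[int, int, str, str]] = []
    n = len(sequence)
    for strand, seq in (("+", sequence), ("-", reverse_complement(sequence))):
        for frame in range(3):
            start_codon: Optional[int] = None
            for pos in range(frame, n - 2, 3):
                codon = seq[pos : pos + 3]
                aa = _CODON_TABLE.get(codon, "X")
                if aa == "*":
                    if start_codon is not None:
                        aa_len = (pos - start_codon) // 3
                        if aa_len >= min_aa:
                            found.append((start_codon, pos + 3, strand, seq))
                        start_codon = None
                elif start_codon is None and codon == "ATG":
                    start_codon = pos
    genes = []
    for start, end, strand, seq in found:
        protein = translate(seq[start : end - 3])
        if strand == "+":
            iv = (start, end)
        else:
            iv = (n - end, n - start)
        genes.append((iv[0], iv[1], strand, protein))
    genes.sort()
    return [
        GeneFeature(f"orf_{i + 1}", "seq", s, e, strand, protein, i)
        for i, (s, e, strand, protein) in enumerate(genes)
    ]
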