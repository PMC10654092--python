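"""Reading and writing the toolkit's on-disk formats.

FASTA goes through Biopython.  Gene annotations are accepted either as GFF3
(CDS features with an ``ID=`` attribute and a ``protein=`` or ``translation=``
attribute) or as a 6-column TSV ``gene_id  contig  start  end  strand
protein`` with 0-based half-open coordinates.  All emitted GFF3/TSV reports
use 1-based inclusive coordinates per GFF3 convention; the TSV gene table is
the internal exchange format and stays 0-based half-open.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import PipelineConfig, DEFAULT_CONFIG
from .core import Contig, GeneFeature, GenomeAssembly, ProphageCall, rank_genes
from .errors import AdmissionError, ValidationError

PathLike = Union[str, Path]


def read_fasta(source: PathLike) -> list[tuple[str, str]]:
    """Parse a (multi-)FASTA file into ``(id, sequence)`` pairs."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(source), "fasta")]
    if not records:
        raise ValidationError(f"no FASTA records in {source}")
    return records


def write_fasta(path: PathLike, records: Iterable[tuple[str, str]]) -> None:
    """Write records as 60-column-wrapped FASTA."""
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_assembly(
    fasta_source: PathLike,
    taxon_id: str,
    strain_id: str,
    config: PipelineConfig = DEFAULT_CONFIG,
    species_label: str = "",
    enforce_admission: bool = True,
) -> GenomeAssembly:
    """Load a draft assembly, enforcing the contig-count admission rule.

    Assemblies with more than ``config.max_contigs`` contigs raise
    :class:`AdmissionError` (the corpus filter used upstream: only genomes
    assembled into 100 or fewer contigs are analyzed); pass
    ``enforce_admission=False`` to override.
    """
    records = read_fasta(fasta_source)
    if enforce_admission and len(records) > config.max_contigs:
        raise AdmissionError(
            f"{fasta_source}: {len(records)} contigs exceeds the admission "
            f"limit of {config.max_contigs}"
        )
    contigs = [Contig(name, seq) for name, seq in records]
    return GenomeAssembly(taxon_id, strain_id, contigs, species_label)


def write_assembly(path: PathLike, assembly: GenomeAssembly) -> None:
    write_fasta(path, [(c.contig_id, c.sequence) for c in assembly.contigs])


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------

GENE_TSV_COLUMNS = ["gene_id", "contig", "start", "end", "strand", "protein"]


def read_gene_table(source: PathLike) -> list[GeneFeature]:
    """Read the 6-column gene TSV (0-based half-open) and assign ranks."""
    per_contig: dict[str, list[GeneFeature]] = {}
    with open(source) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "gene_id":
                continue
            if len(row) < 6:
                raise ValidationError(f"gene table row too short: {row}")
            gene_id, contig, start, end, strand, protein = row[:6]
            feat = GeneFeature(gene_id, contig, int(start), int(end), strand, protein, 0)
            per_contig.setdefault(contig, []).append(feat)
    genes: list[GeneFeature] = []
    for contig in per_contig:
        genes.extend(rank_genes(per_contig[contig]))
    return genes


def write_gene_table(path: PathLike, genes: Iterable[GeneFeature]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(GENE_TSV_COLUMNS)
        for g in genes:
            writer.writerow([g.gene_id, g.contig_id, g.start, g.end, g.strand, g.protein])


def read_genes_gff3(source: PathLike) -> list[GeneFeature]:
    """Read CDS features from GFF3 (1-based inclusive -> 0-based half-open)."""
    per_contig: dict[str, list[GeneFeature]] = {}
    with open(source) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID")
            protein = attrs.get("protein") or attrs.get("translation")
            if gene_id is None or protein is None:
                raise ValidationError(f"CDS lacks ID/protein attributes: {line!r}")
            feat = GeneFeature(
                gene_id, cols[0], int(cols[3]) - 1, int(cols[4]), cols[6], protein, 0
            )
            per_contig.setdefault(cols[0], []).append(feat)
    genes: list[GeneFeature] = []
    for contig in per_contig:
        genes.extend(rank_genes(per_contig[contig]))
    return genes


def write_genes_gff3(path: PathLike, genes: Iterable[GeneFeature]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig_id}\tprophikit\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id};protein={g.protein}\n"
            )


# ---------------------------------------------------------------------------
# Phage reference database (FASTA + cluster-label TSV)
# ---------------------------------------------------------------------------


class PhageDatabase:
    """Reference phage genomes with cluster labels, for fragment scaffolding
    and defective-prophage nucleotide evidence."""

    def __init__(self, sequences: dict[str, str], clusters: dict[str, str]):
        if not sequences:
            raise ValidationError("phage database is empty")
        self.sequences = {k: v.upper() for k, v in sequences.items()}
        self.clusters = dict(clusters)

    def cluster_of(self, phage_id: str) -> Optional[str]:
        return self.clusters.get(phage_id)

    def __len__(self) -> int:
        return len(self.sequences)

    def items(self):
        return self.sequences.items()

    @classmethod
    def from_files(cls, fasta_path: PathLike, cluster_tsv: PathLike) -> "PhageDatabase":
        sequences = dict(read_fasta(fasta_path))
        clusters: dict[str, str] = {}
        with open(cluster_tsv) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#") or row[0] == "phage_id":
                    continue
                clusters[row[0]] = row[1]
        return cls(sequences, clusters)

    def to_files(self, fasta_path: PathLike, cluster_tsv: PathLike) -> None:
        write_fasta(fasta_path, sorted(self.sequences.items()))
        with open(cluster_tsv, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["phage_id", "cluster"])
            for phage_id in sorted(self.sequences):
                writer.writerow([phage_id, self.clusters.get(phage_id, "")])


# ---------------------------------------------------------------------------
# Prophage call reports
# ---------------------------------------------------------------------------

PROPHAGE_TSV_COLUMNS = [
    "designation", "genome_id", "contig", "start_1based", "end",
    "length", "status", "cluster", "att_core", "omission_reason",
]


def write_prophage_report(
    path: PathLike, calls: Iterable[ProphageCall], fasta_path: Optional[PathLike] = None
) -> None:
    """Prophage calls as a 1-based TSV report plus optional sequence FASTA."""
    calls = list(calls)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PROPHAGE_TSV_COLUMNS)
        for c in calls:
            core = getattr(c.core_att, "sequence", "") if c.core_att else ""
            writer.writerow([
                c.designation, c.genome_id, c.contig_id, c.start + 1, c.end,
                c.end - c.start, c.status, c.cluster_label or "", core,
                c.omission_reason or "",
            ])
    if fasta_path is not None:
        kept = [(c.designation, c.sequence) for c in calls if c.status != "omitted"]
        if kept:
            write_fasta(fasta_path, kept)
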