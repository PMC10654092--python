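"""Contig-end splicing: recover prophages that span unjoined contigs of a draft
assembly.

Draft assemblies frequently break inside a prophage, leaving phage-like
fragments at contig ends.  Using a database of previously identified,
cluster-labeled phage genomes as a scaffold, fragments near contig ends
are located, ordered along their best-matching reference genome, and
concatenated into a single prophage sequence.  The reconstruction carries
the reference's cluster label as a provisional assignment and is then
validated by a pluggable prophage validator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from .config import PipelineConfig, DEFAULT_CONFIG
from .core import GeneFeature, GenomeAssembly, find_orfs, reverse_complement
from .errors import (
    AnnotationError,
    ConfigurationError,
    GroupingError,
    SpliceError,
    ValidationError,
)
from .homology import (
    PHAGE_GENE_CATEGORIES,
    KmerIndex,
    LocalAlignment,
    ProfileDatabase,
    find_local_alignments,
)
from .io import PhageDatabase


@dataclass(frozen=True)
class ProphageFragment:
    """A phage-like fragment at (or near) a contig end, mapped onto its
    best reference phage genome."""

    contig_id: str
    frag_start: int
    frag_end: int
    reference_id: str
    ref_start: int
    ref_end: int
    orientation: str  # "+" fragment matches reference forward strand
    end_distance: int
    identity: float

    @property
    def frag_interval(self) -> tuple[int, int]:
        return (self.frag_start, self.frag_end)

    @property
    def ref_interval(self) -> tuple[int, int]:
        return (self.ref_start, self.ref_end)

    @property
    def length(self) -> int:
        return self.frag_end - self.frag_start


@dataclass
class SplicedProphage:
    """An ordered concatenation of contig-end fragments along a reference."""

    fragments: list[ProphageFragment]
    sequence: str
    reference_id: str
    cluster_label: Optional[str] = None
    validated: bool = False
    completeness: str = "partial"  # complete_on_reference | partial
    gaps: list[tuple[int, int]] = field(default_factory=list)

    @property
    def reference_coverage(self) -> list[tuple[int, int]]:
        return [f.ref_interval for f in self.fragments]


def find_end_fragments(
    assembly: GenomeAssembly,
    phage_db: PhageDatabase,
    config: PipelineConfig = DEFAULT_CONFIG,
    index: Optional["KmerIndex"] = None,
) -> list[ProphageFragment]:
    """Locate phage-like fragments within ``end_margin_bp`` of contig ends.

    Each contig is searched against every database phage; alignments of at
    least ``min_fragment_len_bp`` at ``min_alignment_identity`` whose
    nearest contig end is within the margin are kept.  Interior matches on
    long contigs are excluded — an interior prophage is ordinary
    whole-prophage-caller territory, not a splicing problem.  Each
    fragment keeps only its best reference (highest identity × length).
    """
    if len(phage_db) == 0:
        raise ConfigurationError("empty phage database")
    if index is None:
        index = KmerIndex(dict(phage_db.items()), config.seed_kmer)
    fragments: list[ProphageFragment] = []
    for contig in assembly.contigs:
        alignments = find_local_alignments(
            contig.sequence,
            index,
            min_len=config.min_fragment_len_bp,
            min_identity=config.min_alignment_identity,
            k=config.seed_kmer,
            xdrop=config.xdrop,
            query_id=contig.contig_id,
        )
        # keep the best-scoring reference per contig region: greedy
        # selection by identity x length, discarding alignments that
        # overlap an already-selected (better) one on the contig
        candidates = [
            aln
            for aln in alignments
            if min(aln.q_start, contig.length - aln.q_end) <= config.end_margin_bp
        ]
        candidates.sort(key=lambda a: (-a.score, a.subject_id, a.q_start))
        selected: list[LocalAlignment] = []
        for aln in candidates:
            if any(
                aln.q_start < kept.q_end and kept.q_start < aln.q_end
                for kept in selected
            ):
                continue
            selected.append(aln)
        for aln in sorted(selected, key=lambda a: (a.q_start, a.subject_id)):
            end_distance = min(aln.q_start, contig.length - aln.q_end)
            fragments.append(
                ProphageFragment(
                    contig_id=contig.contig_id,
                    frag_start=aln.q_start,
                    frag_end=aln.q_end,
                    reference_id=aln.subject_id,
                    ref_start=aln.s_start,
                    ref_end=aln.s_end,
                    orientation=aln.strand,
                    end_distance=end_distance,
                    identity=aln.identity,
                )
            )
    return fragments


def group_fragments_by_reference(
    fragments: Iterable[ProphageFragment],
) -> dict[str, list[ProphageFragment]]:
    """Group fragments by their best reference genome."""
    groups: dict[str, list[ProphageFragment]] = {}
    for frag in fragments:
        groups.setdefault(frag.reference_id, []).append(frag)
    return groups


def splice_fragments(
    fragments: Sequence[ProphageFragment],
    assembly: GenomeAssembly,
    phage_db: PhageDatabase,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> SplicedProphage:
    """Order fragments along their shared reference and concatenate.

    Fragments are sorted by reference start; a fragment stored in reverse
    orientation on its contig is reverse-complemented first, so the
    concatenation reads in reference direction.  Where two fragments cover
    overlapping reference intervals the later fragment's overlapping
    prefix is trimmed (the earlier fragment's copy is kept).  Reference
    coverage of at least ``splice_complete_coverage`` (default 95%) marks
    the reconstruction complete_on_reference; anything less — including a
    single fragment — is partial.
    """
    fragments = list(fragments)
    if not fragments:
        raise ValidationError("no fragments to splice")
    references = {f.reference_id for f in fragments}
    if len(references) != 1:
        raise GroupingError(
            f"fragments map to multiple references {sorted(references)}; "
            "group by reference first"
        )
    reference_id = fragments[0].reference_id
    if reference_id not in phage_db.sequences:
        raise AnnotationError(f"reference {reference_id} absent from database")
    ref_len = len(phage_db.sequences[reference_id])

    ordered = sorted(fragments, key=lambda f: (f.ref_start, f.ref_end, f.contig_id))
    pieces: list[str] = []
    covered_to: Optional[int] = None
    gaps: list[tuple[int, int]] = []
    for frag in ordered:
        contig = assembly.contig(frag.contig_id)
        seq = contig.sequence[frag.frag_start : frag.frag_end]
        if frag.orientation == "-":
            seq = reverse_complement(seq)
        ref_start = frag.ref_start
        if covered_to is not None:
            if frag.ref_end <= covered_to:
                continue  # fully redundant fragment
            if ref_start < covered_to:
                trim = covered_to - ref_start
                if trim >= len(seq):
                    raise SpliceError(
                        f"fragment {frag.contig_id}:{frag.frag_interval} cannot "
                        "be collinearized with earlier fragments"
                    )
                seq = seq[trim:]
            elif ref_start > covered_to:
                gaps.append((covered_to, ref_start))
        pieces.append(seq)
        covered_to = frag.ref_end

    covered_bases = sum(
        iv[1] - iv[0] for iv in _merge_intervals([f.ref_interval for f in ordered])
    )
    completeness = (
        "complete_on_reference"
        if len(ordered) > 1 and covered_bases / ref_len >= config.splice_complete_coverage
        else "partial"
    )
    return SplicedProphage(
        fragments=ordered,
        sequence="".join(pieces),
        reference_id=reference_id,
        completeness=completeness,
        gaps=gaps,
    )


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def assign_cluster_from_reference(
    spliced: SplicedProphage, phage_db: PhageDatabase
) -> str:
    """Propagate the reference phage's cluster label to the reconstruction."""
    label = phage_db.cluster_of(spliced.reference_id)
    if label is None or label == "":
        raise AnnotationError(
            f"reference {spliced.reference_id} carries no cluster label"
        )
    spliced.cluster_label = label
    return label


ValidatorFn = Callable[[str, Sequence[GeneFeature]], bool]


def make_profile_validator(
    profile_db: ProfileDatabase, config: PipelineConfig = DEFAULT_CONFIG
) -> ValidatorFn:
    """Built-in heuristic validator: accept when at least
    ``validator_min_phage_fraction`` of the genes carry a significant
    phage-archetype profile hit.  A full prophage caller can be plugged in
    through the same ``(sequence, genes) -> bool`` contract."""
    from .homology import score_profile

    archetypes = profile_db.by_category("phage_archetype")

    def validator(sequence: str, genes: Sequence[GeneFeature]) -> bool:
        if not genes:
            return False
        n_hit = 0
        for gene in genes:
            for profile in archetypes:
                hit = score_profile(
                    gene.protein, profile, config.profile_score_threshold, gene.gene_id
                )
                if hit.significant:
                    n_hit += 1
                    break
        return n_hit / len(genes) >= config.validator_min_phage_fraction

    return validator


def validate_spliced(
    spliced: SplicedProphage,
    validator: ValidatorFn,
    genes: Optional[Sequence[GeneFeature]] = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> bool:
    """Run a validator over the reconstruction; naive ORF calls are used
    when no annotation is supplied.  Validator exceptions propagate with
    context and leave the prophage unvalidated."""
    if genes is None:
        genes = find_orfs(spliced.sequence, min_aa=config.min_orf_aa)
    try:
        verdict = bool(validator(spliced.sequence, genes))
    except Exception as exc:
        raise ValidationError(
            f"validator failed on spliced prophage ({spliced.reference_id}): {exc}"
        ) from exc
    spliced.validated = verdict
    return verdict
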