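"""Sliding-window discovery and classification of phage-like regions.

A window of 15 genes slides (one gene at a time) along each contig;
windows containing at least one significant profile hit qualify, and the
union of qualifying windows is merged into maximal regions.  Regions are
then classified, non-exclusively:

* ``integrated_element`` — carries an integrase or transposase hit and
  does not overlap an accepted prophage call (prophages are integrated
  elements by definition and are counted separately);
* ``phage_related`` — carries at least one phage gene (archetypal phage
  gene or major capsid; integrase/transposase-only regions are mobility
  elements, not phage-related);
* ``candidate_PICI`` — integration machinery plus a major capsid gene, the
  signature of a phage-inducible chromosomal island;
* ``defective_prophage`` — nucleotide-level similarity to an intact phage
  genome, flagged separately from the profile-based classes.

The same module hosts prophage-call QC (omission of calls truncated by
contig ends or diluted with bacterial sequence) and strand-normalized
deduplication of identical prophages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .config import PipelineConfig, DEFAULT_CONFIG
from .core import GeneFeature, GenomeAssembly, ProphageCall, reverse_complement
from .errors import ValidationError
from .homology import (
    PHAGE_GENE_CATEGORIES,
    KmerIndex,
    LocalAlignment,
    ProfileHit,
    find_local_alignments,
)
from .io import PhageDatabase

INTEGRATION_CATEGORIES = frozenset({"integrase", "transposase"})

#: the profile categories the sliding-window scanner listens to (the
#: phage-gene + integrase/transposase database; effector/toxin profiles
#: drive the separate cassette analysis, not region discovery)
REGION_SCAN_CATEGORIES = frozenset(
    {"phage_archetype", "major_capsid", "integrase", "transposase"}
)


@dataclass
class GenomicRegion:
    """A maximal run of qualifying windows on one contig."""

    contig_id: str
    rank_start: int  # inclusive gene-rank span
    rank_end: int
    start: int  # bp interval [start, end)
    end: int
    hits: list[ProfileHit] = field(default_factory=list)
    classes: set[str] = field(default_factory=set)
    nt_evidence: list[LocalAlignment] = field(default_factory=list)

    @property
    def gene_rank_span(self) -> tuple[int, int]:
        return (self.rank_start, self.rank_end)

    @property
    def bp_interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def scan_regions(
    genes: Sequence[GeneFeature],
    hits: Sequence[ProfileHit],
    window_size: int = 15,
    extent: str = "window_union",
) -> list[GenomicRegion]:
    """Slide a *window_size*-gene window over one contig's genes and merge
    qualifying windows into regions.

    *genes* must be the rank-ordered genes of a single contig; *hits* are
    significant profile hits (hits on unknown genes raise).  With the
    default ``window_union`` extent a region spans every gene of every
    qualifying window (a lone hit therefore spans up to 2·window−1 genes,
    clipped at contig ends); ``hit_bounded`` shrinks each region to its
    first-to-last hit gene.
    """
    if window_size < 1:
        raise ValidationError(f"window_size must be >= 1, got {window_size}")
    if not genes:
        return []
    contig_ids = {g.contig_id for g in genes}
    if len(contig_ids) != 1:
        raise ValidationError("scan_regions expects genes of a single contig")
    by_id = {g.gene_id: g for g in genes}
    rank_of = {g.gene_id: g.rank for g in genes}
    significant = [h for h in hits if h.significant]
    for hit in significant:
        if hit.gene_id not in by_id:
            raise ValidationError(f"hit references unknown gene {hit.gene_id}")

    n = len(genes)
    hit_ranks = sorted({rank_of[h.gene_id] for h in significant})
    if not hit_ranks:
        return []

    # union of all windows containing each hit (windows clipped at ends)
    spans: list[tuple[int, int]] = []
    for r in hit_ranks:
        if n <= window_size:
            spans.append((0, n - 1))
        else:
            lo = max(0, r - window_size + 1)
            hi = min(r + window_size - 1, n - 1)
            spans.append((lo, hi))
    merged: list[list[int]] = []
    for lo, hi in spans:
        if merged and lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])

    genes_by_rank = {g.rank: g for g in genes}
    regions: list[GenomicRegion] = []
    contig_id = genes[0].contig_id
    for lo, hi in merged:
        if extent == "hit_bounded":
            in_span = [r for r in hit_ranks if lo <= r <= hi]
            lo, hi = min(in_span), max(in_span)
        span_hits = sorted(
            (h for h in significant if lo <= rank_of[h.gene_id] <= hi),
            key=lambda h: (rank_of[h.gene_id], h.category, h.profile_id),
        )
        regions.append(
            GenomicRegion(
                contig_id=contig_id,
                rank_start=lo,
                rank_end=hi,
                start=genes_by_rank[lo].start,
                end=genes_by_rank[hi].end,
                hits=span_hits,
            )
        )
    return regions


def classify_region(
    region: GenomicRegion, prophage_calls: Sequence[ProphageCall] = ()
) -> set[str]:
    """Apply the non-exclusive classification rules to one region.

    ``prophage_calls`` are accepted (non-omitted) calls; a region
    overlapping one by at least 1 bp is not counted as an integrated
    element (the prophage already accounts for it).
    """
    categories = {h.category for h in region.hits if h.significant}
    classes: set[str] = set()
    overlaps_prophage = any(
        c.status != "omitted"
        and c.contig_id == region.contig_id
        and region.start < c.end
        and c.start < region.end
        for c in prophage_calls
    )
    if categories & INTEGRATION_CATEGORIES and not overlaps_prophage:
        classes.add("integrated_element")
    if categories & PHAGE_GENE_CATEGORIES:
        classes.add("phage_related")
    if "integrase" in categories and "major_capsid" in categories:
        classes.add("candidate_PICI")
    region.classes = classes
    return classes


def flag_defective(
    region: GenomicRegion,
    assembly: GenomeAssembly,
    intact_phage_db: PhageDatabase,
    config: PipelineConfig = DEFAULT_CONFIG,
    mask_intervals: Sequence[tuple[int, int]] = (),
    index: Optional[KmerIndex] = None,
) -> tuple[bool, list[LocalAlignment]]:
    """Label a phage-like region a likely defective prophage when its
    sequence aligns significantly to one or more intact phage genomes.

    *mask_intervals* (contig coordinates) are N-masked before the search,
    so accepted prophages inside a region do not themselves count as
    defective evidence.  The same operation run against a reference set
    of known defective elements (e.g. the phiRv1/phiRv2 family)
    identifies those elements.
    """
    sequence = assembly.contig(region.contig_id).sequence[region.start : region.end]
    for m_start, m_end in mask_intervals:
        lo = max(m_start, region.start) - region.start
        hi = min(m_end, region.end) - region.start
        if hi > lo:
            sequence = sequence[:lo] + "N" * (hi - lo) + sequence[hi:]
    evidence = find_local_alignments(
        sequence,
        index if index is not None else dict(intact_phage_db.items()),
        min_len=config.defective_min_len_bp,
        min_identity=config.min_alignment_identity,
        k=config.seed_kmer,
        xdrop=config.xdrop,
        query_id=region.contig_id,
    )
    region.nt_evidence = evidence
    if evidence:
        region.classes.add("defective_prophage")
    return (bool(evidence), evidence)


def filter_prophage_calls(
    calls: Sequence[ProphageCall],
    assembly: GenomeAssembly,
    genes: Sequence[GeneFeature],
    hits: Sequence[ProfileHit],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[list[ProphageCall], list[ProphageCall]]:
    """Omit calls truncated by contig ends or carrying excess bacterial
    sequence.

    A call is *truncated* when a boundary lies within
    ``truncation_margin_bp`` of a contig end and no att core was
    recovered; it is *contaminated* when fewer than
    ``bacterial_contamination_threshold`` of its genes carry significant
    phage-gene profile hits.  Omitted calls are retained with
    ``status="omitted"`` and a reason, so reports can account for them.
    """
    phage_genes = {
        h.gene_id for h in hits if h.significant and h.category in PHAGE_GENE_CATEGORIES
    }
    genes_by_contig: dict[str, list[GeneFeature]] = {}
    for g in genes:
        genes_by_contig.setdefault(g.contig_id, []).append(g)

    kept: list[ProphageCall] = []
    omitted: list[ProphageCall] = []
    for call in calls:
        contig = assembly.contig(call.contig_id)
        reason = None
        near_start = call.start <= config.truncation_margin_bp
        near_end = call.end >= contig.length - config.truncation_margin_bp
        if (near_start or near_end) and call.core_att is None:
            reason = "truncated_by_contig_end"
        else:
            inside = [
                g
                for g in genes_by_contig.get(call.contig_id, [])
                if g.start >= call.start and g.end <= call.end
            ]
            fraction = (
                sum(1 for g in inside if g.gene_id in phage_genes) / len(inside)
                if inside
                else 0.0
            )
            if fraction < config.bacterial_contamination_threshold:
                reason = "excess_bacterial_sequence"
        if reason is None:
            kept.append(call)
        else:
            call.status = "omitted"
            call.omission_reason = reason
            omitted.append(call)
    return kept, omitted


def dedupe_prophages(
    calls: Sequence[ProphageCall],
) -> tuple[list[ProphageCall], list[tuple[str, int, list[str]]]]:
    """Collapse byte-identical prophages (up to reverse complement).

    Many prophages recur across strains; the unique (non-redundant) set
    groups calls by the lexicographically smaller of the sequence and its
    reverse complement, keeps the smallest designation as representative,
    and reports multiplicities.
    """
    groups: dict[str, list[ProphageCall]] = {}
    for call in calls:
        key = min(call.sequence, reverse_complement(call.sequence))
        groups.setdefault(key, []).append(call)
    unique: list[ProphageCall] = []
    table: list[tuple[str, int, list[str]]] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda c: c.designation)
        unique.append(members[0])
        table.append(
            (members[0].designation, len(members), [c.designation for c in members])
        )
    unique.sort(key=lambda c: c.designation)
    table.sort(key=lambda row: row[0])
    return unique, table
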