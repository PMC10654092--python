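"""Attachment-site machinery.

Integrase-mediated recombination between a bacterial attB and a phage
attP duplicates their shared *core* sequence as direct repeats (attL and
attR) flanking the integrated prophage.  This module finds that core at
prophage boundaries as the longest exact direct repeat, maps att
occurrences from many strains onto one reference chromosome, collapses
overlapping occurrences into consensus attB sites (conserved coordinate
positions), reconstructs attP by circularizing the prophage at the core,
and annotates attB overlap with tRNA/tmRNA genes (the classic
tyrosine-integrase targets).

Serine-integrase cores can be shorter than the default 10 bp minimum and
are then missed — lower ``min_core_len_bp`` to chase them at the cost of
chance repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .config import PipelineConfig, DEFAULT_CONFIG
from .core import GenomeAssembly, RnaFeature
from .errors import ConsistencyError, ValidationError
from .homology import find_local_alignments


@dataclass(frozen=True)
class AttCore:
    """The exact direct repeat flanking an integrated prophage."""

    sequence: str
    attL_start: int
    attL_end: int
    attR_start: int
    attR_end: int

    def __post_init__(self) -> None:
        if self.attL_end - self.attL_start != len(self.sequence) or (
            self.attR_end - self.attR_start != len(self.sequence)
        ):
            raise ValidationError("att core intervals must match core length")
        if self.attL_start >= self.attR_start:
            raise ValidationError("attL must lie left of attR")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def attL_interval(self) -> tuple[int, int]:
        return (self.attL_start, self.attL_end)

    @property
    def attR_interval(self) -> tuple[int, int]:
        return (self.attR_start, self.attR_end)


def find_core_repeats(
    assembly: GenomeAssembly,
    contig_id: str,
    prophage_interval: tuple[int, int],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> Optional[AttCore]:
    """Longest exact direct repeat spanning a prophage's two boundaries.

    One copy must fall in the window ``boundary_search_bp`` either side of
    the left boundary, the other in the mirrored right-boundary window;
    copies must not overlap.  Ties at the maximal length are broken by
    leftmost attL, then leftmost attR.  Returns ``None`` when no repeat of
    at least ``min_core_len_bp`` exists.
    """
    contig = assembly.contig(contig_id)
    left, right = prophage_interval
    if not (0 <= left < right <= contig.length):
        raise IndexError(
            f"prophage interval [{left},{right}) outside contig {contig_id}"
        )
    b = config.boundary_search_bp
    lw_start, lw_end = max(0, left - b), min(contig.length, left + b)
    rw_start, rw_end = max(0, right - b), min(contig.length, right + b)
    lw = contig.sequence[lw_start:lw_end]
    rw = contig.sequence[rw_start:rw_end]

    # anchor min-length k-mers shared by the two windows, extend each match
    # maximally, and keep the longest (ties: leftmost attL, then attR)
    k0 = config.min_core_len_bp
    if len(lw) < k0 or len(rw) < k0:
        return None
    index: dict[str, list[int]] = {}
    for i in range(len(lw) - k0 + 1):
        sub = lw[i : i + k0]
        if "N" not in sub:
            index.setdefault(sub, []).append(i)
    matches: set[tuple[int, int, int]] = set()  # (l_pos, r_pos, length), maximal
    for j in range(len(rw) - k0 + 1):
        for i in index.get(rw[j : j + k0], ()):
            # extend the anchor to a maximal exact match
            li, rj = i, j
            while li > 0 and rj > 0 and lw[li - 1] == rw[rj - 1] != "N":
                li -= 1
                rj -= 1
            le, re_ = i + k0, j + k0
            while le < len(lw) and re_ < len(rw) and lw[le] == rw[re_] != "N":
                le += 1
                re_ += 1
            matches.add((lw_start + li, rw_start + rj, le - li))
    candidates = [
        (l_pos, r_pos, length)
        for l_pos, r_pos, length in matches
        if r_pos >= l_pos + length  # non-overlapping direct repeat copies
    ]
    # a maximal overlapping repeat may still contain a valid shorter core:
    # shrink overlapping matches to the longest non-overlapping prefix pair
    for l_pos, r_pos, length in matches:
        if r_pos < l_pos + length and r_pos > l_pos:
            shrunk = r_pos - l_pos
            if shrunk >= k0:
                candidates.append((l_pos, r_pos, shrunk))
    if not candidates:
        return None
    best_len = max(c[2] for c in candidates)
    l_pos, r_pos, _ = min(c for c in candidates if c[2] == best_len)
    return AttCore(
        sequence=contig.sequence[l_pos : l_pos + best_len],
        attL_start=l_pos,
        attL_end=l_pos + best_len,
        attR_start=r_pos,
        attR_end=r_pos + best_len,
    )


# ---------------------------------------------------------------------------
# Mapping occurrences onto a reference chromosome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AttOccurrence:
    """One strain's att site: the core with host-side flanks for placement."""

    strain_id: str
    core: str
    sequence: str  # left host flank + core + right host flank
    core_start: int  # core position within `sequence`
    core_end: int
    integrase_class: str = "unknown"  # Int-Y | Int-S | unknown


@dataclass
class LocatedOccurrence:
    occurrence: AttOccurrence
    ref_start: Optional[int] = None
    ref_end: Optional[int] = None
    ambiguous: bool = False

    @property
    def placed(self) -> bool:
        return self.ref_start is not None and not self.ambiguous


def map_att_to_reference(
    occurrences: Sequence[AttOccurrence],
    reference_assembly: GenomeAssembly,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[LocatedOccurrence]:
    """Place each occurrence's core on a closed reference chromosome.

    The core plus its host flanks is aligned to the reference; the best
    alignment covering the core yields the core's reference coordinates.
    Two or more equally good loci flag the occurrence ambiguous; an
    occurrence with no adequate placement stays unplaced.
    """
    if reference_assembly.contig_count != 1:
        raise ValidationError("reference must be a single closed chromosome")
    ref = reference_assembly.contigs[0]
    from .homology import KmerIndex

    ref_index = KmerIndex({ref.contig_id: ref.sequence}, config.seed_kmer)
    located: list[LocatedOccurrence] = []
    for occ in occurrences:
        alignments = find_local_alignments(
            occ.sequence,
            ref_index,
            min_len=max(config.seed_kmer, len(occ.core)),
            min_identity=config.min_alignment_identity,
            k=config.seed_kmer,
            xdrop=config.xdrop,
            query_id=occ.strain_id,
        )
        covering = [
            a
            for a in alignments
            if a.q_start <= occ.core_start and a.q_end >= occ.core_end
        ]
        rec = LocatedOccurrence(occ)
        if covering:
            best_score = max(a.score for a in covering)
            best = [a for a in covering if a.score == best_score]
            loci = set()
            for a in best:
                if a.strand == "+":
                    start = a.s_start + (occ.core_start - a.q_start)
                else:
                    start = a.s_start + (a.q_end - occ.core_end)
                loci.add(start)
            if len(loci) > 1:
                rec.ambiguous = True
            else:
                start = loci.pop()
                rec.ref_start, rec.ref_end = start, start + len(occ.core)
        located.append(rec)
    return located


@dataclass
class ConsensusAttB:
    """A consensus attB site: overlapping occurrences collapsed to their
    conserved coordinate positions on the reference."""

    attB_id: str
    start: int
    end: int
    occurrences: list[tuple[str, tuple[int, int]]]
    integrase_class: str = "unknown"
    class_conflict: bool = False
    overlap_feature: Optional[str] = None

    @property
    def reference_interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _majority_class(classes: Sequence[str]) -> tuple[str, bool]:
    known = [c for c in classes if c and c != "unknown"]
    if not known:
        return "unknown", False
    counts: dict[str, int] = {}
    for c in known:
        counts[c] = counts.get(c, 0) + 1
    best = max(counts.values())
    winners = sorted(c for c, n in counts.items() if n == best)
    conflict = len(counts) > 1
    return (winners[0] if len(winners) == 1 else "unknown"), conflict


def consensus_attB(
    located: Sequence[LocatedOccurrence],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[ConsensusAttB]:
    """Collapse placed occurrences into consensus attB sites.

    Occurrences are grouped into overlap-connected components along the
    reference; each group's consensus interval is the intersection of its
    member intervals — the coordinate positions conserved across every
    strain ("majority" mode instead takes positions covered by more than
    half the members).  Groups are numbered attB-1, attB-2, ... by
    reference position.  A chain whose intersection is empty is split at
    its largest coverage gap, with a warning.
    """
    placed = sorted(
        (rec for rec in located if rec.placed),
        key=lambda r: (r.ref_start, r.ref_end, r.occurrence.strain_id),
    )
    groups: list[list[LocatedOccurrence]] = []
    group_end = None
    for rec in placed:
        if groups and rec.ref_start < group_end:
            groups[-1].append(rec)
            group_end = max(group_end, rec.ref_end)
        else:
            groups.append([rec])
            group_end = rec.ref_end

    def consensus_of(group: list[LocatedOccurrence]) -> list[ConsensusAttB]:
        if config.att_consensus == "majority":
            lo = min(r.ref_start for r in group)
            hi = max(r.ref_end for r in group)
            need = len(group) / 2.0
            cols = [
                pos
                for pos in range(lo, hi)
                if sum(1 for r in group if r.ref_start <= pos < r.ref_end) > need
            ]
            if cols:
                return [_make_site(group, cols[0], cols[-1] + 1)]
            start, end = lo, lo  # degenerate; fall through to split below
        else:
            start = max(r.ref_start for r in group)
            end = min(r.ref_end for r in group)
        if start < end:
            return [_make_site(group, start, end)]
        # pathological chain: split at the largest gap between adjacent starts
        warnings.warn(
            "att occurrence chain with empty intersection; splitting at the "
            "largest coverage gap"
        )
        gaps = [
            group[i + 1].ref_start - group[i].ref_end for i in range(len(group) - 1)
        ]
        cut = max(range(len(gaps)), key=lambda i: gaps[i]) + 1
        return consensus_of(group[:cut]) + consensus_of(group[cut:])

    def _make_site(group: list[LocatedOccurrence], start: int, end: int) -> ConsensusAttB:
        int_class, conflict = _majority_class(
            [r.occurrence.integrase_class for r in group]
        )
        return ConsensusAttB(
            attB_id="",
            start=start,
            end=end,
            occurrences=[
                (r.occurrence.strain_id, (r.ref_start, r.ref_end)) for r in group
            ],
            integrase_class=int_class,
            class_conflict=conflict,
        )

    sites: list[ConsensusAttB] = []
    for group in groups:
        sites.extend(consensus_of(group))
    sites.sort(key=lambda s: (s.start, s.end))
    for i, site in enumerate(sites, start=1):
        site.attB_id = f"attB-{i}"
    return sites


# ---------------------------------------------------------------------------
# attP reconstruction and in-silico integration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AttPJunction:
    """The excised phage circle, linearized at the att core junction."""

    sequence: str  # core + internal phage sequence (one core copy)
    core: str
    attP_region: str  # core with up to `flank` bp of phage-side flank


def reconstruct_attP(
    prophage_sequence: str, core: str, flank: int = 250
) -> AttPJunction:
    """Circularize a prophage at its core att repeats to recover attP.

    The prophage must begin with one core copy (attL) and end with the
    other (attR); excision joins them into a single copy on the circle,
    so the output has length ``len(prophage) − len(core)`` and carries the
    core exactly once at the junction.
    """
    if isinstance(core, AttCore):
        core = core.sequence
    k = len(core)
    if k == 0 or len(prophage_sequence) < 2 * k:
        raise ConsistencyError("prophage shorter than two core copies")
    if not prophage_sequence.startswith(core) or not prophage_sequence.endswith(core):
        raise ConsistencyError("att core not found at both prophage ends")
    circle = prophage_sequence[: len(prophage_sequence) - k]
    left_flank = circle[-flank:] if len(circle) > k + flank else circle[k:]
    right_flank = circle[k : k + flank]
    return AttPJunction(
        sequence=circle, core=core, attP_region=left_flank + core + right_flank
    )


def integrate_at_attB(host_sequence: str, attB_position: int, junction: AttPJunction) -> str:
    """In-silico site-specific integration of an excised circle.

    The host must carry the core (the attB) at *attB_position*; the core
    is duplicated into attL/attR flanking the incoming phage sequence.
    Excision followed by integration at the original attB restores the
    lysogen exactly.
    """
    core = junction.core
    k = len(core)
    if host_sequence[attB_position : attB_position + k] != core:
        raise ConsistencyError(f"host attB at {attB_position} does not match core")
    internal = junction.sequence[k:]
    return (
        host_sequence[:attB_position]
        + core
        + internal
        + core
        + host_sequence[attB_position + k :]
    )


def annotate_overlap(
    site: ConsensusAttB, features: Sequence[RnaFeature]
) -> Optional[str]:
    """The tRNA/tmRNA feature overlapping a consensus attB (≥1 bp), if any.

    Ties go to the largest overlap.  Returns a display string such as
    ``"tRNA-Arg (TCT)"`` or ``"tmRNA"`` and records it on the site.
    """
    best: Optional[RnaFeature] = None
    best_overlap = 0
    for feat in features:
        overlap = min(site.end, feat.end) - max(site.start, feat.start)
        if overlap > 0 and (
            overlap > best_overlap
            or (overlap == best_overlap and best and feat.start < best.start)
        ):
            best, best_overlap = feat, overlap
    if best is None:
        site.overlap_feature = None
        return None
    label = best.isotype if best.kind == "tRNA" and best.isotype else best.kind
    site.overlap_feature = label
    return label
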