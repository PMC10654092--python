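"""PEST cassette discovery.

Phage-encoded ESX-secreted toxins (PESTs) are cassettes of a WXG100
effector (sometimes two), a polymorphic toxin (PT) and an immunity
protein (Imm), encoded together in prophages.  Discovery proceeds in
pham space: phams matching known PT/WXG/Imm profiles seed an iterative
gene-neighborhood network (each anchor gene contributes the phams of
genes within a small ORF radius; newly reached phams anchor the next
round, to a fixpoint), cassettes are read off contiguous same-strand
runs of role-bearing genes around each PT, PT phams are grouped into
superfamilies by profile–profile alignment of their N-terminal secretion
domains, and per-column conservation over aligned PT proteins exposes
the WXG / linker / TOX domain boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .config import PipelineConfig, DEFAULT_CONFIG
from .core import GeneFeature
from .errors import ConfigurationError, ValidationError
from .homology import ProfileDatabase, Pssm, score_profile

PEST_ROLES = ("polymorphic_toxin", "wxg100", "immunity")
_ROLE_SHORT = {"polymorphic_toxin": "PT", "wxg100": "WXG", "immunity": "Imm"}


# ---------------------------------------------------------------------------
# Homology seeding
# ---------------------------------------------------------------------------


def seed_pest_homologs(
    phams: Mapping[str, Sequence[tuple[str, str]]],
    profile_db: ProfileDatabase,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict[str, str]:
    """Assign PEST roles to phams by profile homology.

    *phams* maps pham_id to its member ``(gene_id, protein)`` pairs.  A
    pham is seeded for a role when any member scores a significant hit
    against a profile of that role; a pham takes at most one role — the
    best-scoring one wins and ties break by role order PT > WXG > Imm.
    Returns pham_id -> role (roles are the profile categories
    ``polymorphic_toxin`` / ``wxg100`` / ``immunity``).
    """
    role_profiles = {role: profile_db.by_category(role) for role in PEST_ROLES}
    if not any(role_profiles.values()):
        raise ConfigurationError("profile database has no PEST role profiles")
    roles: dict[str, str] = {}
    for pham_id in sorted(phams):
        best_role: Optional[str] = None
        best_score = -np.inf
        for role in PEST_ROLES:  # fixed order is the tie-break
            for profile in role_profiles[role]:
                for _, protein in phams[pham_id]:
                    hit = score_profile(
                        protein, profile, config.profile_score_threshold
                    )
                    if hit.significant and hit.score > best_score:
                        best_score = hit.score
                        best_role = role
        if best_role is not None:
            roles[pham_id] = best_role
    return roles


# ---------------------------------------------------------------------------
# Gene-neighborhood network
# ---------------------------------------------------------------------------


@dataclass
class NeighborhoodNetwork:
    """Pham-level adjacency network grown from polymorphic-toxin seeds."""

    nodes: set[str]
    edges: dict[tuple[str, str], int]  # unordered pham pair -> adjacency count
    seeds: set[str]
    iterations_to_fixpoint: int

    def edge_list(self) -> list[tuple[str, str, int]]:
        return sorted((a, b, n) for (a, b), n in self.edges.items())


def build_neighborhood_network(
    genes: Sequence[GeneFeature],
    gene_to_pham: Mapping[str, str],
    seed_phams: Iterable[str],
    radius: int = 2,
    expansion: str = "full",
) -> NeighborhoodNetwork:
    """Iterate the gene-neighborhood search to a fixpoint.

    Every gene of an anchor pham contributes the phams of genes within
    *radius* ORFs up/downstream on its contig (rank distance; strand is
    ignored and contig ends truncate silently), creating edges between the
    anchor pham and each neighbor pham.  With ``expansion="full"`` every
    pham reached becomes an anchor in the next iteration, so the fixpoint
    is the connected component of the radius-adjacency pham graph around
    the seeds; ``"seeds_only"`` stops after the first ring.
    """
    for g in genes:
        if g.gene_id not in gene_to_pham:
            raise ValidationError(f"gene {g.gene_id} has no pham assignment")
    seeds = set(seed_phams)
    if not seeds:
        return NeighborhoodNetwork(set(), {}, set(), 0)

    by_contig: dict[str, list[GeneFeature]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    for contig in by_contig:
        by_contig[contig].sort(key=lambda g: g.rank)
    members: dict[str, list[tuple[str, int]]] = {}  # pham -> [(contig, idx)]
    for contig, contig_genes in by_contig.items():
        for idx, g in enumerate(contig_genes):
            members.setdefault(gene_to_pham[g.gene_id], []).append((contig, idx))

    nodes: set[str] = set(seeds)
    edges: dict[tuple[str, str], int] = {}
    frontier = set(seeds)
    iterations = 0
    while frontier:
        iterations += 1
        new_nodes: set[str] = set()
        for anchor in sorted(frontier):
            for contig, idx in members.get(anchor, ()):
                contig_genes = by_contig[contig]
                lo = max(0, idx - radius)
                hi = min(len(contig_genes), idx + radius + 1)
                for j in range(lo, hi):
                    if j == idx:
                        continue
                    neighbor = gene_to_pham[contig_genes[j].gene_id]
                    if neighbor != anchor:
                        key = (min(anchor, neighbor), max(anchor, neighbor))
                        edges[key] = edges.get(key, 0) + 1
                    if neighbor not in nodes:
                        new_nodes.add(neighbor)
        nodes |= new_nodes
        if expansion == "seeds_only":
            break
        frontier = new_nodes
    return NeighborhoodNetwork(nodes, edges, seeds, iterations)


# ---------------------------------------------------------------------------
# Cassette extraction
# ---------------------------------------------------------------------------


@dataclass
class PESTCassette:
    """One extracted cassette around a polymorphic-toxin gene."""

    genome_id: str
    contig_id: str
    gene_ids: list[str]
    roles: list[str]  # over {"WXG", "PT", "Imm"} in gene-strand reading order
    architecture: str  # three_gene | four_gene | incomplete
    superfamily: str = "unassigned"

    def __post_init__(self) -> None:
        if self.roles.count("PT") != 1:
            raise ValidationError("a cassette must contain exactly one PT")


def extract_cassettes(
    genes: Sequence[GeneFeature],
    gene_roles: Mapping[str, str],
    genome_id: str = "",
) -> list[PESTCassette]:
    """Read cassettes off contiguous same-strand runs of role-bearing genes.

    For every polymorphic-toxin gene, the maximal run of rank-adjacent,
    same-strand genes with assigned roles around it is collected and read
    in the strand's direction.  ``[WXG, PT, Imm]`` is the canonical
    three-gene cassette, ``[WXG, WXG, PT, Imm]`` the four-gene variant
    with tandem effectors; any other PT-containing run is reported as
    incomplete with its observed roles.
    """
    by_contig: dict[str, list[GeneFeature]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    cassettes: list[PESTCassette] = []
    for contig in sorted(by_contig):
        contig_genes = sorted(by_contig[contig], key=lambda g: g.rank)
        consumed: set[int] = set()
        for idx, gene in enumerate(contig_genes):
            if gene_roles.get(gene.gene_id) != "polymorphic_toxin":
                continue
            if idx in consumed:
                continue
            strand = gene.strand
            lo = idx
            while (
                lo - 1 >= 0
                and contig_genes[lo - 1].strand == strand
                and contig_genes[lo - 1].gene_id in gene_roles
            ):
                lo -= 1
            hi = idx
            while (
                hi + 1 < len(contig_genes)
                and contig_genes[hi + 1].strand == strand
                and contig_genes[hi + 1].gene_id in gene_roles
            ):
                hi += 1
            run = contig_genes[lo : hi + 1]
            consumed.update(range(lo, hi + 1))
            if strand == "-":
                run = run[::-1]  # read in the genes' transcription direction
            roles = [_ROLE_SHORT[gene_roles[g.gene_id]] for g in run]
            if roles == ["WXG", "PT", "Imm"]:
                architecture = "three_gene"
            elif roles == ["WXG", "WXG", "PT", "Imm"]:
                architecture = "four_gene"
            else:
                architecture = "incomplete"
            cassettes.append(
                PESTCassette(
                    genome_id=genome_id,
                    contig_id=contig,
                    gene_ids=[g.gene_id for g in run],
                    roles=roles,
                    architecture=architecture,
                )
            )
    return cassettes


# ---------------------------------------------------------------------------
# Superfamily grouping
# ---------------------------------------------------------------------------


def _profile_profile_score(a: Pssm, b: Pssm) -> tuple[float, int]:
    """Best ungapped offset score between two profiles.

    Columns contribute the dot product of their mean-centered log-odds
    vectors — large and positive when both profiles concentrate on the
    same residue, near zero for unrelated columns (centering removes the
    systematic positive product of two columns' background penalties,
    which would otherwise let any two sharp profiles score).  Returns
    (best score, overlap columns at the best offset).
    """
    ma = a.matrix - a.matrix.mean(axis=1, keepdims=True)
    mb = b.matrix - b.matrix.mean(axis=1, keepdims=True)
    best = (-np.inf, 0)
    for off in range(-(b.length - 1), a.length):
        a_lo, a_hi = max(0, off), min(a.length, off + b.length)
        if a_hi - a_lo <= 0:
            continue
        b_lo = a_lo - off
        score = float((ma[a_lo:a_hi] * mb[b_lo : b_lo + (a_hi - a_lo)]).sum())
        if score > best[0]:
            best = (score, a_hi - a_lo)
    return best


def group_superfamilies(
    pt_phams: Mapping[str, Sequence[tuple[str, str]]],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict[str, str]:
    """Group polymorphic-toxin phams into superfamilies by their shared
    N-terminal secretion domains.

    Each pham gets a profile over its members' N-terminal windows
    (``pest_nterm_window_aa``); pham pairs whose profile–profile score
    exceeds ``pest_pp_threshold_bits_per_col`` per overlapped column (with
    a minimum overlap) are connected, and connected components become
    superfamilies PEST1, PEST2, PEST3, ... in decreasing size (ties by
    smallest pham id); components beyond the third are ``unassigned-k``.
    Returns pham_id -> superfamily label.
    """
    import networkx as nx

    if not pt_phams:
        return {}
    window = config.pest_nterm_window_aa
    profiles: dict[str, Pssm] = {}
    for pham_id in sorted(pt_phams):
        windows = [p[:window] for _, p in pt_phams[pham_id]]
        width = min(len(w) for w in windows)
        profiles[pham_id] = Pssm(pham_id, "polymorphic_toxin", [w[:width] for w in windows])

    graph = nx.Graph()
    graph.add_nodes_from(profiles)
    ids = sorted(profiles)
    for i, pa in enumerate(ids):
        for pb in ids[i + 1 :]:
            score, overlap = _profile_profile_score(profiles[pa], profiles[pb])
            if (
                overlap >= config.pest_pp_min_overlap_cols
                and score >= config.pest_pp_threshold_bits_per_col * overlap
            ):
                graph.add_edge(pa, pb)
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), c[0]),
    )
    labels: dict[str, str] = {}
    for idx, component in enumerate(components):
        label = f"PEST{idx + 1}" if idx < 3 else f"unassigned-{idx - 2}"
        for pham_id in component:
            labels[pham_id] = label
    return labels


# ---------------------------------------------------------------------------
# Conservation profiling
# ---------------------------------------------------------------------------


@dataclass
class ConservationProfile:
    """Per-column conservation over aligned PT proteins, with inferred
    WXG / linker / TOX segment boundaries."""

    values: np.ndarray  # raw per-column conservation in [0, 1]
    smoothed: np.ndarray
    smooth_window: int
    segments: list[tuple[str, int, int]]  # (label, col_start, col_end) half-open


def conservation_profile(
    aligned: Sequence[str], smooth_window: int = 15
) -> ConservationProfile:
    """Column-wise conservation of an alignment, smoothed, segmented.

    Conservation is the frequency of the modal residue (gaps excluded
    from the numerator but counted in the denominator).  A centered
    moving average smooths the track; thresholding at the track mean
    splits it into the leading conserved segment (the WXG secretion
    domain), a variable middle (linker) and the trailing conserved
    segment (TOX) — mirroring how domain boundaries show up in real
    polymorphic-toxin families.
    """
    if len(aligned) < 2:
        raise ValidationError("need at least two aligned sequences")
    lengths = {len(s) for s in aligned}
    if len(lengths) != 1:
        raise ValidationError("ragged alignment: sequences differ in length")
    n_cols = lengths.pop()
    n_seqs = len(aligned)
    values = np.zeros(n_cols)
    for col in range(n_cols):
        counts: dict[str, int] = {}
        for seq in aligned:
            aa = seq[col]
            if aa != "-":
                counts[aa] = counts.get(aa, 0) + 1
        values[col] = max(counts.values()) / n_seqs if counts else 0.0

    kernel = np.ones(smooth_window) / smooth_window
    padded = np.pad(values, smooth_window // 2, mode="edge")
    smoothed = np.convolve(padded, kernel, mode="valid")[:n_cols]

    mean = smoothed.mean()
    high = smoothed >= mean
    if high.all() or not high.any():
        segments = [("WXG", 0, n_cols)]
    else:
        first_low = int(np.argmin(high))  # first False
        last_low = n_cols - 1 - int(np.argmin(high[::-1]))
        if first_low == 0 or last_low == n_cols - 1:
            # conservation does not drop internally on both flanks; report
            # a single partition at the largest low run
            segments = [("WXG", 0, n_cols)]
        else:
            segments = [
                ("WXG", 0, first_low),
                ("linker", first_low, last_low + 1),
                ("TOX", last_low + 1, n_cols),
            ]
    return ConservationProfile(values, smoothed, smooth_window, segments)
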