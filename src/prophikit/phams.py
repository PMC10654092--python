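"""Protein phamilies, shared gene content, clusters, and the relatedness
network.

A *pham* (phamily) is a transitive-closure cluster of related protein
sequences: two proteins are directly related when their global identity is
at least ``identity_threshold`` and the shorter covers at least
``coverage_threshold`` of the longer (defaults 50%/50%).  Genome-level
relatedness is then measured as shared gene content — the fraction of
phams two genomes have in common — with cluster membership at 35% and a
looser relatedness network drawn at 25%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import networkx as nx

from .config import PipelineConfig, DEFAULT_CONFIG
from .errors import ValidationError


def protein_identity(a: str, b: str) -> float:
    """Global (end-to-end) identity: 1 − edit_distance / max(len)."""
    if not a or not b:
        raise ValidationError("empty protein in identity computation")
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def proteins_related(
    a: str, b: str, identity_threshold: float, coverage_threshold: float
) -> bool:
    """The pairwise pham relation: identity and coverage of the longer."""
    coverage = min(len(a), len(b)) / max(len(a), len(b))
    if coverage < coverage_threshold:
        return False
    return protein_identity(a, b) >= identity_threshold


@dataclass
class Pham:
    """One phamily: a set of gene ids plus a representative sequence."""

    pham_id: str
    members: frozenset[str]
    representative: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"pham {self.pham_id} has no members")


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_phams(
    proteins: Mapping[str, str] | Sequence[tuple[str, str]],
    identity_threshold: float = 0.50,
    coverage_threshold: float = 0.50,
) -> list[Pham]:
    """Partition proteins into phams by transitive closure of the pairwise
    relation.

    Identical sequences are deduplicated before the all-pairs pass, and a
    length-ratio prefilter skips pairs that cannot meet the coverage
    condition, so corpora with many exact gene copies stay fast.  Pham ids
    ``pham_0001, ...`` are assigned in order of each pham's first gene in
    the input order (stable for a fixed input).
    """
    if not 0 < identity_threshold <= 1 or not 0 < coverage_threshold <= 1:
        raise ValidationError("thresholds must be in (0, 1]")
    items = list(proteins.items()) if isinstance(proteins, Mapping) else list(proteins)
    if not items:
        return []
    gene_ids = [g for g, _ in items]
    if len(gene_ids) != len(set(gene_ids)):
        raise ValidationError("duplicate gene_ids in protein set")
    for g, p in items:
        if not p:
            raise ValidationError(f"empty protein for gene {g}")

    # deduplicate exact sequences
    unique: dict[str, int] = {}
    gene_to_unique: list[int] = []
    unique_seqs: list[str] = []
    for _, seq in items:
        if seq not in unique:
            unique[seq] = len(unique_seqs)
            unique_seqs.append(seq)
        gene_to_unique.append(unique[seq])

    n = len(unique_seqs)
    uf = _UnionFind(n)
    order = sorted(range(n), key=lambda i: len(unique_seqs[i]))
    for a_pos in range(n):
        i = order[a_pos]
        li = len(unique_seqs[i])
        for b_pos in range(a_pos + 1, n):
            j = order[b_pos]
            lj = len(unique_seqs[j])
            if li / lj < coverage_threshold:  # sorted by length: lj >= li
                break
            if uf.find(i) == uf.find(j):
                continue
            if protein_identity(unique_seqs[i], unique_seqs[j]) >= identity_threshold:
                uf.union(i, j)

    groups: dict[int, list[int]] = {}
    for idx, (gene_id, _) in enumerate(items):
        root = uf.find(gene_to_unique[idx])
        groups.setdefault(root, []).append(idx)

    # order phams by first member appearance
    roots_in_order = sorted(groups, key=lambda r: groups[r][0])
    phams = []
    for k, root in enumerate(roots_in_order, start=1):
        member_idx = groups[root]
        members = frozenset(items[i][0] for i in member_idx)
        rep = max(member_idx, key=lambda i: (len(items[i][1]), -i))
        phams.append(Pham(f"pham_{k:04d}", members, items[rep][1]))
    return phams


def pham_membership(phams: Iterable[Pham]) -> dict[str, str]:
    """gene_id -> pham_id map; raises if the partition property is violated."""
    mapping: dict[str, str] = {}
    for pham in phams:
        for gene_id in pham.members:
            if gene_id in mapping:
                raise ValidationError(f"gene {gene_id} present in two phams")
            mapping[gene_id] = pham.pham_id
    return mapping


def phams_by_genome(
    phams: Iterable[Pham], gene_to_genome: Mapping[str, str]
) -> dict[str, frozenset[str]]:
    """The set of distinct phams represented in each genome.

    Paralogs count once: gene content is measured over distinct phams.
    """
    sets: dict[str, set[str]] = {}
    for pham in phams:
        for gene_id in pham.members:
            genome = gene_to_genome[gene_id]
            sets.setdefault(genome, set()).add(pham.pham_id)
    return {g: frozenset(s) for g, s in sets.items()}


def shared_gene_content(
    phams_a: frozenset[str] | set[str],
    phams_b: frozenset[str] | set[str],
    metric: str = "mean",
) -> float:
    """Fraction of gene content two genomes share, in [0, 1].

    ``mean``: average of |A∩B|/|A| and |A∩B|/|B| (symmetric; equals the
    intuitive fraction when |A| == |B|).  ``min_denominator``:
    |A∩B|/max(|A|,|B|), the more conservative variant.
    """
    if not phams_a or not phams_b:
        raise ValidationError("shared_gene_content: empty pham set")
    inter = len(set(phams_a) & set(phams_b))
    if metric == "mean":
        return 0.5 * (inter / len(phams_a) + inter / len(phams_b))
    if metric == "min_denominator":
        return inter / max(len(phams_a), len(phams_b))
    raise ValidationError(f"unknown metric {metric!r}")


@dataclass
class ClusterAssignment:
    """Cluster label per genome, with singleton flags."""

    labels: dict[str, str]
    singletons: dict[str, bool]

    def cluster_members(self) -> dict[str, list[str]]:
        members: dict[str, list[str]] = {}
        for genome, label in sorted(self.labels.items()):
            members.setdefault(label, []).append(genome)
        return members


def _letter_label(index: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA, ... (spreadsheet-style)."""
    label = ""
    index += 1
    while index > 0:
        index, rem = divmod(index - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


def assign_clusters(
    genome_phams: Mapping[str, frozenset[str]],
    threshold: float = 0.35,
    metric: str = "mean",
) -> ClusterAssignment:
    """Group genomes into clusters of ≥ *threshold* shared gene content.

    Clusters are connected components of the graph joining genome pairs at
    or above the threshold; labels A, B, C, ... are assigned in decreasing
    component size (ties broken by smallest member genome id).  A genome
    alone in its component is a singleton — a phage with no close
    relatives at this threshold.
    """
    graph = nx.Graph()
    graph.add_nodes_from(genome_phams)
    genomes = sorted(genome_phams)
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            if shared_gene_content(genome_phams[ga], genome_phams[gb], metric) >= threshold:
                graph.add_edge(ga, gb)
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), c[0]),
    )
    labels: dict[str, str] = {}
    singletons: dict[str, bool] = {}
    for idx, component in enumerate(components):
        label = _letter_label(idx)
        for genome in component:
            labels[genome] = label
            singletons[genome] = len(component) == 1
    return ClusterAssignment(labels, singletons)


def build_proteome_network(
    genome_phams: Mapping[str, frozenset[str]],
    threshold: float = 0.25,
    metric: str = "mean",
) -> list[tuple[str, str, float]]:
    """Undirected relatedness network: edges for pairs at ≥ *threshold*
    shared gene content, each with the metric value; sorted edge list."""
    edges = []
    genomes = sorted(genome_phams)
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            value = shared_gene_content(genome_phams[ga], genome_phams[gb], metric)
            if value >= threshold:
                edges.append((ga, gb, value))
    return edges
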