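"""Independent brute-force oracles used to verify the implementation.

Deliberately naive and written against different primitives than the
package (no edlib, no k-mer seeding, no iterative fixpoint): dynamic
programming, exhaustive enumeration and plain union-find.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# -- nucleotide local alignment ---------------------------------------------


def ungapped_hit_exists(a: str, b: str, min_len: int, min_identity: float) -> bool:
    """Exhaustive diagonal scan: does any ungapped window of length
    ``min_len`` on any diagonal (either strand of *a*) reach the identity
    threshold?  (If a longer window qualifies, its best length-min_len
    sub-window does too, so fixed-length scanning decides hit/no-hit.)"""
    for query in (a, revcomp(a)):
        na, nb = len(query), len(b)
        for diag in range(-(na - 1), nb):
            lo_a = max(0, -diag)
            length = min(na - lo_a, nb - (lo_a + diag))
            if length < min_len:
                continue
            qa = np.frombuffer(query[lo_a : lo_a + length].encode(), dtype=np.uint8)
            qb = np.frombuffer(
                b[lo_a + diag : lo_a + diag + length].encode(), dtype=np.uint8
            )
            matches = ((qa == qb) & (qa != ord("N"))).astype(np.int32)
            window = np.convolve(matches, np.ones(min_len, dtype=np.int32), "valid")
            if window.size and window.max() >= min_identity * min_len:
                return True
    return False


# -- protein comparisons -----------------------------------------------------


def edit_distance(a: str, b: str) -> int:
    """Plain Levenshtein DP (row-vectorized)."""
    if not a:
        return len(b)
    prev = np.arange(len(b) + 1)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    for i, ca in enumerate(a.encode(), start=1):
        cur = np.empty(len(b) + 1, dtype=np.int64)
        cur[0] = i
        sub = prev[:-1] + (bb != ca)
        dele = prev[1:] + 1
        np.minimum(sub, dele, out=sub)
        # insertion needs a sequential pass
        running = cur[0]
        for j in range(1, len(b) + 1):
            running = min(sub[j - 1], running + 1)
            cur[j] = running
        prev = cur
    return int(prev[-1])


def proteins_related_oracle(a: str, b: str, idty: float, cov: float) -> bool:
    if min(len(a), len(b)) / max(len(a), len(b)) < cov:
        return False
    return 1.0 - edit_distance(a, b) / max(len(a), len(b)) >= idty


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra

    def groups(self):
        out = {}
        for x in self.parent:
            out.setdefault(self.find(x), set()).add(x)
        return {frozenset(g) for g in out.values()}


def pham_partition_oracle(proteins: dict[str, str], idty: float, cov: float):
    """Exhaustive all-pairs transitive closure."""
    ids = sorted(proteins)
    uf = UnionFind(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if proteins_related_oracle(proteins[a], proteins[b], idty, cov):
                uf.union(a, b)
    return uf.groups()


def cluster_partition_oracle(genome_phams: dict[str, frozenset], threshold: float):
    """Union-find over exhaustively computed pairwise shared gene content."""
    ids = sorted(genome_phams)
    uf = UnionFind(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            pa, pb = genome_phams[a], genome_phams[b]
            inter = len(pa & pb)
            value = 0.5 * (inter / len(pa) + inter / len(pb))
            if value >= threshold:
                uf.union(a, b)
    return uf.groups()


# -- window scanning ---------------------------------------------------------


def window_regions_oracle(n_genes: int, hit_ranks: set[int], window: int):
    """Union of all qualifying sliding windows, as merged rank spans."""
    if not hit_ranks or n_genes == 0:
        return []
    starts = range(max(1, n_genes - window + 1))
    qualifying = []
    for w in starts:
        span = set(range(w, min(w + window, n_genes)))
        if span & hit_ranks:
            qualifying.append(span)
    covered = sorted(set().union(*qualifying)) if qualifying else []
    spans = []
    for r in covered:
        if spans and r == spans[-1][1] + 1:
            spans[-1][1] = r
        else:
            spans.append([r, r])
    return [tuple(s) for s in spans]


# -- PEST neighborhood network -----------------------------------------------


def neighborhood_component_oracle(contig_layouts, gene_to_pham, seeds, radius):
    """Connected components of the radius-adjacency pham graph around the
    seed phams, via networkx (the implementation iterates its own BFS).

    *contig_layouts*: mapping contig -> ordered list of gene_ids.
    Returns the set of phams reachable from the seeds (including seeds).
    """
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(set(gene_to_pham.values()))
    for genes in contig_layouts.values():
        for i, g in enumerate(genes):
            for j in range(max(0, i - radius), min(len(genes), i + radius + 1)):
                if i != j:
                    pa, pb = gene_to_pham[g], gene_to_pham[genes[j]]
                    if pa != pb:
                        graph.add_edge(pa, pb)
    reachable = set()
    for seed in seeds:
        if seed in graph:
            reachable |= nx.node_connected_component(graph, seed)
    return reachable
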